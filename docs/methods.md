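# Methods

## Image model and containers

All computation happens on 2-D float64 intensity fields normalized to
[0, 1]; integer rasters are divided by the maximum representable value of
their sample type on load, and PSNR uses MAX = 1, so MSE values are
directly comparable across bit depths. `GrayImage` enforces the range
invariant at construction (a 1e-9 round-off band is snapped to the bound).
Identical images have PSNR +∞ by convention — a documented sentinel, not an
error. Pixel indices are row-major and 0-based throughout.

## Speckle simulation

The phantom is piecewise constant: nested, equal-area ellipses on a
background, one intensity level per tissue class (default 0.2 / 0.5 / 0.8:
background, parenchyma-like annulus, sinus-like core), with center and axis
jitter drawn from the geometry seed. Each class is guaranteed ≥ 5 % of the
pixels; specs too small to satisfy that raise.

Speckle is multiplicative Gaussian: `J = clip(I·(1 + n), 0, 1)` with
`n ~ N(0, σ²)` i.i.d. This is the common desk-scale speckle convention: it
is signal-dependent (Var[J] = I²σ² away from the clip bounds) and has
closed-form moments that the tests verify by Monte Carlo. It is **not** a
physical acoustic model — no point-spread function, log-compressed Rayleigh
statistics, scan conversion or attenuation — so passing benchmarks here
demonstrate behavior under controlled signal-dependent noise on
piecewise-smooth anatomy, not clinical performance. A log-compressed
Rayleigh option would be a natural extension.

Defaults (σ = 0.2, 128×128, three classes, 20 replicate seeds) define the
standard benchmark conditions used by the test suite and the acceptance
script.

## Noise estimation and the filter coefficient h

`estimate_noise_std` convolves the image with the 3×3 Laplacian
pseudo-residual stencil `[[1,−2,1],[−2,4,−2],[1,−2,1]]` (interior pixels
only) and scales the residuals' normal-consistent median absolute deviation
by the stencil norm (6). The stencil annihilates constants and ramps, and
the median suppresses the sparse large residuals produced by tissue
boundaries, so on the phantom the estimate stays within ~10 % of the
generating std (verified over seeds). On multiplicative noise it returns an
*additive-equivalent* scale, roughly σ times the median tissue intensity.

The NL-Means bandwidth defaults to `h = λ·σ̂` with **λ = 3**. The
proportionality constant is a genuine free parameter of this family of
filters; the choice is principled as follows. With a patch kernel
normalized to sum 1, the expected distance between two noisy patches of the
same underlying tissue is `E[d] ≈ 2σ²`, so the same-class exponent is
`2σ²/(λσ̂)² ≈ 2/λ²`. λ = 1 makes that exponent ≥ 2 and annihilates nearly
every candidate weight (the filter barely denoises); λ = 3 keeps same-class
exponents ≲ 1 while a one-class intensity step (several σ̂ of contrast)
still contributes an exponent ≫ 1 and is suppressed. λ is exposed as
`--lam` / `h_lambda` for retuning. `a` defaults to 1 so the denominator
`a²h²` reduces to `h²`.

## Non-local means

Discrete weighted averaging as in the README equations. Implementation
choices:

- **Patch kernel**: Gaussian of std `patch_radius/2` (configurable),
  truncated at the patch radius, renormalized to sum 1.
- **Boundaries**: symmetric (mirror) padding for patches and gradients —
  avoids spurious dark borders and makes the filter commute with image
  mirroring (tested).
- **Search window**: Chebyshev radius 10 by default; `None` is the
  whole-image sentinel matching the integral over the full domain (used by
  the oracle tests). Candidates are in-image pixels only; the self-candidate
  always carries weight exp(0) = 1, so the normalizer K(i) ≥ 1 never
  degenerates.
- **Engine**: per-offset accumulation — for each candidate offset the patch
  distance field is a single correlation of the squared shifted difference
  with the patch kernel. This is an exact reordering of the per-pixel
  definition; `naive_oracle_denoise` (a literal pixel-pair loop, quadratic,
  capped at 32×32) agrees with it to ≤ 1e-10 on random images, and
  `weight_field` exposes the per-pixel weights for normalization checks.

### Gradient-augmented variant

The exponent numerator becomes the **product** of the intensity patch
distance and the gradient-magnitude patch distance (gradient = mirrored
central differences; at a border the mirrored neighbor halves the one-sided
difference). When either factor is zero the exponent is zero and the weight
is maximal; constant images therefore remain exact fixed points.

A consequence of the product form worth stating plainly: on [0, 1] images
both factors are ≪ 1, so their product is far smaller than either and, at
equal h, the variant smooths *more* than plain NL-Means, not less. Its
edge-awareness is relative, not absolute — the gradient factor amplifies
the distance ratio between structurally dissimilar and similar candidates
(tested on a step edge) — so the variant needs a smaller h than the plain
filter for comparable smoothing. It is benchmarked at the shared default
for transparency, where it trails the other filters.

## K-means clustering

Features are per-pixel (patch mean, patch std) over the same symmetric
padded patch as the filter (radius defaults to the filter's patch radius);
mean+std separates tissue classes under signal-dependent noise better than
raw intensity and is cheap via uniform filters. Lloyd iteration with fully
specified determinism:

- init: K distinct pixels chosen uniformly without replacement from the
  seeded generator;
- assignment: nearest center by Euclidean distance, ties to the lowest
  cluster index;
- update: member mean; a cluster emptied by reassignment is re-seeded to
  the point farthest from its nearest **live** center (stale positions of
  still-empty clusters do not count), in index order — K live clusters is
  an output invariant;
- termination: centers unchanged (exact, with 1e-12 absolute fallback) or
  `max_iter` (default 100), which sets `converged=False` rather than
  raising.

The within-cluster sum of squares is recorded after every assignment and is
non-increasing (asserted). On well-separated data the run agrees with
scikit-learn's Lloyd implementation from the same initialization (test-only
cross-check). Default K = 4 for the ultrasound use case: background, sinus,
parenchyma, plus an edge-mixture class; no automatic K selection is
attempted.

## KNL-Means coupling

Clustering restricts the candidate set — `label(j) = label(i)` within the
search window — and leaves the weight formula untouched, so normalization
and the convex-combination bound hold on the restricted set, and K = 1
reduces bit-for-bit to plain NL-Means (same floating-point path; tested).
The clustering runs on the noisy image itself, before filtering.

Blockwise mode tiles the image into `block_size` squares (ragged edges
allowed) and filters each independently — the historical 8×8
block-processing setup is available via `--block-size 8` — but clustering
is still computed once globally so blocks do not fragment tissue classes.
Blockwise filtering truncates each pixel's search neighborhood to its
block, so global mode is the default; a block the size of the image is
exactly the global mode.

The "kmeans" comparator in the benchmark replaces each pixel by its
cluster center's mean-feature value (quantization smoothing). It is a
reconstruction of intent for the conventional "K-means-only denoising"
baseline, which has no canonical definition.

## Benchmark harness

`evaluate_denoisers` corrupts the clean reference with seeded speckle, runs
each method, and scores PSNR/MSE against the clean image, per seed plus
mean ± std. h is resolved once per noisy replicate and shared by all
methods, and the cluster seed is offset by the noise seed, so comparisons
are paired and every run is reproducible bit for bit. Under the standard
conditions the orderings KNL ≥ NLM ≥ K-means-quantization ≥ noisy (PSNR,
reversed for MSE) hold over 20 seeds with ≈ 1.4 dB between KNL and NLM.

## Doppler resistive index

`RI = (PSV − EDV)/PSV`, dimensionless and invariant to the velocity unit.
Rows with EDV outside [0, PSV] or non-positive PSV are flagged invalid but
retained (with the computed value where defined) so clinical CSVs remain
auditable; group summaries use valid rows only, report sample (ddof = 1)
standard deviation, and mark n = 1 groups with an undefined (NaN) std. An
optional `site` column (sampling level of the renal arterial tree) passes
through without aggregation.

## Determinism

Every random stage draws from `numpy.random.default_rng` with an explicit
seed; the CLI fans a single `--seed` into geometry (seed), noise (seed+1)
and cluster-init (seed+2) sub-seeds, and serializes the fully resolved
configuration next to each output, so any artifact can be regenerated byte
for byte.

## Known limitations

- The speckle model and phantom are simulation conventions, not acoustic
  physics; absolute PSNR values on real scanner data will differ.
- The gradient-augmented variant's product-form distance requires its own
  bandwidth tuning (see above).
- No FFT/integral-image acceleration: the per-offset engine is O(window ·
  pixels · patch); fine at desk scale, slow for large images with large
  windows.
- Clustering quality on heavily textured tissue limits the KNL restriction;
  misassigned pixels lose useful candidates. K selection is manual.
- Grayscale 2-D only: no Doppler color overlays, DICOM, SSIM, or 3-D
  volumes.
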