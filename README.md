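# knlmeans

Speckle-noise reduction for B-mode ultrasound images by **K-means-guided
non-local-means (KNL-Means) filtering**, with a synthetic speckled-phantom
simulator, a PSNR/MSE benchmark harness, and renal Doppler resistive-index
utilities.

Ultrasound images carry multiplicative speckle that obscures tissue
boundaries. Non-local-means (NL-Means) denoising exploits self-similarity:
each pixel is replaced by a weighted average of candidates whose surrounding
patches look alike,

```
S(w(i)) = Σ_j T(i,j) · w(j)
T(i,j)  = exp( −‖w(W_i) − w(W_j)‖²_G / a²h² ) / K(i)
K(i)    = Σ_j exp( −‖w(W_i) − w(W_j)‖²_G / a²h² )
```

where `‖·‖²_G` is a Gaussian-kernel-weighted squared patch distance and `h`
is the filter bandwidth, tied here to the image's own estimated noise
standard deviation. Plain NL-Means can still average across tissue
boundaries; KNL-Means first clusters pixels by K-means on local patch
statistics (patch mean, patch std) and restricts each pixel's candidate set
to its own tissue class, preserving edges and detail. A gradient-augmented
variant multiplies the intensity patch distance by the analogous distance
between gradient-magnitude patches. The package also computes the Doppler
resistive index `RI = (PSV − EDV)/PSV` from peak-systolic / end-diastolic
velocity tables, the hemodynamic endpoint this imaging pipeline serves.

Audience: researchers prototyping ultrasound denoising pipelines and anyone
needing a small, well-tested, fully deterministic reference implementation
of NL-Means / KNL-Means with an honest evaluation harness.

## Worked example

```sh
knlm simulate --height 128 --width 128 --sigma 0.2 --seed 7 \
    --out clean.png --noisy noisy.png
knlm denoise --method knl --in noisy.png --out denoised.png --ref clean.png
```

prints

```
PSNR input 19.95 dB -> output 29.43 dB
```

the quality of the speckled phantom (19.95 dB against the clean reference)
and of its KNL-Means reconstruction (29.43 dB) — roughly a 10x reduction in
mean squared error. The same run from the library:

```python
from knlmeans import (PhantomSpec, SpeckleParams, KNLConfig,
                      make_phantom, add_speckle, knl_denoise, psnr)

clean = make_phantom(PhantomSpec(geometry_seed=7))
noisy = add_speckle(clean, SpeckleParams(sigma=0.2, seed=8))
denoised = knl_denoise(noisy, KNLConfig(k=4))
print(f"{psnr(clean, noisy):.2f} -> {psnr(clean, denoised):.2f} dB")
```

Doppler resistive index from a velocity table:

```sh
knlm ri --in doppler.csv --out ri.csv
```

```
group  n_valid  n_invalid  ri_mean  ri_std
  dkd        1          0     0.63     NaN
```

A subject with PSV 100 cm/s and EDV 37 cm/s has RI = 0.63; physiologically
impossible rows (EDV > PSV) are kept but flagged invalid and excluded from
the summary.

Other subcommands: `knlm cluster` (K-means label map of an image),
`knlm evaluate` (multi-seed PSNR/MSE benchmark over the implemented
methods), `knlm fixtures` (deterministic demo inputs). Every run writes a
`<output>.manifest.json` with its fully resolved parameters; rerunning with
the same seed reproduces outputs byte for byte.

## Layout

| module | contents |
|---|---|
| `knlmeans.image` | `GrayImage` container, PNG/TIFF I/O, MSE/PSNR |
| `knlmeans.phantom` | phantom generator, speckle model, noise-std estimator |
| `knlmeans.nlmeans` | NL-Means, gradient variant, brute-force oracle |
| `knlmeans.kmeans` | pixel features, Lloyd iteration with documented tie/empty-cluster rules |
| `knlmeans.pipeline` | KNL-Means coupling, blockwise mode, benchmark harness |
| `knlmeans.doppler` | resistive index, batch CSV processing |
| `knlmeans.cli` | `knlm` command-line front end |

See `docs/methods.md` for the model descriptions, parameter defaults and
their rationale, and known limitations.
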