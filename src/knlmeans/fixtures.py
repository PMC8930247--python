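"""Deterministic generation of the standard demonstration/test inputs."""

from __future__ import annotations

from os import PathLike
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .image import GrayImage, save_image
from .phantom import PhantomSpec, SpeckleParams, add_speckle, make_phantom

__all__ = ["make_fixtures"]


def make_fixtures(out_dir: Union[str, PathLike], seed: int = 0) -> dict[str, Path]:
    """Write the standard fixture set into ``out_dir``.

    Emits, all deterministically derived from ``seed``:

    - ``phantom_clean.png`` — 128x128 three-class nested-ellipse phantom
    - ``phantom_noisy.png`` — the same phantom under sigma = 0.2 speckle
    - ``oracle_input.png``  — 12x12 random image, small enough for the
      quadratic brute-force filter
    - ``doppler.csv``       — 6 PSV/EDV rows across two groups, including
      one physiologically invalid row (EDV > PSV)

    Returns the mapping from fixture name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    spec = PhantomSpec(
        height=128, width=128, class_intensities=(0.2, 0.5, 0.8), geometry_seed=seed
    )
    clean = make_phantom(spec)
    noisy = add_speckle(clean, SpeckleParams(sigma=0.2, seed=seed + 1))
    paths["phantom_clean"] = out / "phantom_clean.png"
    paths["phantom_noisy"] = out / "phantom_noisy.png"
    save_image(clean, paths["phantom_clean"])
    save_image(noisy, paths["phantom_noisy"])

    rng = np.random.default_rng(seed + 2)
    oracle = GrayImage(rng.uniform(0.0, 1.0, size=(12, 12)))
    paths["oracle_input"] = out / "oracle_input.png"
    save_image(oracle, paths["oracle_input"])

    doppler = pd.DataFrame(
        {
            "subject_id": ["c1", "c2", "c3", "p1", "p2", "p3"],
            "group": ["control", "control", "control", "dkd", "dkd", "dkd"],
            "psv": [100.0, 90.0, 110.0, 95.0, 105.0, 80.0],
            "edv": [42.0, 38.0, 46.0, 31.0, 33.0, 95.0],  # last row: EDV > PSV
        }
    )
    paths["doppler"] = out / "doppler.csv"
    doppler.to_csv(paths["doppler"], index=False)
    return paths
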