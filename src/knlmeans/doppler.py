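"""Renal Doppler resistive index (RI) from PSV/EDV velocity pairs.

RI = (PSV - EDV) / PSV, with PSV the peak systolic and EDV the end
diastolic blood-flow velocity (cm/s) of the sampled artery.  RI is
dimensionless, scale-invariant in the velocity unit, and lies in [0, 1]
for physiologic measurements (0 <= EDV <= PSV); elevated values indicate
increased downstream vascular resistance, as in diabetic kidney disease.

Batch processing keeps physiologically invalid rows (EDV outside
[0, PSV], or non-positive PSV) in the output table with a ``valid`` flag
instead of dropping them, so clinical CSVs with artifacts stay auditable;
summaries are computed over valid rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["DopplerMeasurement", "BatchRIResult", "resistive_index", "batch_ri"]


def resistive_index(psv: float, edv: float) -> float:
    """RI = (PSV - EDV) / PSV.

    Requires ``psv > 0``; the value is returned even for out-of-range EDV
    (validity is the caller's concern — see ``batch_ri``).
    """
    if psv <= 0:
        raise ValueError(f"PSV must be positive, got {psv}")
    return (psv - edv) / psv


@dataclass(frozen=True)
class DopplerMeasurement:
    """One PSV/EDV pair with its derived RI and validity flag."""

    psv: float
    edv: float
    subject_id: str = ""
    group: str = ""
    site: Optional[str] = None

    @property
    def valid(self) -> bool:
        return self.psv > 0 and 0 <= self.edv <= self.psv

    @property
    def ri(self) -> float:
        if self.psv <= 0:
            return float("nan")
        return resistive_index(self.psv, self.edv)


@dataclass(frozen=True)
class BatchRIResult:
    """Row-level RI table plus per-group descriptive summary.

    ``table`` is the input with ``ri`` and ``valid`` columns appended.
    ``summary`` has one row per group: valid count, invalid count, RI
    mean, and sample (ddof=1) standard deviation — NaN when fewer than
    two valid rows.
    """

    table: pd.DataFrame
    summary: pd.DataFrame


_TableLike = Union[pd.DataFrame, Sequence[DopplerMeasurement]]


def batch_ri(table: _TableLike) -> BatchRIResult:
    """Compute RI per row and per-group mean +/- std over valid rows.

    Accepts a DataFrame with columns ``subject_id, group, psv, edv``
    (extra columns pass through) or a sequence of measurements.  Groups
    with no valid rows are omitted from the summary with a warning.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        for col in ("psv", "edv"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if "group" not in df.columns:
            df["group"] = ""
    else:
        df = pd.DataFrame(
            {
                "subject_id": [m.subject_id for m in table],
                "group": [m.group for m in table],
                "psv": [m.psv for m in table],
                "edv": [m.edv for m in table],
            }
        )
    psv = df["psv"].to_numpy(dtype=float)
    edv = df["edv"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ri = np.where(psv > 0, (psv - edv) / psv, np.nan)
    df["ri"] = ri
    df["valid"] = (psv > 0) & (edv >= 0) & (edv <= psv)

    rows = []
    for group, sub in df.groupby("group", sort=False, dropna=False):
        valid = sub[sub["valid"]]
        if valid.empty:
            warnings.warn(
                f"group {group!r} has no valid measurements; omitted from summary",
                stacklevel=2,
            )
            continue
        vals = valid["ri"].to_numpy()
        rows.append(
            {
                "group": group,
                "n_valid": len(valid),
                "n_invalid": int((~sub["valid"]).sum()),
                "ri_mean": float(vals.mean()),
                "ri_std": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    return BatchRIResult(table=df, summary=pd.DataFrame(rows))
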