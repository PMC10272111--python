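"""Null-anchored secretion thresholds and SEC classification.

The secretion feature barcode of cells that cannot secrete IgG (IGHM+ and
IGHA+ cells) provides an empirical null. On the log10(1+count) scale:

* the high cutoff ``t_hi`` is the nearest-rank 90% quantile (configurable)
  of the null values;
* the low cutoff mirrors it about the null mean:
  ``t_lo = null_mean - (t_hi - null_mean)``.

A cell is SEC-hi when its transformed barcode value is strictly above
``t_hi``, SEC-lo strictly below ``t_lo``, and SEC-mid otherwise (the cutoff
itself is not "above the quantile", so boundary values are mid).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SecretionThresholds",
    "transform_barcode",
    "compute_sec_thresholds",
    "classify_secretion",
    "group_secretion_composition",
    "pseudotime_secretor_profile",
]

SEC_LABELS = ("sec_hi", "sec_lo", "sec_mid")


@dataclass
class SecretionThresholds:
    """Null-anchored high/low cutoffs with the null summary that made them.

    The symmetry ``t_lo = 2 * null_mean - t_hi`` holds exactly by
    construction.
    """

    t_hi: float
    t_lo: float
    null_mean: float
    null_n: int
    quantile: float = 0.90
    transform: str = "log10_1p"

    def __post_init__(self) -> None:
        if not math.isclose(self.t_lo, 2 * self.null_mean - self.t_hi,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("t_lo must mirror t_hi about the null mean")

    def to_dict(self) -> dict:
        return {
            "t_hi": float(self.t_hi),
            "t_lo": float(self.t_lo),
            "null_mean": float(self.null_mean),
            "null_n": int(self.null_n),
            "quantile": float(self.quantile),
            "transform": self.transform,
        }


def transform_barcode(counts: Iterable[float] | float) -> np.ndarray | float:
    """log10(1 + count): monotone, maps 0 to 0."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("barcode counts must be non-negative")
    out = np.log10(1.0 + arr)
    return float(out) if out.ndim == 0 else out


def nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    """Empirical quantile, nearest-rank: sorted value at index ceil(q*n)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    k = max(1, math.ceil(q * n))
    return float(x[k - 1])


def compute_sec_thresholds(
    null_values: Sequence[float],
    quantile: float = 0.90,
    min_null_cells: int = 50,
) -> SecretionThresholds:
    """Derive SEC-hi / SEC-lo cutoffs from the non-IgG null distribution.

    ``null_values`` are the transformed barcode values of IGHM+ and IGHA+
    cells. Raises when the null is too small to anchor a quantile; supply
    explicit thresholds in that case.
    """
    x = np.asarray(null_values, dtype=float)
    if not 0.5 < quantile < 1.0:
        raise ValueError("quantile must lie in (0.5, 1)")
    if x.size < min_null_cells:
        raise ValueError(
            f"only {x.size} null cells (< {min_null_cells}); too few to anchor "
            "thresholds — pass explicit SecretionThresholds instead"
        )
    t_hi = nearest_rank_quantile(x, quantile)
    null_mean = float(x.mean())
    return SecretionThresholds(
        t_hi=t_hi,
        t_lo=null_mean - (t_hi - null_mean),
        null_mean=null_mean,
        null_n=int(x.size),
        quantile=quantile,
    )


def classify_secretion(
    values: Iterable[float] | float, thresholds: SecretionThresholds
) -> np.ndarray | str:
    """Label transformed barcode values sec_hi / sec_lo / sec_mid.

    Strict inequalities on both sides: a value exactly at a cutoff is mid.
    """
    arr = np.asarray(values, dtype=float)
    out = np.select(
        [arr > thresholds.t_hi, arr < thresholds.t_lo],
        ["sec_hi", "sec_lo"],
        default="sec_mid",
    )
    return str(out) if out.ndim == 0 else out


def group_secretion_composition(
    cells: pd.DataFrame, group_key: str, label_col: str = "sec_class"
) -> pd.DataFrame:
    """Per-group percentage of SEC-hi / -lo / -mid cells.

    ``group_key`` is a column of the cell table (cluster, isotype_call,
    subclass_call, donor, ...). Percentages sum to 100 per group; empty
    groups are omitted.
    """
    if group_key not in cells.columns:
        raise ValueError(f"unknown group key {group_key!r}")
    if label_col not in cells.columns:
        raise ValueError(f"cell table lacks {label_col!r}; classify first")
    rows = []
    for group, sub in cells.groupby(group_key, sort=True, observed=True):
        n = len(sub)
        if n == 0:
            continue
        tallies = sub[label_col].value_counts()
        row = {"group": group, "n": n}
        for lab in SEC_LABELS:
            row[f"pct_{lab[4:]}"] = 100.0 * tallies.get(lab, 0) / n
        rows.append(row)
    return pd.DataFrame(rows, columns=["group", "n", "pct_hi", "pct_lo", "pct_mid"])


def pseudotime_secretor_profile(
    cells: pd.DataFrame,
    bin_width: float = 0.05,
    per: str | None = "donor",
    min_bin_cells: int = 10,
    label_col: str = "sec_class",
) -> pd.DataFrame:
    """Fraction of SEC-hi cells per pseudotime bin (per donor by default).

    Bins are half-open ``[k*w, (k+1)*w)`` with the final bin closed at 1.0.
    Bins with fewer than ``min_bin_cells`` cells are reported with
    ``frac_hi`` missing (NaN) rather than zero. Pseudotime must be supplied
    as input (its inference is upstream of this package).
    """
    if "pseudotime" not in cells.columns or cells["pseudotime"].isna().all():
        raise ValueError(
            "pseudotime missing: supply a per-cell pseudotime column computed "
            "upstream (trajectory inference is not part of this pipeline)"
        )
    pt = cells["pseudotime"].to_numpy(dtype=float)
    if np.nanmin(pt) < 0 or np.nanmax(pt) > 1:
        raise ValueError("pseudotime must lie in [0, 1]")
    n_bins = int(math.ceil(round(1.0 / bin_width, 9)))
    # tiny epsilon keeps boundary values (e.g. 0.85 / 0.05) in their own bin
    # despite floating-point division; 1.0 folds into the final closed bin
    idx = np.minimum((pt / bin_width + 1e-9).astype(int), n_bins - 1)

    groups = (
        [("all", np.ones(len(cells), dtype=bool))]
        if per is None
        else [(d, (cells[per] == d).to_numpy()) for d in sorted(cells[per].unique())]
    )
    rows = []
    for gname, mask in groups:
        for b in range(n_bins):
            in_bin = mask & (idx == b) & ~np.isnan(pt)
            n = int(in_bin.sum())
            lo, hi = b * bin_width, min((b + 1) * bin_width, 1.0)
            frac = (
                float((cells.loc[in_bin, label_col] == "sec_hi").mean())
                if n >= min_bin_cells
                else np.nan
            )
            rows.append(
                {
                    "group": gname,
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "bin_mid": (lo + hi) / 2,
                    "n": n,
                    "frac_hi": frac,
                }
            )
    return pd.DataFrame(rows)
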