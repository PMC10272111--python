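"""Transcript-space "flow-style" gating: bimodal gates, isotype calls.

IGHM and IGHA1 expression across a differentiated B-cell cohort is bimodal
(an off mode near zero and an on mode for cells of that isotype). A gate is
placed at the local minimum of a Gaussian kernel density estimate between
the two dominant modes. Cells below both gates (double negative, DN) that
carry any IGHG1-4 transcripts are called IgG cells, with the subclass taken
as the argmax of the raw subclass counts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io_formats import GeneCountMatrix
from .preprocess import NormalizedMatrix

__all__ = [
    "GateSpec",
    "IsotypeCall",
    "GateWarning",
    "find_bimodal_gate",
    "assign_isotype",
    "assign_isotypes",
    "score_activated_vs_asc",
    "DEFAULT_ACTIVATED_MARKERS",
    "DEFAULT_ASC_MARKERS",
]

DEFAULT_ACTIVATED_MARKERS = ("PAX5", "MS4A1", "CD19", "HLA-DRA", "HLA-DMA")
DEFAULT_ASC_MARKERS = ("XBP1", "IRF4", "PRDM1", "MZB1")
IGG_SUBCLASSES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4")


class GateWarning(UserWarning):
    """Emitted when the bimodal gate falls back to a quantile threshold."""


@dataclass
class GateSpec:
    """A threshold on one expression channel.

    ``method`` records how the threshold was obtained: ``kde_local_min``
    (density minimum between the two dominant modes), ``explicit`` (user
    supplied), or ``fallback_quantile`` (distribution not bimodal).
    ``diagnostics`` carries the mode locations and the density at the
    minimum for auditing.
    """

    channel: str
    threshold: float
    method: str = "explicit"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("gate threshold must be finite")
        if self.method == "kde_local_min":
            lo = self.diagnostics.get("mode_lo")
            hi = self.diagnostics.get("mode_hi")
            if lo is not None and hi is not None and not (lo < self.threshold < hi):
                raise ValueError("kde_local_min threshold must lie between modes")

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "threshold": float(self.threshold),
            "method": self.method,
            "diagnostics": {k: float(v) for k, v in self.diagnostics.items()},
        }


@dataclass
class IsotypeCall:
    """Per-cell isotype label and IgG subclass.

    ``subclass`` is one of IGHG1-4 exactly when ``label == "IgG"``.
    """

    label: str  # IGHM_pos | IGHA_pos | IgG | DN_nonIgG | excluded
    subclass: str = "none"
    subclass_tie: bool = False

    def __post_init__(self) -> None:
        if (self.subclass != "none") != (self.label == "IgG"):
            raise ValueError("subclass set iff label is IgG")


def find_bimodal_gate(
    values: Iterable[float],
    channel: str = "",
    grid_points: int = 512,
    bandwidth_rule: str = "silverman",
    fallback_quantile: float = 0.5,
) -> GateSpec:
    """Place a gate at the KDE local minimum between the two dominant modes.

    A Gaussian KDE (Silverman bandwidth by default) is evaluated on an even
    grid spanning the data padded by three bandwidths. The two highest-
    density local maxima are taken as the modes, and the threshold is the
    grid argmin of the density strictly between them. If fewer than two
    modes are found the gate falls back to the ``fallback_quantile`` of the
    data with a :class:`GateWarning`.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 20:
        raise ValueError(
            f"need at least 20 values for a density estimate, got {x.size}"
        )

    def _fallback(reason: str) -> GateSpec:
        thr = float(np.quantile(x, fallback_quantile))
        warnings.warn(
            f"channel {channel or '<unnamed>'}: {reason}; falling back to the "
            f"{fallback_quantile} quantile ({thr:.4g})",
            GateWarning,
            stacklevel=2,
        )
        return GateSpec(
            channel=channel,
            threshold=thr,
            method="fallback_quantile",
            diagnostics={"fallback_quantile": fallback_quantile},
        )

    if np.ptp(x) == 0:
        return _fallback("degenerate (constant) distribution")

    kde = gaussian_kde(x, bw_method=bandwidth_rule)
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    dens = kde(grid)

    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    if len(interior) < 2:
        return _fallback("fewer than two density modes")
    top2 = interior[np.argsort(dens[interior])[-2:]]
    i_lo, i_hi = sorted(int(i) for i in top2)
    if i_hi - i_lo < 2:
        return _fallback("modes not separated on the grid")
    between = slice(i_lo + 1, i_hi)
    j = i_lo + 1 + int(np.argmin(dens[between]))
    return GateSpec(
        channel=channel,
        threshold=float(grid[j]),
        method="kde_local_min",
        diagnostics={
            "mode_lo": float(grid[i_lo]),
            "mode_hi": float(grid[i_hi]),
            "density_at_min": float(dens[j]),
            "bandwidth": float(h),
        },
    )


def assign_isotype(
    cell_norm_expr: Mapping[str, float],
    gates: Mapping[str, GateSpec],
    igg_counts: Sequence[float],
    excluded: bool = False,
) -> IsotypeCall:
    """Classify one cell's heavy-chain isotype.

    IGHM above its gate wins; otherwise IGHA1 above its gate; otherwise the
    cell is DN and is called IgG iff the summed raw IGHG1-4 counts are
    non-zero, with the subclass the argmax subclass count (ties broken by
    subclass order, recorded in ``subclass_tie``). Cells flagged by the
    chain-exclusivity filter are labeled ``excluded``.
    """
    if excluded:
        return IsotypeCall(label="excluded")
    if cell_norm_expr["IGHM"] > gates["IGHM"].threshold:
        return IsotypeCall(label="IGHM_pos")
    if cell_norm_expr["IGHA1"] > gates["IGHA1"].threshold:
        return IsotypeCall(label="IGHA_pos")
    counts = np.asarray(list(igg_counts), dtype=float)
    if counts.shape != (4,):
        raise ValueError("igg_counts must have 4 entries (IGHG1-4)")
    if counts.sum() > 0:
        best = int(np.argmax(counts))  # argmax takes the first on ties
        tie = bool((counts == counts[best]).sum() > 1)
        return IsotypeCall(label="IgG", subclass=IGG_SUBCLASSES[best],
                           subclass_tie=tie)
    return IsotypeCall(label="DN_nonIgG")


def assign_isotypes(
    norm: NormalizedMatrix,
    gates: Mapping[str, GateSpec],
    counts: GeneCountMatrix,
    excluded_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vectorized isotype assignment for a whole cohort.

    Returns a DataFrame aligned to the cell axis with columns
    ``isotype_call``, ``subclass_call`` and ``subclass_tie``.
    """
    n = norm.n_cells
    excluded = (
        np.zeros(n, dtype=bool) if excluded_mask is None
        else np.asarray(excluded_mask, dtype=bool)
    )
    ighm = norm.gene_values("IGHM") > gates["IGHM"].threshold
    igha = norm.gene_values("IGHA1") > gates["IGHA1"].threshold
    sub_counts = np.column_stack(
        [counts.gene_counts(g) for g in IGG_SUBCLASSES]
    ).astype(float)
    any_igg = sub_counts.sum(axis=1) > 0
    best = np.argmax(sub_counts, axis=1)
    n_at_max = (sub_counts == sub_counts[np.arange(n), best][:, None]).sum(axis=1)

    label = np.select(
        [excluded, ighm, igha, any_igg],
        ["excluded", "IGHM_pos", "IGHA_pos", "IgG"],
        default="DN_nonIgG",
    )
    subclass = np.where(
        label == "IgG", np.asarray(IGG_SUBCLASSES)[best], "none"
    )
    tie = (label == "IgG") & (n_at_max > 1)
    return pd.DataFrame(
        {
            "barcode": norm.cell_barcodes,
            "isotype_call": label,
            "subclass_call": subclass,
            "subclass_tie": tie,
        }
    )


def score_activated_vs_asc(
    norm: NormalizedMatrix,
    activated_markers: Sequence[str] = DEFAULT_ACTIVATED_MARKERS,
    asc_markers: Sequence[str] = DEFAULT_ASC_MARKERS,
) -> pd.DataFrame:
    """Cluster-free activated-B vs antibody-secreting-cell call per cell.

    Each score is the mean normalized expression over the marker genes
    present in the panel (missing markers dropped with a warning); the label
    is the argmax, with ties going to ASC (flagged).
    """

    def _score(markers: Sequence[str], which: str) -> np.ndarray:
        present = [m for m in markers if m in norm.gene_symbols]
        missing = [m for m in markers if m not in norm.gene_symbols]
        if missing:
            warnings.warn(f"{which} markers missing from panel: {missing}",
                          stacklevel=3)
        if not present:
            raise ValueError(f"no {which} marker genes present in the panel")
        return np.mean([norm.gene_values(m) for m in present], axis=0)

    if not activated_markers and not asc_markers:
        raise ValueError("both marker sets are empty")
    act = _score(activated_markers, "activated_B")
    asc = _score(asc_markers, "ASC")
    tie = act == asc
    label = np.where(act > asc, "activated_B", "ASC")
    return pd.DataFrame(
        {
            "barcode": norm.cell_barcodes,
            "activated_score": act,
            "asc_score": asc,
            "population_call": label,
            "score_tie": tie,
        }
    )
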