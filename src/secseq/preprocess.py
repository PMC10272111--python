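"""Quality filtering, chain-exclusivity exclusion, and log normalization.

A cell passes QC when it expresses at least ``min_genes_per_cell`` genes and
carries at least ``min_counts_per_cell`` total UMIs. Cells expressing more
than one heavy-chain isotype channel above its gate, or both light chains
above their gates, are excluded (a plasma cell expresses exactly one heavy
and one light chain; multi-chain barcodes are likely doublets).

Normalization follows the usual single-cell convention: scale each cell to
``target_sum`` total counts, then natural ``log1p``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import GeneCountMatrix

if TYPE_CHECKING:  # circular at runtime only for typing
    from .gating import GateSpec

__all__ = [
    "NormalizedMatrix",
    "FilterReport",
    "qc_filter",
    "chain_exclusivity_filter",
    "normalize_log",
    "HEAVY_CHANNELS",
    "LIGHT_CHANNELS",
    "DEFAULT_CHANNEL_GENES",
]

HEAVY_CHANNELS = ("IGHM", "IGHA1", "IGHG-sum")
LIGHT_CHANNELS = ("IGKC", "IGLC")

DEFAULT_CHANNEL_GENES: dict[str, tuple[str, ...]] = {
    "IGHM": ("IGHM",),
    "IGHA1": ("IGHA1",),
    "IGHG-sum": ("IGHG1", "IGHG2", "IGHG3", "IGHG4"),
    "IGHG1": ("IGHG1",),
    "IGHG2": ("IGHG2",),
    "IGHG3": ("IGHG3",),
    "IGHG4": ("IGHG4",),
    "IGKC": ("IGKC",),
    "IGLC": ("IGLC2",),
}


@dataclass
class NormalizedMatrix:
    """Cells x genes log1p(depth-scaled counts), sparse.

    ``zero_total`` flags cells whose raw total was zero; their rows are
    all-zero rather than NaN.
    """

    values: sp.csr_matrix
    cell_barcodes: list[str]
    gene_symbols: list[str]
    target_sum: float
    zero_total: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def gene_values(self, symbol: str) -> np.ndarray:
        try:
            j = self.gene_symbols.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in panel") from None
        return np.asarray(self.values[:, j].todense()).ravel()

    def channel_values(self, channel: str,
                       channel_genes: Mapping[str, Sequence[str]] | None = None
                       ) -> np.ndarray:
        """Normalized value of a gating channel (summing pooled genes' counts
        on the normalized scale via log1p of summed scaled counts)."""
        channel_genes = channel_genes or DEFAULT_CHANNEL_GENES
        genes = channel_genes.get(channel, (channel,))
        cols = [self.gene_symbols.index(g) for g in genes if g in self.gene_symbols]
        if not cols:
            raise KeyError(f"no genes for channel {channel!r} in panel")
        # invert log1p per gene, sum the scaled counts, re-log
        block = np.asarray(self.values[:, cols].todense())
        return np.log1p(np.expm1(block).sum(axis=1))

    def toarray(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class FilterReport:
    """Accounting of a filtering stage: n_input = n_kept + exclusions."""

    n_input: int
    n_kept: int
    n_excluded_lowq: int = 0
    n_excluded_multichain: int = 0
    reasons: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.n_input != (
            self.n_kept + self.n_excluded_lowq + self.n_excluded_multichain
        ):
            raise ValueError("filter report does not conserve cell counts")


def qc_filter(
    matrix: GeneCountMatrix,
    min_genes_per_cell: int = 200,
    min_counts_per_cell: int = 500,
) -> tuple[GeneCountMatrix, FilterReport]:
    """Remove low-quality cells; the gene axis is unchanged."""
    if min_genes_per_cell < 0 or min_counts_per_cell < 0:
        raise ValueError("thresholds must be non-negative")
    csr = matrix.counts.tocsr()
    genes_per_cell = csr.getnnz(axis=1)
    counts_per_cell = np.asarray(csr.sum(axis=1)).ravel()
    keep = (genes_per_cell >= min_genes_per_cell) & (
        counts_per_cell >= min_counts_per_cell
    )
    reasons = pd.DataFrame(
        {
            "barcode": matrix.cell_barcodes,
            "reason": np.where(keep, "kept", "low_quality"),
        }
    )
    report = FilterReport(
        n_input=matrix.n_cells,
        n_kept=int(keep.sum()),
        n_excluded_lowq=int((~keep).sum()),
        reasons=reasons,
    )
    return matrix.subset_cells(np.flatnonzero(keep)), report


def chain_exclusivity_filter(
    matrix: Union[GeneCountMatrix, NormalizedMatrix],
    gates: Mapping[str, "GateSpec"],
    target_sum: float = 1e4,
    channel_genes: Mapping[str, Sequence[str]] | None = None,
) -> tuple[np.ndarray, FilterReport]:
    """Exclude cells violating heavy/light chain exclusivity.

    A cell is excluded when more than one heavy-chain channel (IGHM, IGHA1,
    pooled IGHG1-4) exceeds its gate, when two IGHG subclasses exceed
    subclass gates (if subclass gates are supplied), or when both light
    chains exceed their gates. Gates are on the normalized-log scale; a raw
    count matrix is normalized internally with ``target_sum``.

    Returns the kept cell index array (positions into the input cell axis)
    and a :class:`FilterReport`.
    """
    norm = (
        matrix
        if isinstance(matrix, NormalizedMatrix)
        else normalize_log(matrix, target_sum)
    )
    for channel in HEAVY_CHANNELS + LIGHT_CHANNELS:
        if channel not in gates:
            raise ValueError(f"missing gate for channel {channel!r}")

    def above(channel: str) -> np.ndarray:
        vals = norm.channel_values(channel, channel_genes)
        return vals > gates[channel].threshold

    heavy_hits = sum(above(c).astype(int) for c in HEAVY_CHANNELS)
    multi_heavy = heavy_hits > 1
    sub_gates = [c for c in ("IGHG1", "IGHG2", "IGHG3", "IGHG4") if c in gates]
    if len(sub_gates) >= 2:
        sub_hits = sum(above(c).astype(int) for c in sub_gates)
        multi_heavy |= sub_hits > 1
    both_light = above("IGKC") & above("IGLC")
    excluded = multi_heavy | both_light

    reasons = pd.DataFrame(
        {
            "barcode": norm.cell_barcodes,
            "reason": np.select(
                [multi_heavy, both_light],
                ["multi_heavy_chain", "multi_light_chain"],
                default="kept",
            ),
        }
    )
    report = FilterReport(
        n_input=norm.n_cells,
        n_kept=int((~excluded).sum()),
        n_excluded_multichain=int(excluded.sum()),
        reasons=reasons,
    )
    return np.flatnonzero(~excluded), report


def normalize_log(matrix: GeneCountMatrix, target_sum: float = 1e4) -> NormalizedMatrix:
    """Depth-normalize to ``target_sum`` per cell, then natural log1p.

    value(c, g) = log1p(count(c, g) * target_sum / total(c)); cells with a
    zero total are left all-zero and flagged.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    csr = matrix.counts.tocsr().astype(float)
    totals = np.asarray(csr.sum(axis=1)).ravel()
    zero_total = totals == 0
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals), where=~zero_total
    )
    scaled = sp.diags(scale) @ csr
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(
        values=sp.csr_matrix(scaled),
        cell_barcodes=list(matrix.cell_barcodes),
        gene_symbols=list(matrix.gene_symbols),
        target_sum=float(target_sum),
        zero_total=zero_total,
    )
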