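"""Barnyard species-mixing classification and nanovial on/off calling.

In a mixed human/mouse run the gene panel partitions by species prefix
(``GRCh38_`` / ``mm10_``, the CellRanger barnyard convention). Each barcode
is classified from its per-species transcript totals: too few counts is
uninformative, a minor-species fraction at or above ``minor_threshold``
means coincident loading (mixed), otherwise the majority species wins. The
mixed fraction over informative barcodes estimates the doublet rate.

On/off-nanovial calling thresholds the nanovial feature barcode on the
log10(1+count) scale with the shared bimodal gate detector.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gating import GateSpec, find_bimodal_gate
from .io_formats import GeneCountMatrix
from .secretion import transform_barcode

__all__ = [
    "SpeciesCall",
    "NanovialCall",
    "classify_species",
    "classify_species_matrix",
    "mixed_fraction",
    "classify_on_nanovial",
    "species_totals",
]

SPECIES_PREFIXES = {"human": "GRCh38_", "mouse": "mm10_"}


@dataclass
class SpeciesCall:
    """Species assignment of one barcode from per-species totals."""

    label: str  # human | mouse | mixed | low_info
    human_counts: int
    mouse_counts: int
    minor_fraction: float

    def __post_init__(self) -> None:
        if self.label not in ("human", "mouse", "mixed", "low_info"):
            raise ValueError(f"bad species label {self.label!r}")


@dataclass
class NanovialCall:
    """On/off-nanovial call for one barcode."""

    label: str  # on_nanovial | off_nanovial
    barcode_count: int
    gate: GateSpec = field(repr=False, default=None)  # type: ignore[assignment]


def classify_species(
    H: int,
    M: int,
    min_total: int = 100,
    minor_threshold: float = 0.10,
) -> SpeciesCall:
    """Classify one barcode from human (H) and mouse (M) transcript totals.

    ``H + M < min_total`` is uninformative (low_info); a minor-species
    fraction ``min(H, M) / (H + M)`` at or above ``minor_threshold`` is
    mixed; otherwise the majority species.
    """
    if H < 0 or M < 0:
        raise ValueError("counts must be non-negative")
    total = H + M
    minor = min(H, M) / total if total > 0 else 0.0
    if total < min_total:
        label = "low_info"
    elif minor >= minor_threshold:
        label = "mixed"
    else:
        label = "human" if H >= M else "mouse"
    return SpeciesCall(label=label, human_counts=int(H), mouse_counts=int(M),
                       minor_fraction=float(minor))


def species_totals(
    matrix: GeneCountMatrix,
    prefixes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-barcode transcript totals for each species gene prefix."""
    prefixes = prefixes or SPECIES_PREFIXES
    out = {"barcode": matrix.cell_barcodes}
    csr = matrix.counts.tocsr()
    for species, prefix in prefixes.items():
        cols = [j for j, g in enumerate(matrix.gene_symbols)
                if g.startswith(prefix)]
        if not cols:
            raise ValueError(f"no genes with prefix {prefix!r} in panel")
        out[species] = np.asarray(csr[:, cols].sum(axis=1)).ravel().astype(int)
    return pd.DataFrame(out)


def classify_species_matrix(
    matrix: GeneCountMatrix,
    min_total: int = 100,
    minor_threshold: float = 0.10,
    prefixes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Species call per barcode of a barnyard count matrix."""
    totals = species_totals(matrix, prefixes)
    calls = [
        classify_species(h, m, min_total=min_total,
                         minor_threshold=minor_threshold)
        for h, m in zip(totals["human"], totals["mouse"])
    ]
    totals["species_call"] = [c.label for c in calls]
    totals["minor_fraction"] = [c.minor_fraction for c in calls]
    return totals


def mixed_fraction(calls: Iterable[SpeciesCall | str]) -> float:
    """Fraction of informative barcodes called mixed.

    ``low_info`` barcodes are excluded from the denominator; raises when no
    informative calls remain.
    """
    labels = [c.label if isinstance(c, SpeciesCall) else str(c) for c in calls]
    informative = [l for l in labels if l != "low_info"]
    if not informative:
        raise ValueError("no informative species calls")
    return informative.count("mixed") / len(informative)


def classify_on_nanovial(
    nanovial_counts: Sequence[int],
    gate: GateSpec | None = None,
) -> list[NanovialCall]:
    """Call each barcode on/off nanovial from the nanovial feature barcode.

    Without an explicit gate, the bimodal gate detector runs on
    log10(1+count); a unimodal distribution then raises, requiring an
    explicit threshold. A count strictly above the threshold (on the gate's
    scale) is on-nanovial.
    """
    counts = np.asarray(nanovial_counts)
    if (counts < 0).any():
        raise ValueError("nanovial counts must be non-negative")
    values = transform_barcode(counts)
    if gate is None:
        gate = find_bimodal_gate(values, channel="Nanovial")
        if gate.method != "kde_local_min":
            raise ValueError(
                "nanovial barcode distribution is not bimodal; supply an "
                "explicit gate threshold"
            )
        thresholds = values
    else:
        # explicit gates are interpreted on the raw count scale
        thresholds = counts
    above = thresholds > gate.threshold
    return [
        NanovialCall(
            label="on_nanovial" if a else "off_nanovial",
            barcode_count=int(c),
            gate=gate,
        )
        for a, c in zip(above, counts)
    ]
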