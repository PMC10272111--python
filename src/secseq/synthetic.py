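"""Ground-truth-labeled synthetic SEC-seq datasets.

Two fixtures are generated:

* the main antibody-secreting-cell (ASC) fixture — three donors of
  ex-vivo-differentiated B cells with mutually exclusive heavy-chain
  isotypes (IGHM / IGHA1 / one of IGHG1-4), one light chain per cell,
  a secretion feature barcode whose distribution in true IgG secretors is
  shifted a configurable number of log10 units above the IGHM/IGHA null,
  surrogate-marker genes whose expression mean rises with the latent
  secretion rate, and pseudotime with secretor probability increasing
  linearly over the terminal differentiation window;
* a two-species "barnyard" fixture (human/mouse with disjoint gene panels)
  with a controllable coincident-loading (doublet) rate and a nanovial
  feature barcode separating cells on nanovials from free-floating cells.

Counts are negative binomial per gene with a single shared dispersion; the
secretion barcode is drawn log-normally (``count = round(10^x) - 1`` with
``x`` Gaussian on the log10 scale). Every draw flows from one seeded
generator, so identical config + seed gives bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io_formats import (
    ANTIBODY_CAPTURE,
    FeatureCounts,
    GeneCountMatrix,
    write_cell_table,
    write_counts,
)

__all__ = ["GeneratorConfig", "generate_dataset", "generate_barnyard", "write_fixture"]

POPULATIONS = ("activated_B", "IGHM_ASC", "IGHA_ASC", "IgG_ASC")
IGG_SUBCLASSES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4")
HEAVY_GENES = ("IGHM", "IGHA1") + IGG_SUBCLASSES
LIGHT_GENES = ("IGKC", "IGLC2")
ACTIVATED_MARKERS = ("PAX5", "MS4A1", "CD19", "HLA-DRA", "HLA-DMA")
ASC_MARKERS = ("XBP1", "IRF4", "PRDM1", "MZB1")
SECRETION_MARKERS = ("CD38", "CD59", "MZB1", "XBP1", "SUB1")

# expression means (pre-depth, UMI counts) for the structural genes
_HEAVY_MEAN = 40.0
_LIGHT_MEAN = 40.0
_MARKER_ON = 8.0
_MARKER_OFF = 0.5
_SEC_MARKER_BASE = 6.0
_NANOVIAL_ON_MEAN = 200.0
_NANOVIAL_OFF_MEAN = 2.0


def _norm_weights(raw: Mapping[str, float], keys: Sequence[str], name: str) -> np.ndarray:
    missing = [k for k in keys if k not in raw]
    if missing:
        raise ValueError(f"{name} missing entries for {missing}")
    w = np.array([float(raw[k]) for k in keys])
    if (w < 0).any():
        raise ValueError(f"{name} has negative entries")
    s = w.sum()
    # printed percentages may carry rounding (e.g. summing to 100.1%); accept
    # and renormalize within 2%, reject anything further off
    if abs(s - 1.0) > 0.02:
        raise ValueError(f"{name} sums to {s}, not 1")
    return w / s


@dataclass
class GeneratorConfig:
    """Calibration of the main ASC fixture.

    Defaults encode the study conditions the analysis is built for: three
    donors, an IgG fraction of ~0.63 of all cells, the IgG subclass mixture
    76.5 / 8.2 / 12.7 / 2.7 % (IGHG1/2/3/4), a 1-log10 secretion-barcode
    shift for true secretors over the IGHM/IGHA null, and a secretor
    probability rising linearly from 10% at pseudotime 0.85 to 40% at 1.0.
    """

    n_cells: int = 6000
    n_donors: int = 3
    donor_sizes: list[int] | None = None
    timepoint_labels: list[str] = field(
        default_factory=lambda: ["day10", "day13", "day13"]
    )
    pop_weights: dict[str, float] = field(
        default_factory=lambda: {
            "activated_B": 0.161,
            "IGHM_ASC": 0.12,
            "IGHA_ASC": 0.09,
            "IgG_ASC": 0.629,
        }
    )
    igg_subclass_weights: dict[str, float] = field(
        default_factory=lambda: {
            "IGHG1": 0.765,
            "IGHG2": 0.082,
            "IGHG3": 0.127,
            "IGHG4": 0.027,
        }
    )
    secretor_fraction_range: tuple[float, float] = (0.10, 0.40)
    null_barcode_log_mean: float = 1.0
    null_barcode_log_sd: float = 0.35
    secretor_log_shift: float = 1.0
    n_marker_genes: int = 5
    marker_effect: float = 2.0
    n_background_genes: int = 200
    nb_dispersion: float = 2.0
    library_size_mean: int = 2000
    heavy_chain_leakage: float = 0.0
    light_violation_fraction: float = 0.0
    kappa_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_donors", "n_marker_genes",
                     "n_background_genes", "library_size_mean"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.donor_sizes is None:
            base, extra = divmod(self.n_cells, self.n_donors)
            self.donor_sizes = [base + (1 if d < extra else 0)
                                for d in range(self.n_donors)]
        if any(s < 0 for s in self.donor_sizes):
            raise ValueError("donor_sizes must be non-negative")
        if sum(self.donor_sizes) != self.n_cells:
            raise ValueError(
                f"donor_sizes sums to {sum(self.donor_sizes)}, expected {self.n_cells}"
            )
        if len(self.donor_sizes) != self.n_donors:
            raise ValueError("donor_sizes length must equal n_donors")
        self._pop_w = _norm_weights(self.pop_weights, POPULATIONS, "pop_weights")
        self._sub_w = _norm_weights(
            self.igg_subclass_weights, IGG_SUBCLASSES, "igg_subclass_weights"
        )
        f0, f1 = self.secretor_fraction_range
        if not (0 <= f0 <= 1 and 0 <= f1 <= 1):
            raise ValueError("secretor_fraction_range must lie in [0, 1]")
        if self.secretor_log_shift < 0:
            raise ValueError("secretor_log_shift must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.null_barcode_log_sd < 0 or self.heavy_chain_leakage < 0:
            raise ValueError("scale parameters must be non-negative")
        if not 0 <= self.light_violation_fraction <= 1:
            raise ValueError("light_violation_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "secretor_fraction_range" in raw:
            raw["secretor_fraction_range"] = tuple(raw["secretor_fraction_range"])
        return cls(**raw)


def _gene_panel(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    markers = list(SECRETION_MARKERS[: config.n_marker_genes])
    markers += [f"SECM{i:02d}" for i in range(len(markers), config.n_marker_genes)]
    structural = list(HEAVY_GENES) + list(LIGHT_GENES)
    named = list(dict.fromkeys(
        structural + list(ACTIVATED_MARKERS) + list(ASC_MARKERS) + markers
    ))
    background = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    return named + background, markers


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, size_r: float) -> np.ndarray:
    """Negative binomial draws with mean mu and shape (size) r; mu=0 -> 0."""
    mu = np.asarray(mu, float)
    p = size_r / (size_r + mu)
    return rng.negative_binomial(size_r, p)


def _sec_barcode_counts(rng: np.random.Generator, log_mean: np.ndarray,
                        log_sd: float) -> np.ndarray:
    x = rng.normal(log_mean, log_sd)
    return np.maximum(np.rint(10.0 ** x) - 1, 0).astype(np.int64)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[GeneCountMatrix, FeatureCounts, pd.DataFrame, pd.DataFrame]:
    """Generate the main ASC fixture.

    Returns ``(genes, features, cells, truth)`` where ``cells`` is the
    per-cell annotation table (barcode, donor, timepoint, cluster,
    pseudotime) and ``truth`` carries the generating labels
    (true_population, true_isotype, true_subclass, true_secretion_rate,
    true_secretor, true_pseudotime, true_light_chain).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    genes, marker_names = _gene_panel(config)
    g_index = {g: j for j, g in enumerate(genes)}

    donor = np.repeat(
        [f"donor{d + 1}" for d in range(config.n_donors)], config.donor_sizes
    )
    timepoint = np.repeat(
        [config.timepoint_labels[d % len(config.timepoint_labels)]
         for d in range(config.n_donors)],
        config.donor_sizes,
    )
    population = rng.choice(POPULATIONS, size=n, p=config._pop_w)
    is_asc = population != "activated_B"

    subclass = np.where(
        population == "IgG_ASC",
        rng.choice(IGG_SUBCLASSES, size=n, p=config._sub_w),
        "none",
    )
    isotype = np.select(
        [population == "IGHM_ASC", population == "IGHA_ASC",
         population == "IgG_ASC"],
        ["IGHM", "IGHA1", "IGHG"],
        default="IGHM",  # activated B cells carry unswitched IgM transcripts
    )
    light = np.where(rng.random(n) < config.kappa_fraction, "IGKC", "IGLC2")
    light_violation = rng.random(n) < config.light_violation_fraction

    # pseudotime: activated cells early, ASCs in the terminal window
    pseudotime = np.where(
        is_asc, rng.uniform(0.85, 1.0, size=n), rng.uniform(0.0, 0.2, size=n)
    )
    f0, f1 = config.secretor_fraction_range
    p_secretor = np.where(
        population == "IgG_ASC",
        np.clip(f0 + (f1 - f0) * (pseudotime - 0.85) / 0.15, 0.0, 1.0),
        0.0,
    )
    secretor = rng.random(n) < p_secretor
    # latent secretion rate: mean 1 among secretors so the median barcode
    # shift equals secretor_log_shift
    rate = np.where(secretor, rng.uniform(0.5, 1.5, size=n), 0.0)

    # per-cell, per-gene expression means
    mu = np.zeros((n, len(genes)))
    for hc, active in (
        ("IGHM", isotype == "IGHM"),
        ("IGHA1", isotype == "IGHA1"),
    ):
        mu[:, g_index[hc]] = np.where(active, _HEAVY_MEAN, config.heavy_chain_leakage)
    for sub in IGG_SUBCLASSES:
        mu[:, g_index[sub]] = np.where(
            subclass == sub, _HEAVY_MEAN, config.heavy_chain_leakage
        )
    for lc in LIGHT_GENES:
        mu[:, g_index[lc]] = np.where(
            (light == lc) | light_violation, _LIGHT_MEAN, 0.0
        )
    for gname in ACTIVATED_MARKERS:
        mu[:, g_index[gname]] = np.where(is_asc, _MARKER_OFF, _MARKER_ON)
    for gname in ASC_MARKERS:
        mu[:, g_index[gname]] = np.where(is_asc, _MARKER_ON, _MARKER_OFF)
    for gname in marker_names:
        base = mu[:, g_index[gname]]
        base = np.where(base > 0, base,
                        np.where(is_asc, _SEC_MARKER_BASE, _MARKER_OFF))
        mu[:, g_index[gname]] = base * (1.0 + config.marker_effect * rate)

    if config.n_background_genes:
        structural_budget = 250.0
        bg_rel = rng.lognormal(0.0, 1.0, size=config.n_background_genes)
        bg_total = max(config.library_size_mean - structural_budget, 50.0)
        bg_mu = bg_rel / bg_rel.sum() * bg_total
        mu[:, len(genes) - config.n_background_genes:] = bg_mu[None, :]

    counts = _nb_sample(rng, mu, config.nb_dispersion) if n else np.zeros(
        (0, len(genes)), dtype=np.int64
    )

    sec_log_mean = config.null_barcode_log_mean + config.secretor_log_shift * rate
    sec_counts = (
        _sec_barcode_counts(rng, sec_log_mean, config.null_barcode_log_sd)
        if n else np.zeros(0, dtype=np.int64)
    )
    nanovial_counts = rng.poisson(_NANOVIAL_ON_MEAN, size=n)

    barcodes = [f"BC{i:06d}-1" for i in range(n)]
    gene_m = GeneCountMatrix(
        counts=sp.csr_matrix(counts, shape=(n, len(genes))),
        cell_barcodes=barcodes,
        gene_symbols=genes,
    )
    feat_m = FeatureCounts(
        counts=sp.csr_matrix(np.column_stack([sec_counts, nanovial_counts])
                             if n else np.zeros((0, 2), dtype=np.int64)),
        cell_barcodes=barcodes,
        feature_names=["SEC-IgG", "Nanovial"],
        feature_types=[ANTIBODY_CAPTURE, ANTIBODY_CAPTURE],
    )
    cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "donor": donor,
            "timepoint": timepoint,
            "cluster": population,
            "pseudotime": pseudotime,
        }
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "true_population": population,
            "true_isotype": isotype,
            "true_subclass": subclass,
            "true_secretion_rate": rate,
            "true_secretor": secretor,
            "true_pseudotime": pseudotime,
            "true_light_chain": light,
            "true_light_violation": light_violation,
        }
    )
    return gene_m, feat_m, cells, truth


def generate_barnyard(
    n_human: int,
    n_mouse: int,
    doublet_rate: float,
    on_nanovial_fraction: float = 0.8,
    seed: int = 0,
    n_genes_per_species: int = 25,
    nb_dispersion: float = 2.0,
) -> tuple[GeneCountMatrix, FeatureCounts, pd.DataFrame, pd.DataFrame]:
    """Generate a two-species mixing fixture.

    The gene panel is the disjoint union of ``GRCh38_``- and ``mm10_``-
    prefixed genes. A doublet barcode sums the counts of one cell of each
    species (coincident loading). The nanovial feature barcode is high for
    cells on nanovials and background otherwise; the anti-IgG secretion
    barcode is high only for on-nanovial mouse (hybridoma) cells.
    """
    if n_human < 0 or n_mouse < 0:
        raise ValueError("cell counts must be non-negative")
    if not (0 <= doublet_rate <= 1 and 0 <= on_nanovial_fraction <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_human + n_mouse
    genes = [f"GRCh38_GENE{i:03d}" for i in range(n_genes_per_species)] + [
        f"mm10_GENE{i:03d}" for i in range(n_genes_per_species)
    ]
    per_species_mu = rng.lognormal(0.0, 0.8, size=(2, n_genes_per_species))
    per_species_mu *= 1500.0 / per_species_mu.sum(axis=1, keepdims=True)

    species = np.array(["human"] * n_human + ["mouse"] * n_mouse)
    doublet = rng.random(n) < doublet_rate
    on_vial = rng.random(n) < on_nanovial_fraction

    mu = np.zeros((n, len(genes)))
    human_cols = slice(0, n_genes_per_species)
    mouse_cols = slice(n_genes_per_species, 2 * n_genes_per_species)
    mu[species == "human", human_cols] = per_species_mu[0]
    mu[species == "mouse", mouse_cols] = per_species_mu[1]
    # coincident loading adds a full cell of the other species
    mu[doublet & (species == "human"), mouse_cols] += per_species_mu[1]
    mu[doublet & (species == "mouse"), human_cols] += per_species_mu[0]
    counts = _nb_sample(rng, mu, nb_dispersion) if n else np.zeros(
        (0, len(genes)), dtype=np.int64
    )

    nanovial_counts = rng.poisson(
        np.where(on_vial, _NANOVIAL_ON_MEAN, _NANOVIAL_OFF_MEAN)
    ) if n else np.zeros(0, dtype=np.int64)
    secretes = on_vial & (species == "mouse")
    sec_counts = _sec_barcode_counts(
        rng, np.where(secretes, 2.0, 0.7), 0.35
    ) if n else np.zeros(0, dtype=np.int64)

    barcodes = [f"BY{i:06d}-1" for i in range(n)]
    gene_m = GeneCountMatrix(
        counts=sp.csr_matrix(counts, shape=(n, len(genes))),
        cell_barcodes=barcodes,
        gene_symbols=genes,
    )
    feat_m = FeatureCounts(
        counts=sp.csr_matrix(np.column_stack([sec_counts, nanovial_counts])
                             if n else np.zeros((0, 2), dtype=np.int64)),
        cell_barcodes=barcodes,
        feature_names=["SEC-IgG", "Nanovial"],
        feature_types=[ANTIBODY_CAPTURE, ANTIBODY_CAPTURE],
    )
    cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "donor": "barnyard",
            "timepoint": "mix",
        }
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "true_species": species,
            "true_on_nanovial": on_vial,
            "true_doublet": doublet,
        }
    )
    return gene_m, feat_m, cells, truth


def write_fixture(
    gene_m: GeneCountMatrix,
    feat_m: FeatureCounts,
    cells: pd.DataFrame,
    truth: pd.DataFrame | None,
    dir_path: str | Path,
) -> None:
    """Write a generated fixture in the on-disk layout the readers consume."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    write_counts(gene_m, feat_m, dir_path)
    write_cell_table(cells, dir_path / "cells.tsv")
    if truth is not None:
        write_cell_table(truth, dir_path / "truth.tsv")
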