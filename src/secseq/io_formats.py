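"""CellRanger-style sparse matrix I/O and per-cell metadata tables.

On disk the layout mirrors a CellRanger ``filtered_feature_bc_matrix``
directory: ``matrix.mtx[.gz]`` (MatrixMarket coordinate integer, features x
cells, 1-based), ``features.tsv[.gz]`` (id, name, type; no header),
``barcodes.tsv[.gz]`` (one barcode per line). In memory, matrices are
cells x genes / cells x features CSR with 0-based indices. Rows whose feature
type is "Gene Expression" populate the :class:`GeneCountMatrix`; every other
feature type (e.g. "Antibody Capture") is routed to :class:`FeatureCounts`.

The per-cell annotation table ("CellTable") is a plain pandas DataFrame with
a ``barcode`` column plus ``donor``, ``timepoint`` and optional ``cluster`` /
``pseudotime`` columns; downstream stages append their call columns
(``isotype_call``, ``subclass_call``, ``sec_class``, ...).
"""
from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import load_config  # re-exported: part of this module's surface

__all__ = [
    "GeneCountMatrix",
    "FeatureCounts",
    "read_counts",
    "write_counts",
    "read_cell_table",
    "write_cell_table",
    "load_config",
]

GENE_EXPRESSION = "Gene Expression"
ANTIBODY_CAPTURE = "Antibody Capture"


@dataclass
class GeneCountMatrix:
    """Cells x genes UMI counts with cell barcodes and gene symbols."""

    counts: sp.csr_matrix
    cell_barcodes: list[str]
    gene_symbols: list[str]
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_barcodes):
            raise ValueError(
                f"{n_cells} matrix rows vs {len(self.cell_barcodes)} barcodes"
            )
        if n_genes != len(self.gene_symbols):
            raise ValueError(
                f"{n_genes} matrix columns vs {len(self.gene_symbols)} gene symbols"
            )
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise ValueError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_symbols.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in panel") from None

    def gene_counts(self, symbol: str) -> np.ndarray:
        """Dense per-cell count vector for one gene symbol."""
        return np.asarray(
            self.counts[:, self.gene_index(symbol)].todense()
        ).ravel()

    def subset_cells(self, index: np.ndarray) -> "GeneCountMatrix":
        index = np.asarray(index)
        return GeneCountMatrix(
            counts=self.counts[index],
            cell_barcodes=[self.cell_barcodes[i] for i in index],
            gene_symbols=list(self.gene_symbols),
            gene_ids=list(self.gene_ids) if self.gene_ids is not None else None,
        )


@dataclass
class FeatureCounts:
    """Cells x capture-features counts (antibody/feature barcodes).

    The cell axis (barcodes and order) is identical to the paired
    :class:`GeneCountMatrix`.
    """

    counts: sp.csr_matrix
    cell_barcodes: list[str]
    feature_names: list[str]
    feature_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if not self.feature_types:
            self.feature_types = [ANTIBODY_CAPTURE] * len(self.feature_names)
        n_cells, n_feat = self.counts.shape
        if n_cells != len(self.cell_barcodes):
            raise ValueError("cell axis mismatch")
        if n_feat != len(self.feature_names) or n_feat != len(self.feature_types):
            raise ValueError("feature axis mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def feature_vector(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not present") from None
        return np.asarray(self.counts[:, j].todense()).ravel()

    def subset_cells(self, index: np.ndarray) -> "FeatureCounts":
        index = np.asarray(index)
        return FeatureCounts(
            counts=self.counts[index],
            cell_barcodes=[self.cell_barcodes[i] for i in index],
            feature_names=list(self.feature_names),
            feature_types=list(self.feature_types),
        )


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dir_path}")


def _read_tsv_lines(path: Path) -> list[list[str]]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def read_counts(dir_path: str | Path) -> tuple[GeneCountMatrix, FeatureCounts]:
    """Read a CellRanger-style matrix directory.

    Returns the gene-expression matrix and the capture-feature matrix, both
    on the same cell axis. Dimension mismatches between the MTX header and
    the TSV files raise a ``ValueError`` naming the offending file.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    barcodes_path = _find(dir_path, "barcodes.tsv")
    features_path = _find(dir_path, "features.tsv")

    mat = sp.csc_matrix(scipy.io.mmread(str(mtx_path)))  # features x cells
    barcodes = [row[0] for row in _read_tsv_lines(barcodes_path)]
    feat_rows = _read_tsv_lines(features_path)

    if mat.shape[0] != len(feat_rows):
        raise ValueError(
            f"{features_path.name}: {len(feat_rows)} rows but matrix.mtx "
            f"header declares {mat.shape[0]} features"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"{barcodes_path.name}: {len(barcodes)} barcodes but matrix.mtx "
            f"header declares {mat.shape[1]} cells"
        )

    ids = [r[0] for r in feat_rows]
    names = [r[1] if len(r) > 1 else r[0] for r in feat_rows]
    types = [r[2] if len(r) > 2 else GENE_EXPRESSION for r in feat_rows]

    known = {GENE_EXPRESSION, ANTIBODY_CAPTURE}
    for t in sorted(set(types) - known):
        warnings.warn(
            f"unknown feature type {t!r}; routed to FeatureCounts", stacklevel=2
        )

    is_gene = np.array([t == GENE_EXPRESSION for t in types])
    cells_by_feat = sp.csr_matrix(mat.T)  # cells x features
    gene_m = GeneCountMatrix(
        counts=cells_by_feat[:, np.flatnonzero(is_gene)],
        cell_barcodes=barcodes,
        gene_symbols=[n for n, g in zip(names, is_gene) if g],
        gene_ids=[i for i, g in zip(ids, is_gene) if g],
    )
    feat_m = FeatureCounts(
        counts=cells_by_feat[:, np.flatnonzero(~is_gene)],
        cell_barcodes=barcodes,
        feature_names=[n for n, g in zip(names, is_gene) if not g],
        feature_types=[t for t, g in zip(types, is_gene) if not g],
    )
    return gene_m, feat_m


def write_counts(
    matrix: GeneCountMatrix,
    features: FeatureCounts | None,
    dir_path: str | Path,
    compress: bool = False,
) -> None:
    """Write a CellRanger-style matrix directory (MTX + TSVs).

    Gene-expression rows come first, capture features after, matching
    CellRanger's concatenated layout. Indices on disk are 1-based.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)

    blocks = [sp.csc_matrix(matrix.counts.T)]
    ids = list(matrix.gene_ids or matrix.gene_symbols)
    names = list(matrix.gene_symbols)
    types = [GENE_EXPRESSION] * matrix.n_genes
    if features is not None:
        if features.cell_barcodes != matrix.cell_barcodes:
            raise ValueError("FeatureCounts cell axis differs from GeneCountMatrix")
        blocks.append(sp.csc_matrix(features.counts.T))
        ids += list(features.feature_names)
        names += list(features.feature_names)
        types += list(features.feature_types)
    stacked = sp.vstack(blocks).astype(np.int64)  # features x cells

    suffix = ".gz" if compress else ""
    mtx_path = dir_path / f"matrix.mtx{suffix}"
    if compress:
        with gzip.open(mtx_path, "wb") as fh:
            scipy.io.mmwrite(fh, sp.coo_matrix(stacked), field="integer")
    else:
        scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(stacked),
                         field="integer")

    def _write_lines(stem: str, lines: list[str]) -> None:
        path = dir_path / f"{stem}{suffix}"
        data = ("\n".join(lines) + "\n") if lines else ""
        if compress:
            with gzip.open(path, "wt") as fh:
                fh.write(data)
        else:
            path.write_text(data)

    _write_lines("barcodes.tsv", list(matrix.cell_barcodes))
    _write_lines(
        "features.tsv",
        ["\t".join(row) for row in zip(ids, names, types)],
    )


def read_cell_table(path: str | Path, barcodes: list[str] | None = None) -> pd.DataFrame:
    """Read a per-cell annotation TSV (header required).

    When ``barcodes`` is given and the table has a ``barcode`` column, rows
    are aligned to that barcode order (join by barcode string, not position).
    """
    table = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    if "pseudotime" in table.columns:
        pt = table["pseudotime"].dropna()
        if len(pt) and ((pt < 0).any() or (pt > 1).any()):
            raise ValueError("pseudotime outside [0, 1]")
    if barcodes is not None:
        if "barcode" not in table.columns:
            if len(table) != len(barcodes):
                raise ValueError(
                    "cell table has no barcode column and row count differs "
                    "from the matrix cell axis"
                )
            table = table.copy()
            table.insert(0, "barcode", barcodes)
        else:
            table = (
                table.set_index("barcode").reindex(barcodes).reset_index()
            )
    return table


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
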