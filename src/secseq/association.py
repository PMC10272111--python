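"""Surrogate-marker discovery and SEC-hi vs SEC-lo differential expression.

Marker discovery correlates each gene's normalized log expression with the
log-transformed secretion barcode, per donor (Pearson r, two-tailed t-test
p). A gene is a cross-donor consensus marker when its correlation clears
``r_min`` in the requested direction in *every* donor; candidates are ranked
by the mean r across donors.

Differential expression between SEC-hi and SEC-lo cells uses the Wilcoxon
rank-sum test with Benjamini-Hochberg adjustment; the reported fold change
is the difference of group means on the normalized log scale.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .preprocess import NormalizedMatrix

__all__ = [
    "gene_secretion_correlation",
    "consensus_markers",
    "subgroup_zscore_table",
    "rank_sum_de",
    "bh_adjust",
]


def gene_secretion_correlation(
    norm: NormalizedMatrix,
    sec_values: Sequence[float],
    cell_subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with the secretion barcode.

    p-values come from the t statistic ``r * sqrt((n-2) / (1-r^2))`` against
    Student's t with n-2 degrees of freedom, two-tailed. Genes with zero
    variance in the subset get r=0, p=1 and are flagged.
    """
    sec = np.asarray(sec_values, dtype=float)
    if sec.shape[0] != norm.n_cells:
        raise ValueError("sec_values not aligned to the cell axis")
    if cell_subset is not None:
        cell_subset = np.asarray(cell_subset)
        X = norm.values[cell_subset]
        sec = sec[cell_subset]
    else:
        X = norm.values
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 cells, got {n}")

    y = sec - sec.mean()
    y_ss = float(y @ y)
    x_mean = np.asarray(X.mean(axis=0)).ravel()
    x_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    x_var = np.maximum(x_sq - x_mean**2, 0.0) * n  # sum of squares about mean
    xy = np.asarray(X.T @ y).ravel()  # equals sum((x - xbar) * (y - ybar))

    denom = np.sqrt(x_var * y_ss)
    zero_var = (x_var <= 1e-12 * n) | (y_ss <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(zero_var, 0.0, xy / np.where(denom == 0, 1.0, denom))
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = np.where(
        np.isfinite(t), 2.0 * st.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)),
                                      df=n - 2), 0.0
    )
    p = np.where(zero_var, 1.0, p)
    r = np.where(zero_var, 0.0, r)
    return pd.DataFrame(
        {
            "gene": norm.gene_symbols,
            "r": r,
            "p": p,
            "n": n,
            "zero_variance": zero_var,
        }
    )


def consensus_markers(
    tables: Mapping[str, pd.DataFrame],
    r_min: float = 0.10,
    direction: str = "positive",
    top_k: int = 40,
) -> pd.DataFrame:
    """Cross-donor consensus correlation table ranked by mean r.

    ``tables`` maps donor name to the per-donor output of
    :func:`gene_secretion_correlation`. ``consensus`` is true iff the
    directional criterion (r >= r_min, or r <= -r_min for ``negative``)
    holds in every donor. Output is sorted by mean r, descending for
    positive search and ascending for negative; ``top_k`` only annotates
    the rank cutoff, all genes are returned.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    donors = sorted(tables)
    if not donors:
        raise ValueError("no donor tables supplied")
    panels = {d: list(tables[d]["gene"]) for d in donors}
    ref = panels[donors[0]]
    mismatched = [d for d in donors if panels[d] != ref]
    if mismatched:
        raise ValueError(
            f"gene panels differ between donors {donors[0]} and {mismatched}"
        )

    r_mat = np.column_stack([tables[d]["r"].to_numpy() for d in donors])
    p_mat = np.column_stack([tables[d]["p"].to_numpy() for d in donors])
    mean_r = r_mat.mean(axis=1)
    if direction == "positive":
        consensus = (r_mat >= r_min).all(axis=1)
    else:
        consensus = (r_mat <= -r_min).all(axis=1)

    out = pd.DataFrame({"gene": ref})
    for j, d in enumerate(donors):
        out[f"r_{d}"] = r_mat[:, j]
    for j, d in enumerate(donors):
        out[f"p_{d}"] = p_mat[:, j]
    out["mean_r"] = mean_r
    out["consensus"] = consensus
    out["n_cells_per_donor"] = [
        tuple(int(tables[d]["n"].iloc[0]) for d in donors)
    ] * len(ref)
    ascending = direction == "negative"
    out = out.sort_values(
        ["mean_r", "gene"], ascending=[ascending, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["top_k"] = out["rank"] <= top_k
    return out


def subgroup_zscore_table(
    norm: NormalizedMatrix,
    cells: pd.DataFrame,
    genes: Sequence[str],
    group_col: str = "sec_class",
    donor_col: str = "donor",
    groups: Sequence[str] = ("sec_lo", "sec_hi"),
) -> pd.DataFrame:
    """Heatmap-ready mean z-score per gene per (donor, SEC group).

    z-scores are computed per gene across *all* of a donor's cells
    (population standard deviation), then averaged within each SEC group.
    Genes constant within a donor have undefined z and are reported NaN;
    empty groups are NaN, not 0.
    """
    if len(cells) != norm.n_cells:
        raise ValueError("cell table not aligned to the matrix")
    cols = [norm.gene_symbols.index(g) for g in genes]
    X = np.asarray(norm.values[:, cols].todense())
    records = {}
    for donor in sorted(cells[donor_col].unique()):
        d_mask = (cells[donor_col] == donor).to_numpy()
        Xd = X[d_mask]
        mean = Xd.mean(axis=0)
        sd = Xd.std(axis=0)  # population sd
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = (Xd - mean) / sd
        Z[:, sd == 0] = np.nan  # constant gene: z undefined, excluded
        glab = cells.loc[d_mask, group_col].to_numpy()
        for grp in groups:
            g_mask = glab == grp
            col = (donor, grp)
            records[col] = (
                Z[g_mask].mean(axis=0) if g_mask.any()
                else np.full(len(genes), np.nan)
            )
    out = pd.DataFrame(records, index=list(genes))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["donor", "group"])
    return out


def _ranksum_z(hi: np.ndarray, lo: np.ndarray) -> float:
    """Tie-corrected normal z for the Wilcoxon rank-sum statistic of ``hi``."""
    n1, n2 = len(hi), len(lo)
    pooled = np.concatenate([hi, lo])
    ranks = st.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    return float((w - mu) / np.sqrt(var))


def rank_sum_de(
    norm: NormalizedMatrix,
    cells_hi: np.ndarray,
    cells_lo: np.ndarray,
    fdr_alpha: float = 0.10,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression, SEC-hi vs SEC-lo.

    Per gene: two-sided rank-sum p (exact enumeration when both groups are
    small and tie-free, tie-corrected normal approximation otherwise), BH
    adjustment across the tested genes, and the difference of group means
    on the normalized log scale as the fold change. Sorted by q then by
    descending z so the head of the table is the SEC-hi signature.
    """
    hi_idx = np.asarray(cells_hi)
    lo_idx = np.asarray(cells_lo)
    if hi_idx.size < 3 or lo_idx.size < 3:
        raise ValueError("both groups need at least 3 cells")
    Xh = np.asarray(norm.values[hi_idx].todense())
    Xl = np.asarray(norm.values[lo_idx].todense())
    n_genes = Xh.shape[1]
    stats = np.zeros(n_genes)
    pvals = np.ones(n_genes)
    small = hi_idx.size <= 8 and lo_idx.size <= 8
    for g in range(n_genes):
        hi, lo = Xh[:, g], Xl[:, g]
        pooled = np.concatenate([hi, lo])
        if np.ptp(pooled) == 0:
            stats[g], pvals[g] = 0.0, 1.0
            continue
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (small and no_ties) else "asymptotic"
        res = st.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
        stats[g] = _ranksum_z(hi, lo)
        pvals[g] = float(res.pvalue)
    qvals = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "gene": norm.gene_symbols,
            "statistic": stats,
            "p": pvals,
            "q": qvals,
            "mean_hi": Xh.mean(axis=0),
            "mean_lo": Xl.mean(axis=0),
        }
    )
    out["log_fold_change"] = out["mean_hi"] - out["mean_lo"]
    out["significant"] = out["q"] < fdr_alpha
    return out.sort_values(
        ["q", "statistic"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return st.false_discovery_control(p, method="bh")
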