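import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from secseq.association import (
    bh_adjust,
    consensus_markers,
    gene_secretion_correlation,
    rank_sum_de,
    subgroup_zscore_table,
)
from secseq.preprocess import NormalizedMatrix


def _norm_from_dense(values):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        cell_barcodes=[f"BC{i}" for i in range(values.shape[0])],
        gene_symbols=[f"G{j}" for j in range(values.shape[1])],
        target_sum=1e4,
        zero_total=np.zeros(values.shape[0], dtype=bool),
    )


class TestCorrelation:
    def test_perfect_positive(self):
        norm = _norm_from_dense([[1], [2], [3]])
        out = gene_secretion_correlation(norm, [2, 4, 6])
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        norm = _norm_from_dense([[1], [2], [3]])
        out = gene_secretion_correlation(norm, [6, 4, 2])
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        # cov/sd arithmetic by hand: r([1,3,2,4], [1,2,3,4]) = 0.8
        norm = _norm_from_dense([[1], [3], [2], [4]])
        out = gene_secretion_correlation(norm, [1, 2, 3, 4])
        assert out["r"].iloc[0] == pytest.approx(0.8)

    def test_p_matches_scipy_pearsonr(self, rng):
        from scipy.stats import pearsonr

        x = rng.normal(0, 1, (40, 3))
        y = rng.normal(0, 1, 40)
        out = gene_secretion_correlation(_norm_from_dense(x), y)
        for j in range(3):
            r_ref, p_ref = pearsonr(x[:, j], y)
            assert out["r"].iloc[j] == pytest.approx(r_ref)
            assert out["p"].iloc[j] == pytest.approx(p_ref, rel=1e-9)

    def test_zero_variance_flagged(self):
        norm = _norm_from_dense([[5, 1], [5, 2], [5, 3]])
        out = gene_secretion_correlation(norm, [1, 2, 3])
        assert out["zero_variance"].iloc[0]
        assert out["r"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, (30, 2))
        y = rng.normal(0, 1, 30)
        base = gene_secretion_correlation(_norm_from_dense(x), y)["r"]
        scaled = gene_secretion_correlation(_norm_from_dense(3 * x + 2), y)["r"]
        flipped = gene_secretion_correlation(_norm_from_dense(-x), y)["r"]
        np.testing.assert_allclose(scaled, base, atol=1e-12)
        np.testing.assert_allclose(flipped, -base, atol=1e-12)

    def test_subset_too_small(self):
        norm = _norm_from_dense(np.ones((5, 1)))
        with pytest.raises(ValueError):
            gene_secretion_correlation(norm, np.arange(5), cell_subset=[0, 1])


class TestConsensus:
    def _tables(self, r_by_donor):
        tables = {}
        genes = [f"G{j}" for j in range(len(next(iter(r_by_donor.values()))))]
        for donor, rs in r_by_donor.items():
            tables[donor] = pd.DataFrame(
                {"gene": genes, "r": rs, "p": 0.5, "n": 100}
            )
        return tables

    def test_all_donors_above_threshold(self):
        tables = self._tables({"d1": [0.3], "d2": [0.2], "d3": [0.15]})
        out = consensus_markers(tables, r_min=0.1)
        assert out["consensus"].iloc[0]
        assert out["mean_r"].iloc[0] == pytest.approx(np.mean([0.3, 0.2, 0.15]))

    def test_one_donor_below_threshold(self):
        tables = self._tables({"d1": [0.3], "d2": [0.05], "d3": [0.4]})
        out = consensus_markers(tables, r_min=0.1)
        assert not out["consensus"].iloc[0]

    def test_negative_direction(self):
        tables = self._tables({"d1": [-0.3], "d2": [-0.2], "d3": [-0.15]})
        out = consensus_markers(tables, r_min=0.1, direction="negative")
        assert out["consensus"].iloc[0]

    def test_donor_order_invariance(self):
        rs = {"d1": [0.3, 0.0], "d2": [0.2, 0.1], "d3": [0.25, -0.2]}
        a = consensus_markers(self._tables(rs), r_min=0.1)
        b = consensus_markers(
            self._tables({k: rs[k] for k in ["d3", "d1", "d2"]}), r_min=0.1
        )
        pd.testing.assert_frame_equal(a, b)

    def test_panel_mismatch_rejected(self):
        tables = self._tables({"d1": [0.3], "d2": [0.2]})
        tables["d2"] = tables["d2"].assign(gene=["OTHER"])
        with pytest.raises(ValueError, match="panels differ"):
            consensus_markers(tables)


class TestZScore:
    def test_two_cell_hand_example(self):
        # values (1, 3): mean 2, population sd 1 -> z = (-1, +1)
        norm = _norm_from_dense([[1.0], [3.0]])
        cells = pd.DataFrame({"donor": ["d", "d"], "sec_class": ["sec_lo",
                                                                 "sec_hi"]})
        out = subgroup_zscore_table(norm, cells, ["G0"])
        assert out.loc["G0", ("d", "sec_lo")] == pytest.approx(-1.0)
        assert out.loc["G0", ("d", "sec_hi")] == pytest.approx(+1.0)

    def test_zero_mean_unit_sd_before_grouping(self, rng):
        vals = rng.normal(2, 3, (50, 2))
        cells = pd.DataFrame(
            {"donor": ["d"] * 50,
             "sec_class": rng.choice(["sec_lo", "sec_hi"], 50)}
        )
        out = subgroup_zscore_table(_norm_from_dense(vals), cells, ["G0", "G1"])
        for g in ("G0", "G1"):
            col = vals[:, int(g[1])]
            z = (col - col.mean()) / col.std()
            for grp in ("sec_lo", "sec_hi"):
                mask = (cells["sec_class"] == grp).to_numpy()
                assert out.loc[g, ("d", grp)] == pytest.approx(z[mask].mean())

    def test_constant_gene_is_nan(self):
        norm = _norm_from_dense([[5.0], [5.0], [5.0]])
        cells = pd.DataFrame({"donor": ["d"] * 3,
                              "sec_class": ["sec_lo", "sec_hi", "sec_hi"]})
        out = subgroup_zscore_table(norm, cells, ["G0"])
        assert out.isna().all().all()

    def test_empty_group_missing_not_zero(self):
        norm = _norm_from_dense([[1.0], [2.0]])
        cells = pd.DataFrame({"donor": ["d", "d"],
                              "sec_class": ["sec_hi", "sec_hi"]})
        out = subgroup_zscore_table(norm, cells, ["G0"])
        assert np.isnan(out.loc["G0", ("d", "sec_lo")])

    def test_cell_order_permutation_invariant(self, rng):
        vals = rng.normal(0, 1, (30, 2))
        cells = pd.DataFrame(
            {"donor": rng.choice(["d1", "d2"], 30),
             "sec_class": rng.choice(["sec_lo", "sec_hi"], 30)}
        )
        perm = rng.permutation(30)
        a = subgroup_zscore_table(_norm_from_dense(vals), cells, ["G0", "G1"])
        b = subgroup_zscore_table(
            _norm_from_dense(vals[perm]),
            cells.iloc[perm].reset_index(drop=True), ["G0", "G1"]
        )
        pd.testing.assert_frame_equal(a, b)


def _exact_ranksum_p(hi, lo):
    """Exhaustive permutation null of the rank-sum statistic (two-sided)."""
    pooled = np.concatenate([hi, lo])
    n1 = len(hi)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n1].sum()
    center = n1 * (len(pooled) + 1) / 2
    stats = [
        ranks[list(comb)].sum()
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    stats = np.asarray(stats)
    return float(np.mean(np.abs(stats - center) >= abs(observed - center) - 1e-12))


class TestRankSumDE:
    def test_identical_groups_null(self):
        vals = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        out = rank_sum_de(_norm_from_dense(vals), [0, 1, 2], [3, 4, 5])
        assert out["statistic"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        vals = np.array([[5.0], [6.0], [7.0], [1.0], [2.0], [3.0]])
        out = rank_sum_de(_norm_from_dense(vals), [0, 1, 2], [3, 4, 5])
        # 20 equally likely 3-of-6 splits; only the 2 extremes are as extreme
        assert out["p"].iloc[0] == pytest.approx(0.1)
        assert out["log_fold_change"].iloc[0] == pytest.approx(4.0)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6)])
    def test_matches_exhaustive_enumeration(self, rng, n1, n2):
        vals = rng.normal(0, 1, (n1 + n2, 4))
        out = rank_sum_de(_norm_from_dense(vals), np.arange(n1),
                          np.arange(n1, n1 + n2))
        out = out.set_index("gene")
        for j in range(4):
            expected = _exact_ranksum_p(vals[:n1, j], vals[n1:, j])
            assert out.loc[f"G{j}", "p"] == pytest.approx(expected, abs=1e-10)

    def test_group_too_small(self):
        vals = np.zeros((4, 1))
        with pytest.raises(ValueError):
            rank_sum_de(_norm_from_dense(vals), [0, 1], [2, 3])


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_equal_pair(self):
        np.testing.assert_allclose(bh_adjust([0.5, 0.5]), [0.5, 0.5])

    def test_hand_step_up_four(self):
        # sorted (0.005, 0.01, 0.03, 0.04) -> (0.02, 0.02, 0.04, 0.04)
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_uniform_spacing_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_q_at_least_p_and_bounded(self, rng):
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def test_null_correlation_type_i_control():
    """With marker_effect = 0 the background genes are independent of the
    barcode; the fraction with p < 0.05 stays near 0.05."""
    from secseq.preprocess import normalize_log
    from secseq.secretion import transform_barcode
    from secseq.synthetic import GeneratorConfig, generate_dataset

    fracs = []
    for seed in (101, 102, 103):
        cfg = GeneratorConfig(
            n_cells=1500, seed=seed, marker_effect=0.0,
            n_background_genes=500,
            pop_weights={"activated_B": 0, "IGHM_ASC": 0, "IGHA_ASC": 0,
                         "IgG_ASC": 1.0},
        )
        genes, feats, _, _ = generate_dataset(cfg)
        norm = normalize_log(genes)
        vals = transform_barcode(feats.feature_vector("SEC-IgG"))
        out = gene_secretion_correlation(norm, vals)
        bg = out[out["gene"].str.startswith("BG")]
        fracs.append((bg["p"] < 0.05).mean())
    assert abs(np.mean(fracs) - 0.05) < 0.02
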