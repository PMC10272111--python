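import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from secseq.secretion import (
    SecretionThresholds,
    classify_secretion,
    compute_sec_thresholds,
    group_secretion_composition,
    pseudotime_secretor_profile,
    transform_barcode,
)
from secseq.synthetic import GeneratorConfig, generate_dataset


class TestTransform:
    def test_values(self):
        assert transform_barcode(0) == 0.0
        assert transform_barcode(9) == pytest.approx(1.0)
        np.testing.assert_allclose(transform_barcode([0, 9, 99]), [0, 1, 2])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_barcode([-1])

    def test_monotone(self, rng):
        x = np.sort(rng.integers(0, 1000, 50))
        assert (np.diff(transform_barcode(x)) >= 0).all()


class TestThresholds:
    def test_hand_example_nearest_rank(self):
        thr = compute_sec_thresholds(np.arange(1, 11), quantile=0.9,
                                     min_null_cells=1)
        assert thr.t_hi == 9  # ceil(0.9 * 10) = 9th order statistic
        assert thr.null_mean == pytest.approx(5.5)
        assert thr.t_lo == pytest.approx(2.0)

    def test_degenerate_constant_null(self):
        thr = compute_sec_thresholds(np.full(60, 3.0), quantile=0.9)
        assert thr.t_hi == thr.t_lo == thr.null_mean == 3.0

    def test_symmetric_null_symmetric_cutoffs(self, rng):
        x = rng.normal(5, 1, 4001)
        x = np.concatenate([x, 10 - x])  # exactly symmetric about 5
        thr = compute_sec_thresholds(x, quantile=0.9)
        assert thr.t_hi - thr.null_mean == pytest.approx(
            thr.null_mean - thr.t_lo, abs=1e-12
        )
        below = (x < thr.t_lo).mean()
        above = (x > thr.t_hi).mean()
        assert abs(below - above) < 0.01

    def test_too_few_null_cells_rejected(self):
        with pytest.raises(ValueError, match="explicit"):
            compute_sec_thresholds(np.arange(10), quantile=0.9,
                                   min_null_cells=50)

    def test_quantile_range_enforced(self):
        with pytest.raises(ValueError):
            compute_sec_thresholds(np.arange(100), quantile=0.4)

    def test_symmetry_holds_for_random_samples(self, rng):
        """t_hi + t_lo == 2 * null_mean to machine precision, any input."""
        for _ in range(100):
            x = rng.lognormal(0, rng.uniform(0.1, 2), rng.integers(50, 500))
            thr = compute_sec_thresholds(x, quantile=rng.uniform(0.55, 0.99))
            assert thr.t_hi + thr.t_lo == pytest.approx(2 * thr.null_mean,
                                                        abs=1e-12)

    def test_calibration_nearest_rank_exact(self, rng):
        """Fraction of null values at or below t_hi is exactly ceil(q*n)/n
        for tie-free samples."""
        for n in (53, 200, 1111):
            x = rng.normal(0, 1, n)
            thr = compute_sec_thresholds(x, quantile=0.9, min_null_cells=1)
            frac = (x <= thr.t_hi).mean()
            assert frac == pytest.approx(np.ceil(0.9 * n) / n, abs=1e-12)

    def test_mirror_invariant_enforced(self):
        with pytest.raises(ValueError):
            SecretionThresholds(t_hi=3.0, t_lo=0.0, null_mean=1.0, null_n=100)


class TestClassify:
    THR = SecretionThresholds(t_hi=9.0, t_lo=2.0, null_mean=5.5, null_n=10)

    @pytest.mark.parametrize("value,label", [
        (9.5, "sec_hi"),
        (1.5, "sec_lo"),
        (5.0, "sec_mid"),
        (9.0, "sec_mid"),  # boundary: "above" is strict
        (2.0, "sec_mid"),
    ])
    def test_rules(self, value, label):
        assert classify_secretion(value, self.THR) == label

    def test_monotone_response(self, rng):
        """Raising every IgG cell's barcode never lowers the hi fraction."""
        vals = rng.uniform(0, 10, 500)
        base = (classify_secretion(vals, self.THR) == "sec_hi").mean()
        raised = (classify_secretion(vals + 1.0, self.THR) == "sec_hi").mean()
        assert raised >= base


class TestComposition:
    def test_hand_tally(self):
        cells = pd.DataFrame(
            {"cluster": ["a"] * 4,
             "sec_class": ["sec_hi", "sec_hi", "sec_lo", "sec_mid"]}
        )
        comp = group_secretion_composition(cells, "cluster")
        row = comp.iloc[0]
        assert (row["pct_hi"], row["pct_lo"], row["pct_mid"]) == (50, 25, 25)

    def test_single_cell_group(self):
        cells = pd.DataFrame({"cluster": ["x"], "sec_class": ["sec_lo"]})
        comp = group_secretion_composition(cells, "cluster")
        assert comp.iloc[0]["pct_lo"] == 100

    def test_matches_brute_force(self, rng):
        cells = pd.DataFrame(
            {"donor": rng.choice(["d1", "d2", "d3"], 300),
             "sec_class": rng.choice(["sec_hi", "sec_lo", "sec_mid"], 300)}
        )
        comp = group_secretion_composition(cells, "donor").set_index("group")
        for donor, sub in cells.groupby("donor"):
            for lab in ("hi", "lo", "mid"):
                expected = 100 * (sub["sec_class"] == f"sec_{lab}").mean()
                assert comp.loc[donor, f"pct_{lab}"] == pytest.approx(expected)
        sums = comp[["pct_hi", "pct_lo", "pct_mid"]].sum(axis=1)
        np.testing.assert_allclose(sums, 100, atol=1e-9)

    def test_unknown_group_key(self):
        cells = pd.DataFrame({"sec_class": ["sec_hi"]})
        with pytest.raises(ValueError, match="group key"):
            group_secretion_composition(cells, "nope")


class TestPseudotimeProfile:
    def test_two_cell_bin(self):
        cells = pd.DataFrame(
            {"donor": ["d", "d"], "pseudotime": [0.86, 0.87],
             "sec_class": ["sec_hi", "sec_lo"]}
        )
        prof = pseudotime_secretor_profile(cells, min_bin_cells=1)
        row = prof[np.isclose(prof["bin_lo"], 0.85) & (prof["n"] > 0)].iloc[0]
        assert row["n"] == 2
        assert row["frac_hi"] == pytest.approx(0.5)

    def test_boundary_one_goes_to_final_bin(self):
        cells = pd.DataFrame(
            {"donor": ["d"], "pseudotime": [1.0], "sec_class": ["sec_hi"]}
        )
        prof = pseudotime_secretor_profile(cells, min_bin_cells=1)
        final = prof.iloc[-1]
        assert final["bin_hi"] == 1.0 and final["n"] == 1

    def test_small_bins_reported_missing_not_zero(self):
        cells = pd.DataFrame(
            {"donor": ["d"] * 5, "pseudotime": [0.1] * 5,
             "sec_class": ["sec_hi"] * 5}
        )
        prof = pseudotime_secretor_profile(cells, min_bin_cells=10)
        assert prof["frac_hi"].isna().all()

    def test_missing_pseudotime_instructive_error(self):
        cells = pd.DataFrame({"donor": ["d"], "sec_class": ["sec_hi"]})
        with pytest.raises(ValueError, match="upstream"):
            pseudotime_secretor_profile(cells)

    def test_linear_ramp_gives_monotone_profile(self):
        """With the generator's linear secretor ramp the per-bin SEC-hi
        fractions rise monotonically (Spearman >= 0.8) among IgG cells."""
        cfg = GeneratorConfig(
            n_cells=4000, seed=31,
            pop_weights={"activated_B": 0, "IGHM_ASC": 0, "IGHA_ASC": 0,
                         "IgG_ASC": 1.0},
        )
        genes, feats, cells, truth = generate_dataset(cfg)
        vals = transform_barcode(feats.feature_vector("SEC-IgG"))
        null = np.random.default_rng(31).normal(
            cfg.null_barcode_log_mean, cfg.null_barcode_log_sd, 2000
        )
        thr = compute_sec_thresholds(null, quantile=0.9)
        cells = cells.assign(sec_class=classify_secretion(vals, thr))
        prof = pseudotime_secretor_profile(cells, per=None, min_bin_cells=10)
        ok = prof["frac_hi"].notna()
        rho, _ = st.spearmanr(prof.loc[ok, "bin_mid"], prof.loc[ok, "frac_hi"])
        assert ok.sum() >= 3
        assert rho >= 0.8


def test_separation_recovery_high_secretor_cohort():
    """When most IgG cells secrete, the median transformed barcode of IgG
    cells sits >= 0.8 log10 above the IGHM/A null median (the qualitative
    one-log median increase)."""
    cfg = GeneratorConfig(n_cells=4000, seed=17,
                          secretor_fraction_range=(0.9, 1.0))
    _, feats, _, truth = generate_dataset(cfg)
    vals = transform_barcode(feats.feature_vector("SEC-IgG"))
    igg = (truth["true_population"] == "IgG_ASC").to_numpy()
    null = truth["true_population"].isin(["IGHM_ASC", "IGHA_ASC"]).to_numpy()
    assert np.median(vals[igg]) - np.median(vals[null]) >= 0.8
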