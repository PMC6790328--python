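import numpy as np
import pytest
from helpers import i2c2_oracle, icc_oracle

from retest import (
    FeatureTable,
    SeedPairIndex,
    i2c2,
    i2c2_bootstrap_ci,
    icc,
    reliability_report,
    seed_mean_icc,
)

# 4 subjects x 2 sessions; frozen expected values computed by exact fractions
# from the explicit ANOVA sums (and re-derived at test time by the loop oracle)
FOUR_BY_TWO = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 6.0]])
FOUR_BY_TWO_EXPECTED = {
    "ICC(1,1)": 86.0 / 128.0,  # 0.671875
    "ICC(2,1)": 52.0 / 73.0,  # 0.71232876...
    "ICC(3,1)": 52.0 / 55.0,  # 0.94545454...
}


def _as_table(x_2d: np.ndarray) -> FeatureTable:
    vals = x_2d[:, :, None]
    return FeatureTable(
        [f"s{i}" for i in range(len(x_2d))], ["f"], vals
    )


class TestIcc:
    @pytest.mark.parametrize("form,expected", FOUR_BY_TWO_EXPECTED.items())
    def test_frozen_small_table(self, form, expected):
        got = icc(_as_table(FOUR_BY_TWO), form=form)[0]
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(icc_oracle(FOUR_BY_TWO, form), abs=1e-12)

    def test_agrees_with_pingouin(self):
        # second independent implementation of the Shrout-Fleiss forms
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        x = rng.normal(size=(9, 2)) + rng.normal(size=(9, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(9), 2),
                "rater": np.tile([0, 1], 9),
                "y": x.ravel(),
            }
        )
        res = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="y"
        ).set_index("Type")["ICC"]
        ours = {f: icc(_as_table(x), form=f)[0] for f in FOUR_BY_TWO_EXPECTED}
        assert ours["ICC(1,1)"] == pytest.approx(res["ICC(1,1)"], abs=1e-8)
        assert ours["ICC(2,1)"] == pytest.approx(res["ICC(A,1)"], abs=1e-8)
        assert ours["ICC(3,1)"] == pytest.approx(res["ICC(C,1)"], abs=1e-8)

    def test_perfect_agreement(self, identical_sessions_table):
        for form in FOUR_BY_TWO_EXPECTED:
            assert np.allclose(icc(identical_sessions_table, form=form), 1.0)

    def test_zero_variance_feature_is_nan(self):
        vals = np.zeros((5, 2, 2))
        vals[:, :, 1] = np.arange(5)[:, None] + [[0.0, 0.1]]
        t = FeatureTable([f"s{i}" for i in range(5)], ["flat", "ok"], vals)
        out = icc(t)
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_session_shift_orders_forms(self, table_factory):
        # absolute agreement pays for the systematic shift, consistency does not
        for seed in range(20):
            t, _ = table_factory(
                n_subjects=25, n_features=5, session_shift=1.0, seed=seed
            )
            assert np.all(icc(t, "ICC(2,1)") <= icc(t, "ICC(3,1)") + 1e-12)

    def test_parameter_recovery(self, table_factory):
        t, truth = table_factory(
            n_subjects=2000, n_features=10, sigma_b=1.0, sigma_w=1 / 3, seed=9
        )
        assert np.nanmean(icc(t)) == pytest.approx(0.9, abs=0.02)


class TestI2c2:
    def test_identical_sessions_give_one(self, identical_sessions_table):
        assert i2c2(identical_sessions_table) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, table_factory):
        for seed in range(10):
            t, _ = table_factory(n_subjects=8, n_features=3, seed=seed)
            for demean in (True, False):
                assert i2c2(t, demean_sessions=demean) == pytest.approx(
                    i2c2_oracle(t.values, demean=demean), abs=1e-12
                )

    def test_parameter_recovery(self, table_factory):
        t, truth = table_factory(
            n_subjects=2000, n_features=50, sigma_b=1.0, sigma_w=0.5, seed=4
        )
        assert i2c2(t) == pytest.approx(truth["i2c2"], abs=0.02)

    def test_broken_pairing_near_zero(self, table_factory):
        t, _ = table_factory(n_subjects=2000, n_features=20, seed=6)
        rng = np.random.default_rng(0)
        shuffled = t.values.copy()
        shuffled[:, 1, :] = shuffled[rng.permutation(t.n_subjects), 1, :]
        broken = FeatureTable(t.subject_ids, t.feature_names, shuffled)
        assert abs(i2c2(broken)) < 0.05

    def test_p1_matches_icc_population_target(self, table_factory):
        # for a single feature both estimators target sigma_b^2/(sigma_b^2+sigma_w^2)
        t, truth = table_factory(n_subjects=3000, n_features=1, seed=13)
        assert i2c2(t) == pytest.approx(truth["i2c2"], abs=0.03)
        assert icc(t, "ICC(3,1)")[0] == pytest.approx(truth["i2c2"], abs=0.03)

    def test_never_exceeds_one(self, table_factory):
        for seed in range(10):
            t, _ = table_factory(n_subjects=6, n_features=4, seed=seed)
            assert i2c2(t) <= 1.0

    def test_constant_table_is_error(self):
        t = FeatureTable(["a", "b", "c"], ["f"], np.ones((3, 2, 1)))
        with pytest.raises(ValueError, match="total trace"):
            i2c2(t)


class TestBootstrapCi:
    def test_deterministic_given_seed(self, table_factory):
        t, _ = table_factory(n_subjects=15, n_features=5, seed=2)
        a = i2c2_bootstrap_ci(t, n_boot=200, seed=77)
        b = i2c2_bootstrap_ci(t, n_boot=200, seed=77)
        assert a == b

    def test_noise_free_ci_is_degenerate_at_one(self, table_factory):
        t, _ = table_factory(n_subjects=10, n_features=4, sigma_w=0.0, seed=3)
        assert i2c2_bootstrap_ci(t, n_boot=200, seed=0) == (1.0, 1.0)

    def test_ci_contains_point_estimate(self, table_factory):
        for seed in range(5):
            t, _ = table_factory(n_subjects=20, n_features=8, seed=seed)
            lo, hi = i2c2_bootstrap_ci(t, n_boot=300, seed=seed)
            assert lo <= i2c2(t) <= hi

    def test_small_n_boot_rejected(self, table_factory):
        t, _ = table_factory(n_subjects=10, n_features=2, seed=0)
        with pytest.raises(ValueError, match="n_boot"):
            i2c2_bootstrap_ci(t, n_boot=50)


class TestSeedMeanIcc:
    def test_constant_pairs(self):
        idx = SeedPairIndex(["A", "B", "C", "D"])
        assert np.allclose(seed_mean_icc(np.full(6, 0.4), idx), 0.4)

    def test_three_seed_hand_example(self):
        idx = SeedPairIndex(["A", "B", "C"])
        out = seed_mean_icc(np.array([0.2, 0.4, 0.6]), idx)  # AB, AC, BC
        assert np.allclose(out, [0.3, 0.4, 0.5])

    def test_54_seeds_output_length(self):
        idx = SeedPairIndex([f"s{k}" for k in range(54)])
        assert seed_mean_icc(np.linspace(0, 1, 1431), idx).shape == (54,)

    def test_nan_pairs_excluded(self):
        idx = SeedPairIndex(["A", "B", "C"])
        out = seed_mean_icc(np.array([np.nan, 0.4, 0.6]), idx)
        assert out[0] == pytest.approx(0.4)
        assert out[2] == pytest.approx(0.5)


def test_reliability_report_bundle(table_factory):
    t, _ = table_factory(n_subjects=12, n_features=6, seed=1)
    rep = reliability_report(t, n_boot=150, seed=0)
    assert rep.i2c2_ci[0] <= rep.i2c2 <= rep.i2c2_ci[1]
    assert len(rep.per_feature_icc) == 6
    summary = rep.summary()
    assert summary["icc_form"] == "ICC(2,1)"
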