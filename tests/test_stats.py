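import numpy as np
import pytest

import facemetry as fm


class TestIcc:
    def test_perfect_agreement(self):
        res = fm.icc_two_way_absolute(np.array([[1, 1], [2, 2], [3, 3.0]]))
        assert res.icc_single == pytest.approx(1.0)
        assert res.icc_average == pytest.approx(1.0)

    def test_hand_anova_example(self):
        """[[1,2],[2,3],[3,4]]: MSR = 2, MSC = 1.5, MSE = 0 by hand, so
        ICC(A,1) = (2-0)/(2 + 0 + 2*1.5/3) = 2/3."""
        res = fm.icc_two_way_absolute(np.array([[1, 2], [2, 3], [3, 4.0]]))
        assert res.ms_rows == pytest.approx(2.0)
        assert res.ms_cols == pytest.approx(1.5)
        assert res.ms_error == pytest.approx(0.0, abs=1e-12)
        assert res.icc_single == pytest.approx(2 / 3)
        assert res.icc_average == pytest.approx(0.8)

    def test_matches_pingouin_on_random_data(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        X = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": X.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score").set_index("Type")
        res = fm.icc_two_way_absolute(X)
        assert res.icc_single == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert res.icc_average == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        assert res.ci_single[0] == pytest.approx(lo, abs=5e-3)
        assert res.ci_single[1] == pytest.approx(hi, abs=5e-3)

    def test_variance_component_recovery(self):
        """Simulated two-way data with subject SD 1, rater-bias SD 0.3 and
        residual SD 0.3 estimates ICC near 1/(1 + 0.09 + 0.09)."""
        rng = np.random.default_rng(7)
        n, k = 200, 3
        X = (
            rng.normal(0, 1.0, (n, 1))
            + rng.normal(0, 0.3, (1, k))
            + rng.normal(0, 0.3, (n, k))
        )
        res = fm.icc_two_way_absolute(X)
        assert abs(res.icc_single - 1 / 1.18) < 0.05

    def test_average_at_least_single(self, rng):
        X = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
        res = fm.icc_two_way_absolute(X)
        if res.icc_single >= 0:
            assert res.icc_average >= res.icc_single

    def test_shift_and_scale_invariance(self, rng):
        X = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1))
        base = fm.icc_two_way_absolute(X).icc_single
        assert fm.icc_two_way_absolute(X + 100).icc_single == pytest.approx(base)
        assert fm.icc_two_way_absolute(X * 7).icc_single == pytest.approx(base)

    def test_missing_cells_rejected(self):
        X = np.array([[1, 2], [2, np.nan], [3, 4.0]])
        with pytest.raises(fm.InvalidArgumentError):
            fm.icc_two_way_absolute(X)

    def test_too_small_rejected(self):
        with pytest.raises(fm.InvalidArgumentError):
            fm.icc_two_way_absolute(np.array([[1, 2], [2, 3.0]]))


class TestPairedT:
    def test_equal_vectors_give_null_result(self):
        x = np.arange(10.0)
        res = fm.paired_t_from_pairs(x, x)
        assert res.t == 0 and res.p == 1 and res.df == 9

    def test_hand_example(self):
        """d = (1,2,3): mean 2, sd 1, t = 2/(1/sqrt(3)) = 2*sqrt(3)."""
        res = fm.paired_t_from_pairs(np.array([1.0, 2, 3]), np.zeros(3))
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-12)

    def test_constant_nonzero_difference_flags_infinite_t(self):
        res = fm.paired_t_from_pairs(np.ones(5), np.zeros(5))
        assert np.isinf(res.t) and res.p == 0 and res.degenerate

    def test_type_i_error_calibrated(self, rng):
        """Null differences N(0,1) at n = 23: rejection at alpha = 0.05
        lands in [0.04, 0.06] over 5000 replicates."""
        rejections = 0
        reps = 5000
        for _ in range(reps):
            d = rng.normal(0, 1, 23)
            if fm.paired_t_from_pairs(d, np.zeros(23)).p < 0.05:
                rejections += 1
        assert 0.04 <= rejections / reps <= 0.06

    def test_summary_form_agrees_with_pairs(self, rng):
        x = rng.normal(size=23)
        y = rng.normal(size=23)
        from_pairs = fm.paired_t_from_pairs(x, y)
        d = x - y
        from_summary = fm.paired_t_from_summary(d.mean(), d.std(ddof=1), 23)
        assert from_summary.t == pytest.approx(from_pairs.t, abs=1e-9)
        assert from_summary.p == pytest.approx(from_pairs.p, abs=1e-9)

    def test_zero_mean_summary(self):
        res = fm.paired_t_from_summary(0.0, 1.0, 10)
        assert res.t == 0 and res.p == 1

    def test_invalid_sd_rejected(self):
        with pytest.raises(fm.InvalidArgumentError):
            fm.paired_t_from_summary(1.0, 0.0, 10)


class TestMeanCi:
    def test_zero_sd_collapses_to_point(self):
        assert fm.mean_ci(3.2, 0.0, 10) == (3.2, 3.2)

    def test_width_shrinks_with_n(self):
        w = [np.diff(fm.mean_ci(0, 1, n))[0] for n in (5, 50, 500, 50000)]
        assert all(w[i + 1] < w[i] for i in range(len(w) - 1))
        assert w[-1] < 0.02

    def test_contains_the_mean(self, rng):
        for _ in range(50):
            m, s, n = rng.normal() * 10, abs(rng.normal()) + 0.1, int(rng.integers(2, 100))
            lo, hi = fm.mean_ci(m, s, n)
            assert lo <= m <= hi

    def test_invalid_level_rejected(self):
        with pytest.raises(fm.InvalidArgumentError):
            fm.mean_ci(0, 1, 10, level=1.5)


class TestShapiroWilk:
    def test_w_bounded_by_one(self, rng):
        for _ in range(20):
            w, _ = fm.shapiro_wilk(rng.normal(size=23))
            assert 0 < w <= 1

    def test_type_i_error_calibrated(self, rng):
        rejections = sum(
            fm.shapiro_wilk(rng.normal(size=23))[1] < 0.05 for _ in range(2000)
        )
        assert 0.04 <= rejections / 2000 <= 0.06

    def test_detects_exponential_samples(self, rng):
        detected = sum(
            fm.shapiro_wilk(rng.exponential(size=50))[1] < 0.01 for _ in range(200)
        )
        assert detected / 200 >= 0.95

    def test_constant_sample_rejected(self):
        with pytest.raises(fm.DegenerateInputError):
            fm.shapiro_wilk(np.ones(10))


class TestSampleSize:
    def test_study_design_value(self):
        """d = 0.8 at 95% power, alpha 0.05 (two-sided) needs 23 pairs."""
        res = fm.paired_sample_size(0.8, 0.95, 0.05)
        assert res.n == 23
        assert res.achieved_power >= 0.95
        assert res.power_at_n_minus_1 < 0.95

    def test_eighty_percent_power_needs_fifteen(self):
        assert fm.paired_sample_size(0.8, 0.80, 0.05).n == 15

    def test_larger_effects_need_fewer_subjects(self):
        assert fm.paired_sample_size(1.2, 0.95, 0.05).n < 23

    def test_deterministic(self):
        a = fm.paired_sample_size(0.5, 0.9, 0.05)
        b = fm.paired_sample_size(0.5, 0.9, 0.05)
        assert (a.n, a.achieved_power) == (b.n, b.achieved_power)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(fm.InvalidArgumentError):
            fm.paired_sample_size(0.0, 0.95, 0.05)
        with pytest.raises(fm.InvalidArgumentError):
            fm.paired_sample_size(0.8, 1.2, 0.05)
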