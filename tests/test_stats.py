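"""Cohort statistics: routing, matching, reproducibility, sample size."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctecv import phantom as ph
from ctecv.errors import ValidationError
from ctecv.stats import (bland_altman, compare_groups, comparison_table,
                         correlate, cv_reproducibility, describe, icc,
                         independent_ttest, propensity_match,
                         sample_size_ttest, standardized_mean_differences)


class TestDescribe:
    def test_normal_routes_to_mean_sd(self, rng):
        s = describe(rng.normal(10, 2, 200))
        assert s.route == "mean_sd"
        assert s.values["mean"] == pytest.approx(10, abs=0.5)

    def test_skewed_routes_to_median_iqr(self, rng):
        s = describe(rng.exponential(1.0, 200))
        assert s.route == "median_iqr"
        assert "(" in s.text

    def test_binary(self):
        s = describe([1, 1, 1, 0, 0], kind="binary")
        assert s.route == "count_pct"
        assert s.values["n"] == 3 and s.values["pct"] == 60.0

    def test_constant_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            s = describe([5.0, 5.0, 5.0, 5.0])
        assert s.route == "median_iqr"

    def test_validation(self):
        with pytest.raises(ValidationError):
            describe([1.0, 2.0])
        with pytest.raises(ValidationError):
            describe([1, 2, 3], kind="ordinal")


class TestCompareGroups:
    def test_spss_style_binary_table_uses_chi2(self):
        # 16/20 vs 13/20 positives: all expected cells >= 5 -> chi-square
        x = [1] * 16 + [0] * 4
        y = [1] * 13 + [0] * 7
        c = compare_groups(x, y, kind="binary")
        assert c.test == "chi2"
        assert c.p_value == pytest.approx(0.288, abs=0.005)

    def test_small_expected_cells_use_fisher(self):
        x = [1] * 19 + [0]
        y = [1] * 16 + [0] * 4
        c = compare_groups(x, y, kind="binary")
        assert c.test == "fisher"

    def test_normal_groups_use_t(self, rng):
        c = compare_groups(rng.normal(0, 1, 40), rng.normal(2, 1, 40))
        assert c.test == "t"
        assert c.p_value < 1e-6

    def test_nonnormal_groups_use_mannwhitney(self, rng):
        c = compare_groups(rng.exponential(1, 60), rng.exponential(2, 60))
        assert c.test == "mannwhitney"

    def test_welch_flag(self, rng):
        c = compare_groups(rng.normal(0, 1, 40), rng.normal(0, 4, 40),
                           welch=True)
        assert c.test in ("welch_t", "mannwhitney")

    def test_empty_group(self):
        with pytest.raises(ValidationError):
            compare_groups([], [1.0, 2.0])

    def test_comparison_table(self):
        df = ph.generate_cohort(ph.CohortParams(seed=5))
        tab = comparison_table(df, "group",
                               continuous=["ecv_pct", "age"],
                               binary=["male", "diabetes"])
        assert len(tab) == 4
        assert set(tab.columns) >= {"variable", "test", "p"}
        assert tab.loc[tab["variable"] == "ecv_pct", "p"].iloc[0] < 0.01


class TestCorrelate:
    def test_pearson_for_normal(self, rng):
        # exact normal quantiles: Shapiro cannot reject either variable
        from scipy import stats as sps
        q = sps.norm.ppf((np.arange(100) + 0.5) / 100)
        x = q
        y = 0.6 * x + 0.8 * q[rng.permutation(100)]
        r, p, method = correlate(x, y)
        assert method == "pearson"
        assert 0.3 < r < 0.8 and p < 0.01

    def test_spearman_for_skewed(self, rng):
        x = rng.exponential(1, 100)
        r, p, method = correlate(x, x ** 2)
        assert method == "spearman"
        assert r == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValidationError):
            correlate([1, 2], [1, 2])
        with pytest.raises(ValidationError):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])


class TestPropensityMatch:
    def test_identical_covariates_match_everyone(self):
        cov = pd.DataFrame({"age": [60.0] * 10, "bmi": [24.0] * 10})
        t = [1] * 5 + [0] * 5
        res = propensity_match(cov, t)
        assert len(res.pairs) == 5
        assert res.n_unmatched_treated == 0

    def test_caliper_limits_pairing(self, rng):
        age = rng.normal(60, 8, 60)
        t = np.array([1] * 25 + [0] * 35)
        cov = pd.DataFrame({"age": age})
        loose = propensity_match(cov, t, caliper=np.inf)
        tight = propensity_match(cov, t, caliper=1e-12)
        assert len(loose.pairs) == 25          # everyone pairs without a caliper
        assert len(tight.pairs) < len(loose.pairs)

    def test_perfect_separation_rejected(self, rng):
        # non-overlapping arms: the propensity model is not estimable
        age = np.concatenate([rng.normal(80, 0.5, 20), rng.normal(30, 0.5, 20)])
        cov = pd.DataFrame({"age": age})
        t = np.array([1] * 20 + [0] * 20)
        with pytest.raises(ValidationError, match="not estimable"):
            propensity_match(cov, t)

    def test_matching_improves_balance(self, rng):
        n = 150
        age = rng.normal(60, 8, n)
        p = 1 / (1 + np.exp(-(age - 60) / 4))
        t = (rng.random(n) < p).astype(int)
        if t.sum() < 10 or t.sum() > n - 10:
            t[:10], t[-10:] = 1, 0
        cov = pd.DataFrame({"age": age})
        res = propensity_match(cov, t, caliper=0.1)
        assert len(res.pairs) >= 10
        ti = [a for a, _ in res.pairs]
        ci = [b for _, b in res.pairs]
        smd_before = standardized_mean_differences(cov, t)["age"]
        matched = pd.concat([cov.iloc[ti], cov.iloc[ci]])
        flags = np.array([1] * len(ti) + [0] * len(ci))
        smd_after = standardized_mean_differences(matched, flags)["age"]
        assert smd_after < smd_before
        # every accepted pair is within the caliper on the logit scale
        gaps = np.abs(res.logits[ti] - res.logits[ci])
        assert gaps.max() <= 0.1 + 1e-12

    def test_one_armed_input_rejected(self):
        cov = pd.DataFrame({"age": np.arange(6.0)})
        with pytest.raises(ValidationError):
            propensity_match(cov, [1] * 6)


class TestReproducibility:
    def test_bland_altman_known(self):
        a = np.array([10.0, 12.0, 11.0, 13.0])
        b = np.array([9.0, 12.5, 10.0, 12.0])
        bias, sd, lo, hi = bland_altman(a, b)
        d = a - b
        assert bias == pytest.approx(d.mean())
        assert sd == pytest.approx(d.std(ddof=1))
        assert lo == pytest.approx(bias - 1.96 * sd)
        assert hi == pytest.approx(bias + 1.96 * sd)

    def test_cv_known(self):
        a = np.array([10.0, 10.0, 10.0, 10.0])
        b = np.array([11.0, 9.0, 11.0, 9.0])
        want = (a - b).std(ddof=1) / np.sqrt(2) / 10.0 * 100
        assert cv_reproducibility(a, b) == pytest.approx(want)
        with pytest.raises(ValidationError):
            cv_reproducibility(-a, -b)

    def test_icc_perfect_agreement(self, rng):
        a = rng.normal(30, 5, 50)
        val, lo, hi = icc(a, a)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_icc_validation(self):
        with pytest.raises(ValidationError):
            icc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_two_reader_regime(self, rng):
        # two readers of the same quantity: high ICC, small bias, CV of a
        # few percent — the regime these metrics are designed for
        truth = rng.normal(30, 5, 40)
        a = truth + rng.normal(0, 1.0, 40)
        b = truth + rng.normal(0.5, 1.0, 40)
        bias, sd, *_ = bland_altman(a, b)
        assert bias == pytest.approx(-0.5, abs=0.6)
        val, lo, hi = icc(a, b)
        assert 0.85 < val <= 1.0
        assert lo < val < hi


class TestSampleSize:
    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower
        solver = TTestIndPower()
        for delta, sd, power in [(5, 5, 0.8), (3, 5, 0.9), (10, 8, 0.8),
                                 (2, 5, 0.5)]:
            n = sample_size_ttest(delta, sd, power, 0.05)
            want = int(np.ceil(solver.solve_power(
                effect_size=delta / sd, alpha=0.05, power=power,
                ratio=1.0, alternative="two-sided")))
            assert n == want, (delta, sd, power)

    def test_monotone_in_effect_and_power(self):
        assert sample_size_ttest(5, 5, 0.9) > sample_size_ttest(5, 5, 0.8)
        assert sample_size_ttest(2, 5, 0.8) > sample_size_ttest(5, 5, 0.8)

    @pytest.mark.parametrize("kwargs", [
        dict(delta=0, sd=5), dict(delta=5, sd=0),
        dict(delta=5, sd=5, power=1.0), dict(delta=5, sd=5, alpha=0.0),
        dict(delta=5, sd=5, power=0.04, alpha=0.05),
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValidationError):
            sample_size_ttest(**kwargs)


class TestTtest:
    def test_matches_scipy_pooled(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 18)
        from scipy import stats as sps
        stat, p = independent_ttest(x, y)
        want = sps.ttest_ind(x, y)
        assert stat == pytest.approx(want.statistic)
        assert p == pytest.approx(want.pvalue)

    def test_validation(self):
        with pytest.raises(ValidationError):
            independent_ttest([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------------

@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                          allow_nan=False, allow_infinity=False),
                min_size=3, max_size=60))
def test_describe_always_routes(xs):
    s = describe(np.asarray(xs))
    assert s.route in ("mean_sd", "median_iqr")


@settings(max_examples=100, deadline=None)
@given(st.floats(min_value=1e-6, max_value=1.0, exclude_min=False))
def test_segment_score_total_band_cover(v):
    from ctecv.perfusion import segment_score
    assert segment_score(v) in (0, 1, 2, 3)


@settings(max_examples=100, deadline=None)
@given(st.tuples(*[st.floats(min_value=0, max_value=100) for _ in range(4)]))
def test_cad_rads_always_valid_and_monotone_flag(vals):
    from ctecv.morphometry import VesselStenosis, cad_rads
    cat, obs = cad_rads(VesselStenosis(*vals))
    assert cat in ("0", "1", "2", "3", "4A", "4B", "5")
    assert obs == (cat in ("3", "4A", "4B", "5"))
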