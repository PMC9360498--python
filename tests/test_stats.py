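"""Unequal-variance statistics: oracles, identities, calibration."""

import math

import mpmath
import numpy as np
import pytest
from scipy import stats

import redoxim as rx
from redoxim.errors import ContractError
from redoxim.redox_stats import smm_sf


def welch_oracle(m1, s1, n1, m2, s2, n2, dps=50):
    """Arbitrary-precision evaluation of the Welch closed form."""
    with mpmath.workdps(dps):
        m1, s1, m2, s2 = map(mpmath.mpf, (m1, s1, m2, s2))
        v1 = s1**2 / n1
        v2 = s2**2 / n2
        t = (m1 - m2) / mpmath.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        x = df / (df + t**2)
        p = mpmath.betainc(df / 2, mpmath.mpf(1) / 2, 0, x, regularized=True)
        return float(t), float(df), float(p)


class TestWelchT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = rx.welch_t(a, a.copy())
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert r.effect_size == pytest.approx(0.0)

    def test_nc_ratio_worked_example_against_oracle(self):
        # cell-based N:C comparison from printed group summaries
        t_o, df_o, p_o = welch_oracle(0.16, 0.04, 90, 0.28, 0.14, 90)
        assert abs(t_o) == pytest.approx(7.82, abs=0.01)
        r = rx.welch_t((0.16, 0.04, 90), (0.28, 0.14, 90))
        assert r.statistic == pytest.approx(t_o, rel=1e-12)
        assert r.df == pytest.approx(df_o, rel=1e-12)
        assert r.p_value == pytest.approx(p_o, rel=1e-9)
        assert r.p_value < 0.0001

    def test_raw_sample_p_matches_arbitrary_precision_closed_form(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, 5)
        b = rng.normal(1.0, 2.0, 5)
        r = rx.welch_t(a, b)
        t_o, df_o, p_o = welch_oracle(
            a.mean(), a.std(ddof=1), 5, b.mean(), b.std(ddof=1), 5
        )
        assert r.p_value == pytest.approx(p_o, abs=1e-9)

    def test_summary_equals_raw_sample_form(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.4, 2, 20)
        r1 = rx.welch_t(a, b)
        r2 = rx.welch_t(
            (a.mean(), a.std(ddof=1), a.size), (b.mean(), b.std(ddof=1), b.size)
        )
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.effect_size == pytest.approx(r2.effect_size, rel=1e-12)

    def test_degenerate_zero_variance_equal_means(self):
        r = rx.welch_t((1.0, 0.0, 5), (1.0, 0.0, 5))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_n_below_two_rejected(self):
        with pytest.raises(ContractError):
            rx.welch_t(np.array([1.0]), np.array([1.0, 2.0]))


class TestBrownForsythe:
    def test_identical_groups_null(self):
        g = np.array([1.0, 2.0, 3.0])
        r = rx.brown_forsythe_anova([g, g.copy(), g.copy()])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_reduces_to_classical_anova_for_equal_variances(self):
        # balanced groups with exactly equal sample variances: shift copies
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 10)
        groups = [base, base + 0.5, base + 1.3]
        ours = rx.brown_forsythe_anova(groups)
        classic = stats.f_oneway(*groups)
        assert ours.statistic == pytest.approx(classic.statistic, rel=1e-12)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ContractError):
            rx.brown_forsythe_anova([np.arange(3.0), np.arange(3.0)])

    def test_null_rejection_rate_under_unequal_variances(self):
        rng = np.random.default_rng(12345)
        reps = 500
        rej = sum(
            rx.brown_forsythe_anova(
                [rng.normal(0, s, 15) for s in (1.0, 2.0, 3.0)]
            ).p_value
            < 0.05
            for _ in range(reps)
        )
        lo = stats.binom.ppf(0.005, reps, 0.05)
        hi = stats.binom.ppf(0.995, reps, 0.05)
        assert lo <= rej <= hi


class TestDunnettT3:
    def test_identical_groups_adjusted_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        for r in rx.dunnett_t3([g, g.copy(), g.copy()]):
            assert r.p_adjusted == pytest.approx(1.0)

    def test_smm_with_one_comparison_is_two_sided_t(self):
        for t, df in ((1.5, 8.0), (2.7, 23.4), (0.4, 3.3)):
            assert smm_sf(t, 1, df) == pytest.approx(2 * stats.t.sf(t, df), rel=1e-6)

    def test_adjusted_dominates_raw_on_random_datasets(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            groups = [
                rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3), rng.integers(5, 20))
                for _ in range(3)
            ]
            for r in rx.dunnett_t3(groups):
                assert 0.0 <= r.p_value <= r.p_adjusted <= 1.0

    def test_sidak_fallback_is_at_least_as_conservative(self):
        rng = np.random.default_rng(17)
        groups = [rng.normal(m, 1, 12) for m in (0.0, 0.3, 0.8)]
        smm = rx.dunnett_t3(groups, method="smm")
        sidak = rx.dunnett_t3(groups, method="sidak")
        for a, b in zip(smm, sidak):
            assert b.p_adjusted >= a.p_adjusted - 1e-12

    def test_only_separated_pair_flagged(self):
        rng = np.random.default_rng(21)
        g1 = rng.normal(0.0, 1.0, 20)
        g2 = rng.normal(0.1, 1.0, 20)
        g3 = rng.normal(5.0, 1.0, 20)
        results = {r.labels: r for r in rx.dunnett_t3([g1, g2, g3], labels="abc")}
        assert results[("a", "b")].p_adjusted > 0.05
        assert results[("a", "c")].p_adjusted < 0.05
        assert results[("b", "c")].p_adjusted < 0.05


class TestFitLine:
    def test_exact_line(self):
        x = np.arange(10.0)
        f = rx.fit_line(x, 2 * x + 1)
        assert f.slope == pytest.approx(2.0)
        assert f.intercept == pytest.approx(1.0)
        assert f.r_squared == pytest.approx(1.0)

    def test_identity(self):
        x = np.linspace(0, 5, 20)
        f = rx.fit_line(x, x)
        assert f.slope == pytest.approx(1.0) and f.r_squared == pytest.approx(1.0)

    def test_independent_noise_has_no_slope(self):
        rng = np.random.default_rng(31)
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        f = rx.fit_line(x, y)
        assert abs(f.slope) < 0.1
        assert f.r_squared < 0.02

    def test_constant_x_rejected(self):
        with pytest.raises(ContractError):
            rx.fit_line(np.ones(5), np.arange(5.0))


class TestCompareSlopes:
    def test_identical_fits_null(self):
        x = np.arange(10.0)
        f = rx.fit_line(x, 1.5 * x + np.sin(x))
        r = rx.compare_slopes(f, f)
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(44)
        x = rng.uniform(0, 1, 30)
        fa = rx.fit_line(x, 0.4 * x + rng.normal(0, 0.1, 30))
        fb = rx.fit_line(x, 0.9 * x + rng.normal(0, 0.1, 30))
        r1 = rx.compare_slopes(fa, fb)
        r2 = rx.compare_slopes(fb, fa)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_separated_slopes_detected(self):
        # nuclear-vs-cytoplasmic Fp slopes 0.37 vs 0.94, residual scatter set
        # so each slope SE is 0.08 exactly: residuals are drawn once, then
        # orthogonalized against the design and rescaled, making the fitted
        # slopes and their SEs exact rather than sampled
        rng = np.random.default_rng(55)
        n = 45
        target_se = 0.08

        def build(slope):
            x = rng.uniform(0.5, 1.5, n)
            e = rng.normal(0, 1, n)
            X = np.column_stack([np.ones(n), x])
            e -= X @ np.linalg.lstsq(X, e, rcond=None)[0]  # residualize
            sxx = ((x - x.mean()) ** 2).sum()
            sigma = target_se * math.sqrt(sxx)
            e *= sigma * math.sqrt(n - 2) / np.linalg.norm(e)
            return rx.fit_line(x, slope * x + e)

        fa, fb = build(0.37), build(0.94)
        assert fa.slope == pytest.approx(0.37, abs=1e-12)
        assert fa.slope_se == pytest.approx(target_se, rel=1e-9)
        r = rx.compare_slopes(fa, fb)
        assert r.p_value < 0.001

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(77)
        reps = 400
        rej = 0
        for _ in range(reps):
            x1 = rng.uniform(0, 1, 20)
            x2 = rng.uniform(0, 1, 20)
            fa = rx.fit_line(x1, 0.5 * x1 + rng.normal(0, 0.3, 20))
            fb = rx.fit_line(x2, 0.5 * x2 + rng.normal(0, 0.6, 20))
            rej += rx.compare_slopes(fa, fb).p_value < 0.05
        lo = stats.binom.ppf(0.005, reps, 0.05)
        hi = stats.binom.ppf(0.995, reps, 0.05)
        assert lo <= rej <= hi


def test_significance_tiers():
    assert rx.significance_tier(0.2) == "ns"
    assert rx.significance_tier(0.03) == "*"
    assert rx.significance_tier(0.004) == "**"
    assert rx.significance_tier(0.0004) == "***"
    assert rx.significance_tier(1e-6) == "****"
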