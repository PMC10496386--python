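"""Parametric laws, RMST, sampling, censored MLE, KM and hybrid splicing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from psmcea.survival import (
    FitError,
    KMCurve,
    ParameterError,
    PseudoIPD,
    SurvivalDist,
    build_hybrid,
    fit_mle,
    km_estimate,
    median_survival,
    rmst,
    sample_times,
    survival_at,
)

WEIBULL_OS = SurvivalDist("weibull", (22.065, 1.536))
LOGNORMAL_OS = SurvivalDist("lognormal", (1.834, 0.873))


class TestSurvivalAt:
    @pytest.mark.parametrize(
        "dist, t, expected",
        [
            (WEIBULL_OS, 0.0, 1.0),
            (WEIBULL_OS, 22.065, np.exp(-1.0)),  # t = scale gives exponent -1
            (SurvivalDist("lognormal", (1.834, 0.873)), np.exp(1.834), 0.5),
            (SurvivalDist("gengamma", (1.0, 0.5, 0.0)), np.exp(1.0), 0.5),
        ],
    )
    def test_known_values(self, dist, t, expected):
        assert survival_at(dist, t) == pytest.approx(expected, abs=1e-12)

    def test_gengamma_reduces_to_weibull_and_lognormal(self):
        grid = np.linspace(0.0, 240.0, 500)
        gg_w = SurvivalDist("gengamma", (np.log(22.065), 1.0 / 1.536, 1.0))
        np.testing.assert_allclose(
            gg_w.survival(grid), WEIBULL_OS.survival(grid), atol=1e-12
        )
        gg_l = SurvivalDist("gengamma", (1.834, 0.873, 0.0))
        np.testing.assert_allclose(
            gg_l.survival(grid), LOGNORMAL_OS.survival(grid), atol=1e-12
        )

    @pytest.mark.parametrize(
        "family, params",
        [
            ("weibull", (-1.0, 1.5)),
            ("weibull", (22.0, 0.0)),
            ("lognormal", (1.8, -0.1)),
            ("gengamma", (1.0, 0.0, 0.5)),
            ("weibull", (22.0,)),
        ],
    )
    def test_invalid_parameters_rejected(self, family, params):
        with pytest.raises(ParameterError):
            SurvivalDist(family, params)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            WEIBULL_OS.survival(-1.0)


class TestMedian:
    @pytest.mark.parametrize(
        "dist, expected",
        [
            (SurvivalDist("lognormal", (1.834, 0.873)), np.exp(1.834)),   # 6.26 mo
            (SurvivalDist("lognormal", (1.962, 0.971)), np.exp(1.962)),   # 7.11 mo
            (WEIBULL_OS, 22.065 * np.log(2.0) ** (1.0 / 1.536)),          # 17.4 mo
        ],
    )
    def test_closed_forms(self, dist, expected):
        assert median_survival(dist) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "dist",
        [
            WEIBULL_OS,
            LOGNORMAL_OS,
            SurvivalDist("gengamma", (2.5, 0.8, 0.7)),
            SurvivalDist("gengamma", (2.5, 0.8, -0.6)),
        ],
    )
    def test_median_inverts_survival(self, dist):
        assert dist.survival(median_survival(dist)) == pytest.approx(0.5, abs=1e-8)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    family=st.sampled_from(["weibull", "lognormal", "gengamma"]),
    p1=st.floats(0.5, 40.0),
    p2=st.floats(0.1, 3.0),
    q=st.floats(-1.5, 1.5),
)
def test_survival_is_monotone_and_proper(family, p1, p2, q):
    """S(0)=1, S in [0,1], non-increasing on a 1000-point grid over 20 years."""
    if family == "weibull":
        dist = SurvivalDist("weibull", (p1, p2))
    elif family == "lognormal":
        dist = SurvivalDist("lognormal", (np.log(p1), p2))
    else:
        dist = SurvivalDist("gengamma", (np.log(p1), p2, q))
    grid = np.linspace(0.0, 240.0, 1000)
    s = dist.survival(grid)
    assert s[0] == 1.0
    assert np.all((s >= 0.0) & (s <= 1.0))
    assert np.all(np.diff(s) <= 1e-12)


class TestRmst:
    def _trapezoid_oracle(self, dist, horizon, rate=0.0, n=20001):
        t = np.linspace(0.0, horizon, n)
        integrand = dist.survival(t) * (1.0 + rate) ** (-t / 12.0)
        return np.trapezoid(integrand, t) / 12.0

    @pytest.mark.parametrize("dist", [WEIBULL_OS, LOGNORMAL_OS,
                                      SurvivalDist("gengamma", (2.5, 0.8, 0.7))])
    def test_matches_independent_trapezoid(self, dist):
        assert rmst(dist, 60.0, 0.0) == pytest.approx(
            self._trapezoid_oracle(dist, 60.0), abs=1e-4
        )

    def test_degenerate_flat_curve_gives_horizon(self):
        # scale so large that S is ~1 over the horizon
        near_immortal = SurvivalDist("weibull", (1e9, 1.0))
        assert rmst(near_immortal, 60.0, 0.0) == pytest.approx(5.0, rel=1e-6)

    def test_discounting_reduces_value(self):
        assert rmst(WEIBULL_OS, 60.0, 0.03) < rmst(WEIBULL_OS, 60.0, 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rmst(WEIBULL_OS, 0.0)
        with pytest.raises(ValueError):
            rmst(WEIBULL_OS, 60.0, 1.0)


class TestSampling:
    def test_deterministic_for_fixed_seed(self):
        a = sample_times(WEIBULL_OS, 100, 7)
        b = sample_times(WEIBULL_OS, 100, 7)
        np.testing.assert_array_equal(a, b)

    def test_requires_positive_n(self):
        with pytest.raises(ValueError):
            sample_times(WEIBULL_OS, 0, 1)

    def test_empirical_median_converges(self):
        x = sample_times(SurvivalDist("lognormal", (1.834, 0.873)), 100_000, 11)
        assert np.median(x) == pytest.approx(np.exp(1.834), abs=0.2)

    @pytest.mark.parametrize(
        "dist",
        [WEIBULL_OS, LOGNORMAL_OS, SurvivalDist("gengamma", (2.5, 0.8, 0.7)),
         SurvivalDist("gengamma", (2.5, 0.8, -0.6))],
    )
    def test_kolmogorov_distance_small(self, dist):
        x = sample_times(dist, 10_000, 3)
        ks = stats.kstest(x, lambda t: 1.0 - dist.survival(t)).statistic
        assert ks < 0.02


class TestFitMle:
    def test_exponential_data_gives_unit_shape(self):
        t = sample_times(SurvivalDist("weibull", (10.0, 1.0)), 2000, 5)
        fit = fit_mle(PseudoIPD(t, np.ones_like(t, dtype=int)), "weibull")
        assert fit.dist.params[1] == pytest.approx(1.0, abs=0.08)

    def test_censored_weibull_recovery_and_loglik(self):
        t = sample_times(WEIBULL_OS, 500, 42)
        ipd = PseudoIPD(np.minimum(t, 24.0), (t <= 24.0).astype(int))
        fit = fit_mle(ipd, "weibull")
        scale, shape = fit.dist.params
        assert scale == pytest.approx(22.065, rel=0.15)
        assert shape == pytest.approx(1.536, rel=0.15)
        # our closed-form censored log-likelihood must agree with lifelines'
        from lifelines import WeibullFitter

        wf = WeibullFitter().fit(ipd.time, ipd.event)
        assert fit.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)
        assert fit.bic == pytest.approx(2 * np.log(500) - 2 * fit.loglik)

    def test_aic_prefers_true_family_at_large_n(self):
        t = sample_times(SurvivalDist("lognormal", (1.9, 0.9)), 2000, 13)
        ipd = PseudoIPD(np.minimum(t, 36.0), (t <= 36.0).astype(int))
        assert fit_mle(ipd, "lognormal").aic < fit_mle(ipd, "weibull").aic

    def test_requires_enough_events(self):
        t = np.linspace(1, 10, 20)
        e = np.zeros(20, dtype=int)
        e[:5] = 1
        with pytest.raises(ValueError):
            fit_mle(PseudoIPD(t, e), "weibull")


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        ipd = PseudoIPD(time=[1.0, 2.0, 3.0], event=[1, 1, 0])
        km = km_estimate(ipd)
        assert km(0.0) == 1.0
        assert km(1.0) == pytest.approx(2.0 / 3.0)
        assert km(1.5) == pytest.approx(2.0 / 3.0)
        assert km(2.0) == pytest.approx(1.0 / 3.0)
        assert km(3.0) == pytest.approx(1.0 / 3.0)

    def test_no_censoring_equals_empirical_survival(self):
        t = sample_times(WEIBULL_OS, 200, 9)
        km = km_estimate(PseudoIPD(t, np.ones_like(t, dtype=int)))
        ts = np.sort(t)
        # just after the k-th order statistic the ECDF-based survival is 1-k/n
        for k in (0, 50, 150, 199):
            assert km(ts[k]) == pytest.approx(1.0 - (k + 1) / 200.0, abs=1e-12)

    def test_all_censored_warns_and_is_flat(self):
        ipd = PseudoIPD(time=[5.0, 5.0, 5.0], event=[0, 0, 0])
        with pytest.warns(UserWarning):
            km = km_estimate(ipd)
        assert km(4.9) == 1.0


class TestHybrid:
    def test_switch_at_zero_is_pure_parametric(self):
        km = KMCurve([0.0], [1.0], [100.0], max_follow_up=0.0)
        hy = build_hybrid(km, WEIBULL_OS, 0.0)
        grid = np.linspace(0.0, 120.0, 200)
        np.testing.assert_allclose(hy.survival(grid), WEIBULL_OS.survival(grid))

    def test_continuous_at_switch(self):
        t = sample_times(WEIBULL_OS, 400, 21)
        km = km_estimate(PseudoIPD(np.minimum(t, 30.0), (t <= 30.0).astype(int)))
        switch = 12.0
        hy = build_hybrid(km, LOGNORMAL_OS, switch)
        eps = 1e-9
        assert hy.survival(switch) == pytest.approx(hy.survival(switch + eps), abs=1e-6)

    def test_self_consistency_with_matching_tail(self):
        """KM of a big sample from the law, spliced to the same law, stays close."""
        t = sample_times(WEIBULL_OS, 5000, 17)
        km = km_estimate(PseudoIPD(np.minimum(t, 60.0), (t <= 60.0).astype(int)))
        hy = build_hybrid(km, WEIBULL_OS, median_survival(WEIBULL_OS))
        grid = np.linspace(0.0, 120.0, 400)
        assert np.max(np.abs(hy.survival(grid) - WEIBULL_OS.survival(grid))) < 0.02

    def test_monotone_after_splice(self):
        t = sample_times(WEIBULL_OS, 1000, 3)
        km = km_estimate(PseudoIPD(np.minimum(t, 30.0), (t <= 30.0).astype(int)))
        hy = build_hybrid(km, WEIBULL_OS, 18.0)
        s = hy.survival(np.linspace(0.0, 240.0, 2000))
        assert np.all(np.diff(s) <= 1e-12)

    def test_switch_outside_support_rejected(self):
        km = km_estimate(PseudoIPD([1.0, 2.0, 3.0], [1, 1, 1]))
        with pytest.raises(ValueError):
            build_hybrid(km, WEIBULL_OS, 10.0)
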