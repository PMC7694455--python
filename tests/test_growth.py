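"""Biomass curve families, TIME50, lack of fit and suppression ratios."""

import numpy as np
import pytest
import sympy
from scipy import optimize

from phenokit.exceptions import DomainError, InsufficientDataError
from phenokit.growth import (GrowthModel, GrowthResults, loglogistic_curve,
                             suppression_ratio, weibull_curve)

TIMES6 = np.array([500.0, 800.0, 1100.0, 1400.0, 1750.0, 2100.0])


class TestCurves:
    def test_weibull_inflection_value(self):
        # at t = e the Gompertz-type curve sits at d/e
        assert weibull_curve(1317.0, 11.4, 14.8, 1317.0) == pytest.approx(
            14.8 * np.exp(-1.0))

    def test_weibull_asymptotes(self):
        assert weibull_curve(1e9, 11.4, 14.8, 1317.0) == pytest.approx(14.8,
                                                                       rel=1e-6)
        assert weibull_curve(1e-9, 11.4, 14.8, 1317.0) == pytest.approx(0.0,
                                                                        abs=1e-12)

    def test_weibull_matches_symbolic_oracle(self):
        t_sym, c_sym, d_sym, e_sym = sympy.symbols("t c d e", positive=True)
        expr = d_sym * sympy.exp(-sympy.exp(-c_sym * (sympy.log(t_sym)
                                                      - sympy.log(e_sym))))
        for t in (100.0, 700.0, 1317.0, 2500.0):
            ref = float(expr.evalf(30, subs={t_sym: t, c_sym: 8.7,
                                             d_sym: 16.4, e_sym: 1230.0}))
            assert weibull_curve(t, 8.7, 16.4, 1230.0) == pytest.approx(
                ref, rel=1e-12)

    def test_loglogistic_half_at_t50(self):
        assert loglogistic_curve(1548.0, -10.1, 29.3, 1548.0) == 29.3 / 2

    def test_loglogistic_near_asymptote(self):
        assert loglogistic_curve(3000.0, -10.1, 29.3, 1548.0) > 0.95 * 29.3

    def test_loglogistic_flat_when_slope_zero(self):
        t = np.array([10.0, 100.0, 1000.0])
        np.testing.assert_allclose(loglogistic_curve(t, 0.0, 20.0, 500.0),
                                   10.0)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            weibull_curve(-1.0, 5.0, 10.0, 100.0)
        with pytest.raises(DomainError):
            loglogistic_curve(0.0, -5.0, 10.0, 100.0)


class TestFit:
    @pytest.mark.parametrize("family, truth", [
        ("loglogistic", (-10.0, 20.0, 1400.0)),
        ("weibull", (11.4, 14.8, 1317.0)),
    ])
    def test_noise_free_recovery(self, family, truth):
        t = np.repeat(TIMES6, 3)
        curve = weibull_curve if family == "weibull" else loglogistic_curve
        y = curve(t, *truth)
        res = GrowthModel(t, y, family).fit()
        np.testing.assert_allclose(res.params_.astype(float), truth,
                                   rtol=1e-5)
        assert res.converged

    def test_noisy_recovery_of_total_biomass(self):
        """Median relative error of d stays under 5% at 10% noise."""
        t = np.repeat(TIMES6, 3)
        errors = []
        for k in range(200):
            gen = np.random.default_rng(400 + k)
            y = np.maximum(0.0, loglogistic_curve(t, -10.0, 20.0, 1400.0)
                           + gen.normal(0, 2.0, len(t)))
            res = GrowthModel(t, y, "loglogistic").fit()
            errors.append(abs(res.d - 20.0) / 20.0)
        assert np.median(errors) < 0.05

    def test_all_zero_biomass_rejected(self):
        with pytest.raises(InsufficientDataError):
            GrowthModel(np.repeat(TIMES6, 2), np.zeros(12), "weibull")

    def test_too_few_times_rejected(self):
        with pytest.raises(InsufficientDataError):
            GrowthModel([100.0, 200.0, 300.0], [1.0, 2.0, 3.0], "weibull")


class TestTime50:
    def test_loglogistic_identity(self):
        t = np.repeat(TIMES6, 3)
        res = GrowthModel(t, loglogistic_curve(t, -10.1, 29.3, 1548.0),
                          "loglogistic").fit()
        assert res.time50() == pytest.approx(1548.0, rel=1e-6)

    def test_weibull_against_bisection_oracle(self):
        c = 11.4
        e = 1317.0 * np.log(2.0) ** (1.0 / c)  # chosen so half-time is 1317
        t = np.repeat(TIMES6, 3)
        res = GrowthModel(t, weibull_curve(t, c, 14.8, e), "weibull").fit()
        t50 = res.time50()
        oracle = optimize.brentq(
            lambda x: weibull_curve(x, res.c, res.d, res.timing) - res.d / 2,
            10.0, 5000.0, xtol=1e-9)
        assert t50 == pytest.approx(1317.0, rel=1e-4)
        assert t50 == pytest.approx(oracle, rel=1e-6)

    def test_weibull_steep_limit_is_scale(self):
        assert 500.0 * np.log(2.0) ** (-1.0 / 1e8) == pytest.approx(500.0,
                                                                    rel=1e-7)

    @pytest.mark.parametrize("family, params", [
        ("weibull", (8.7, 16.4, 1230.0)),
        ("loglogistic", (-9.8, 22.0, 1319.0)),
    ])
    def test_curve_at_time50_is_half_d(self, family, params):
        t = np.repeat(TIMES6, 3)
        curve = weibull_curve if family == "weibull" else loglogistic_curve
        res = GrowthModel(t, curve(t, *params), family).fit()
        assert res.predict(res.time50()) == pytest.approx(res.d / 2,
                                                          rel=1e-9)


class TestLackOfFit:
    def test_null_rejection_rate(self):
        """Data from the fitted family reject at roughly the nominal rate."""
        t = np.repeat(TIMES6, 3)
        mu = loglogistic_curve(t, -10.0, 20.0, 1400.0)
        rejections = 0
        n_rep = 500
        for k in range(n_rep):
            gen = np.random.default_rng(900 + k)
            y = np.maximum(0.0, mu + gen.normal(0, 1.0, len(t)))
            res = GrowthModel(t, y, "loglogistic").fit()
            _, p = res.lack_of_fit()
            rejections += p < 0.05
        assert rejections / n_rep < 0.10

    def test_power_against_step_function(self):
        """A step-shaped mean is flagged as lack of fit most of the time."""
        t = np.repeat(TIMES6, 3)
        step = np.where(t < 1200.0, 2.0, 20.0)
        rejections = 0
        n_rep = 200
        for k in range(n_rep):
            gen = np.random.default_rng(3000 + k)
            y = np.maximum(0.0, step + gen.normal(0, 1.0, len(t)))
            res = GrowthModel(t, y, "loglogistic").fit()
            _, p = res.lack_of_fit()
            rejections += p < 0.05
        assert rejections / n_rep > 0.80

    def test_unavailable_without_replication(self):
        t = TIMES6
        y = loglogistic_curve(t, -10.0, 20.0, 1400.0)
        res = GrowthModel(t, y, "loglogistic").fit()
        with pytest.raises(InsufficientDataError):
            res.lack_of_fit()


def _dummy_results(d, d_se):
    """GrowthResults carrying just the total-biomass estimate and its SE."""
    cov = np.diag([1e-4, d_se ** 2, 1.0])
    t = np.repeat(TIMES6, 2)
    model = GrowthModel(t, loglogistic_curve(t, -10.0, d, 1400.0),
                        "loglogistic")
    return GrowthResults(model=model, family="loglogistic",
                         params_=np.array([-10.0, d, 1400.0]),
                         cov_params_=cov, rss=0.0, df_resid=9, converged=True)


class TestSuppressionRatio:
    @pytest.mark.parametrize("d_minus, d_plus, expected", [
        (14.9, 6.2, 0.42),
        (29.3, 5.4, 0.18),
        (15.2, 10.3, 0.68),
    ])
    def test_reported_ratios(self, d_minus, d_plus, expected):
        r = suppression_ratio(_dummy_results(d_minus, 1.0),
                              _dummy_results(d_plus, 1.0))
        assert round(r.ratio, 2) == expected

    def test_identical_fits(self):
        res = _dummy_results(15.0, 1.0)
        r = suppression_ratio(res, res)
        assert r.ratio == pytest.approx(1.0)
        assert r.pvalue == pytest.approx(1.0)

    def test_delta_se_matches_parametric_bootstrap(self):
        """Delta-method ratio SE within 15% of a 10k-draw bootstrap SE."""
        d_m, se_m, d_p, se_p = 20.0, 1.2, 7.0, 0.8
        r = suppression_ratio(_dummy_results(d_m, se_m),
                              _dummy_results(d_p, se_p))
        gen = np.random.default_rng(17)
        draws = (gen.normal(d_p, se_p, 10000) / gen.normal(d_m, se_m, 10000))
        assert r.se == pytest.approx(float(draws.std(ddof=1)), rel=0.15)

    def test_invalid_denominator(self):
        good = _dummy_results(15.0, 1.0)
        bad = _dummy_results(15.0, 1.0)
        bad.params_ = np.array([-10.0, -1.0, 1400.0])
        with pytest.raises(DomainError):
            suppression_ratio(bad, good)
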