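"""Log-logistic emergence curve, grouped event-time ML fit and comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_emergence_units
from helpers import grid_search_ml
from phenokit.emergence import (EmergenceCounts, EmergenceModel,
                                compare_parameters, loglogistic_cdf,
                                loglogistic_quantile)
from phenokit.exceptions import (DegenerateSlopeError, DomainError,
                                 UnidentifiableError)


class TestCurve:
    @pytest.mark.parametrize("b", [-9.5, -5.0, -1.2, 3.0])
    def test_half_emergence_at_g50(self, b):
        assert loglogistic_cdf(200.0, b, 200.0) == pytest.approx(0.5)

    def test_ten_percent_point_from_reported_parameters(self):
        # slope -5.0, half-emergence 197 degree C: the curve passes 10%
        # at ~127 degree C
        assert loglogistic_cdf(127.0, -5.0, 197.0) == pytest.approx(0.10,
                                                                    abs=5e-3)

    def test_monotone_on_grid(self):
        t = np.arange(1.0, 1001.0)
        vals = loglogistic_cdf(t, -5.0, 197.0)
        assert np.array_equal(vals, np.sort(vals))
        assert np.all((vals > 0) & (vals < 1))

    def test_domain_error(self):
        with pytest.raises(DomainError):
            loglogistic_cdf(0.0, -5.0, 197.0)
        with pytest.raises(DomainError):
            loglogistic_quantile(1.0, -5.0, 197.0)
        with pytest.raises(DegenerateSlopeError):
            loglogistic_quantile(0.5, 0.0, 197.0)


class TestQuantile:
    @pytest.mark.parametrize("b, g50, p, expected", [
        (-5.0, 197.0, 0.10, 127),
        (-9.5, 199.0, 0.90, 251),
        (-5.7, 179.0, 0.90, 263),
        (-4.9, 237.0, 0.90, 371),
    ])
    def test_reported_quantiles(self, b, g50, p, expected):
        """Rounded quantiles reproduce field-study GERM estimates."""
        assert round(loglogistic_quantile(p, b, g50)) == expected

    def test_median_is_g50(self):
        assert loglogistic_quantile(0.5, -7.3, 231.0) == 231.0

    @settings(derandomize=True, max_examples=60)
    @given(b=st.floats(-12, -0.5), g50=st.floats(20, 800),
           p=st.floats(0.01, 0.99))
    def test_quantile_inverts_cdf(self, b, g50, p):
        t_p = loglogistic_quantile(p, b, g50)
        assert loglogistic_cdf(t_p, b, g50) == pytest.approx(p, rel=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(b=st.floats(-12, -0.5), g50=st.floats(20, 800))
    def test_log_symmetry_of_quantiles(self, b, g50):
        """GERM10 * GERM90 = GERM50^2 (log-logistic symmetry)."""
        q10 = loglogistic_quantile(0.1, b, g50)
        q90 = loglogistic_quantile(0.9, b, g50)
        assert q10 * q90 == pytest.approx(g50 ** 2, rel=1e-9)


TIMES8 = (60.0, 100.0, 140.0, 180.0, 230.0, 300.0, 400.0, 550.0)


def _noise_free_units(b, g50, times=TIMES8, n=10000.0):
    cdf = loglogistic_cdf(np.asarray(times), b, g50)
    cum = tuple(n * c for c in cdf)
    return [EmergenceCounts("exact", times, cum, n_sown=int(n))]


class TestFit:
    def test_noise_free_recovery(self):
        """Counts placed exactly on the curve are recovered to tolerance."""
        model = EmergenceModel(_noise_free_units(-5.0, 200.0),
                               use_censoring=True)
        res = model.fit()
        assert res.b == pytest.approx(-5.0, abs=1e-3)
        assert res.g50 == pytest.approx(200.0, rel=1e-4)
        assert res.converged

    def test_beats_grid_search_oracle(self):
        """The optimizer's likelihood matches a brute-force grid search."""
        units = make_emergence_units(-5.0, 200.0, 3, 400, TIMES8, seed=11)
        model = EmergenceModel(units, use_censoring=True)
        res = model.fit()
        grid_best, grid_val = grid_search_ml(
            model.nloglike,
            np.linspace(-8, -2, 61), np.linspace(np.log(120), np.log(320), 81))
        assert -res.llf <= grid_val + 1e-6
        assert res.b == pytest.approx(grid_best[0], abs=0.15)
        assert res.log_g50 == pytest.approx(grid_best[1], abs=0.05)

    def test_multinomial_simulation_recovery(self):
        """500 seeds x 6 units: estimates within 3 joint SE of truth."""
        units = make_emergence_units(-5.0, 200.0, 6, 500, TIMES8, seed=42)
        res = EmergenceModel(units, use_censoring=True).fit()
        assert abs(res.b - (-5.0)) < 3 * res.bse["b"]
        assert abs(res.g50 - 200.0) < 3 * res.bse["g50"]

    def test_likelihood_dominates_truth(self):
        units = make_emergence_units(-5.5, 180.0, 4, 300, TIMES8, seed=7)
        model = EmergenceModel(units, use_censoring=True)
        res = model.fit()
        assert res.llf >= -model.nloglike((-5.5, np.log(180.0))) - 1e-9

    def test_single_interval_unidentifiable(self):
        unit = EmergenceCounts("deg", (100.0, 200.0, 300.0), (50, 50, 50))
        with pytest.raises(UnidentifiableError):
            EmergenceModel([unit])

    def test_invalid_counts_rejected(self):
        with pytest.raises(Exception):
            EmergenceCounts("bad", (100.0, 200.0), (30, 20))


class TestCompare:
    @staticmethod
    def _fit(seed, g50=200.0, b=-5.0):
        units = make_emergence_units(b, g50, 4, 400, TIMES8, seed=seed)
        return EmergenceModel(units, use_censoring=True).fit()

    def test_identical_fits(self):
        res = self._fit(3)
        t = compare_parameters(res, res, which="g50")
        assert t.statistic == 0.0
        assert t.pvalue == 1.0

    def test_large_separation_rejected(self):
        """Ten joint-SE separation gives an extreme Wald tail."""
        a, b = self._fit(3), self._fit(4)
        shift = 10 * np.hypot(a.bse["g50"], b.bse["g50"])
        b.log_g50 = float(np.log(a.g50 + shift))
        t = compare_parameters(a, b, which="g50")
        assert t.pvalue < 1e-3

    def test_type_one_error_rate(self):
        """Equal-g50 pairs are rejected at roughly the nominal 5% level."""
        rejections = 0
        n_rep = 400
        for k in range(n_rep):
            a = self._fit(1000 + 2 * k)
            b = self._fit(1001 + 2 * k)
            t = compare_parameters(a, b, which="g50")
            rejections += t.pvalue < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08

    def test_quantile_comparison(self):
        a, b = self._fit(3), self._fit(4)
        t = compare_parameters(a, b, which="quantile", p=0.1)
        assert 0 <= t.pvalue <= 1
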