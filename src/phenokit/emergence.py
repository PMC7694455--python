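"""Grouped time-to-event modelling of seedling emergence.

Cumulative emergence of a weed cohort as a function of thermal time t is
described by the two-parameter log-logistic curve

    E(t) = 1 / (1 + exp[b (ln t - ln GERM50)])

where GERM50 is the thermal time at which half of the final emergence has
occurred and b is the (dimensionless) emergence-rate slope. With the sign
convention used throughout (and in the reported tables), b is negative for
an increasing curve.

Counts from repeated quadrat inspections are grouped event-time data: a
seedling observed for the first time at inspection j is only known to have
emerged in the interval (t_{j-1}, t_j]. :class:`EmergenceModel` maximizes
the corresponding multinomial interval likelihood, optionally with a
right-censored term for sown seeds never observed emerged, and
:class:`EmergenceResults` exposes delta-method confidence intervals for the
GERM10/50/90 quantiles together with Wald comparisons between fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from ._wald import WaldTestResult, require_converged, wald_compare
from .exceptions import (ConvergenceError, DegenerateSlopeError, DomainError,
                         InsufficientDataError, InvalidRecordError,
                         UnidentifiableError)

__all__ = [
    "loglogistic_cdf", "loglogistic_quantile", "EmergenceCounts",
    "EmergenceModel", "EmergenceResults", "QuantileEstimate",
    "compare_parameters",
]


def loglogistic_cdf(t, b: float, g50: float):
    """Log-logistic cumulative emergence E(t); increasing in t for b < 0.

    Parameters
    ----------
    t : float or array-like
        Thermal time, strictly positive.
    b : float
        Slope; negative for an increasing curve.
    g50 : float
        Thermal time of 50% emergence, strictly positive.
    """
    t_a = np.asarray(t, dtype=float)
    if np.any(t_a <= 0):
        raise DomainError("thermal time must be positive")
    if g50 <= 0:
        raise DomainError("g50 must be positive")
    out = 1.0 / (1.0 + np.exp(b * (np.log(t_a) - np.log(g50))))
    return float(out) if np.isscalar(t) else out


def loglogistic_quantile(p, b: float, g50: float):
    """Thermal time at which the curve reaches proportion p.

    Closed form: t_p = g50 * ((1 - p) / p) ** (1 / b). Exactly g50 at p=0.5.
    """
    p_a = np.asarray(p, dtype=float)
    if np.any((p_a <= 0) | (p_a >= 1)):
        raise DomainError("p must lie strictly between 0 and 1")
    if b == 0:
        raise DegenerateSlopeError("quantile undefined for slope b = 0")
    if g50 <= 0:
        raise DomainError("g50 must be positive")
    out = g50 * ((1.0 - p_a) / p_a) ** (1.0 / b)
    return float(out) if np.isscalar(p) else out


@dataclass(frozen=True)
class QuantileEstimate:
    """An emergence quantile GERM100p with its 95% confidence interval."""

    p: float
    estimate: float
    ci_lo: float
    ci_hi: float
    se_log: float


@dataclass(frozen=True)
class EmergenceCounts:
    """Cumulative emergence counts for one observation unit (quadrat).

    ``times`` are inspection thermal times (strictly increasing, positive),
    ``cum_counts`` the cumulative number of seedlings observed emerged at
    each inspection (nondecreasing). ``n_sown`` enables the right-censored
    likelihood term for seeds never observed emerged; when None the final
    count is taken as the emerging population (conditional-on-emergence
    fit, reproducing 0-100% normalized curves).
    """

    unit_id: str
    times: tuple
    cum_counts: tuple
    n_sown: int | None = None
    species: str = ""
    crop: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.cum_counts, dtype=float)
        if t.ndim != 1 or t.shape != n.shape or len(t) < 2:
            raise InvalidRecordError(
                f"unit {self.unit_id}: need >=2 (time, count) inspections")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise InvalidRecordError(
                f"unit {self.unit_id}: inspection times must be positive and "
                "strictly increasing")
        if np.any(np.diff(n) < 0) or np.any(n < 0):
            raise InvalidRecordError(
                f"unit {self.unit_id}: cumulative counts must be nondecreasing")
        if self.n_sown is not None and n[-1] > self.n_sown:
            raise InvalidRecordError(
                f"unit {self.unit_id}: final count exceeds n_sown")


class EmergenceModel:
    """Maximum-likelihood log-logistic fit to grouped emergence counts.

    Parameters
    ----------
    units : sequence of EmergenceCounts
        Pooled observation units sharing one species x year grouping.
    use_censoring : bool
        If True, units with ``n_sown`` contribute a right-censored term
        (n_sown - final count) * ln[1 - E(t_last)]. Default False: the final
        observed count is treated as the emerging population.

    The likelihood is maximized over (b, ln GERM50); the covariance of that
    pair is the inverse observed information (numerical Hessian at the
    optimum).
    """

    def __init__(self, units: Sequence[EmergenceCounts], use_censoring: bool = False):
        if len(units) == 0:
            raise InsufficientDataError("no observation units")
        self.units = list(units)
        self.use_censoring = use_censoring
        self._cells = [self._unit_cells(u) for u in self.units]
        self._check_identifiable()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, use_censoring: bool = False
                       ) -> "EmergenceModel":
        """Build from a long frame with columns unit_id, cum_tt_c, cum_count
        and optionally n_sown, species, crop."""
        units = []
        for uid, g in df.groupby("unit_id", sort=True):
            g = g.sort_values("cum_tt_c")
            n_sown = None
            if "n_sown" in g.columns and g["n_sown"].notna().all():
                n_sown = int(g["n_sown"].iloc[0])
            units.append(EmergenceCounts(
                unit_id=str(uid),
                times=tuple(g["cum_tt_c"].astype(float)),
                cum_counts=tuple(g["cum_count"].astype(float)),
                n_sown=n_sown,
                species=str(g["species"].iloc[0]) if "species" in g.columns else "",
                crop=int(g["crop"].iloc[0]) if "crop" in g.columns else 0,
            ))
        return cls(units, use_censoring=use_censoring)

    # -- likelihood ---------------------------------------------------------

    def _unit_cells(self, unit: EmergenceCounts):
        """(times, interval counts, censored count) for one unit."""
        t = np.asarray(unit.times, dtype=float)
        n = np.asarray(unit.cum_counts, dtype=float)
        d = np.diff(np.concatenate(([0.0], n)))
        if self.use_censoring and unit.n_sown is not None:
            cens = float(unit.n_sown - n[-1])
        else:
            cens = 0.0
        return t, d, cens

    def _check_identifiable(self):
        nonzero = 0
        for t, d, cens in self._cells:
            nonzero += int(np.count_nonzero(d))
            nonzero += int(cens > 0)
        # distinct occupied interval cells across the pool; one cell means
        # the likelihood is flat along a ridge in (b, ln g50)
        occupied = set()
        for t, d, cens in self._cells:
            for j in np.nonzero(d)[0]:
                occupied.add(round(float(t[j]), 9))
            if cens > 0:
                occupied.add("censored")
        if len(occupied) < 2:
            raise UnidentifiableError(
                "all emergence falls in a single interval; (b, GERM50) are "
                "not jointly identifiable")
        if nonzero == 0:
            raise InsufficientDataError("no emergence observed in any unit")

    def nloglike(self, params) -> float:
        """Negative grouped log-likelihood at params = (b, ln g50)."""
        b, lg50 = params
        total = 0.0
        for t, d, cens in self._cells:
            cdf = 1.0 / (1.0 + np.exp(b * (np.log(t) - lg50)))
            probs = np.diff(np.concatenate(([0.0], cdf)))
            probs = np.clip(probs, 1e-300, None)
            total += float(np.dot(d, np.log(probs)))
            if cens > 0:
                total += cens * np.log(max(1.0 - cdf[-1], 1e-300))
        return -total

    # -- fitting ------------------------------------------------------------

    def _start_values(self):
        """Logit-linear regression of empirical cumulative proportions on ln t."""
        ts, logits = [], []
        for unit, (t, d, cens) in zip(self.units, self._cells):
            n = np.cumsum(d)
            total = n[-1] + cens
            if total <= 0:
                continue
            p = np.clip(n / total, 1e-3, 1 - 1e-3)
            interior = (p > 1e-3) & (p < 1 - 1e-3)
            # keep boundary-clipped points too if nothing interior
            sel = interior if interior.sum() >= 2 else np.ones_like(p, bool)
            ts.append(np.log(t[sel]))
            logits.append(np.log((1 - p[sel]) / p[sel]))
        x = np.concatenate(ts)
        y = np.concatenate(logits)
        if len(np.unique(x)) < 2:
            return np.array([-5.0, np.log(np.median(np.exp(x)))])
        slope, intercept = np.polyfit(x, y, 1)
        b0 = slope if slope != 0 else -5.0
        lg0 = -intercept / b0
        return np.array([b0, lg0])

    def fit(self, start=None, tol: float = 1e-8) -> "EmergenceResults":
        """Maximize the grouped likelihood; returns :class:`EmergenceResults`.

        Gradient-based (BFGS) optimization with a Nelder-Mead fallback, on
        the (b, ln g50) scale; covariance from the observed information.
        """
        x0 = np.asarray(start, float) if start is not None else self._start_values()
        res = optimize.minimize(self.nloglike, x0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        res2 = optimize.minimize(self.nloglike, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": tol,
                                          "maxiter": 4000})
        best = res2 if res2.fun <= res.fun else res
        if not (res.success or res2.success):
            raise ConvergenceError("emergence likelihood failed to converge",
                                   trace={"bfgs": res, "nelder_mead": res2})
        b_hat, lg50_hat = best.x
        flipped = False
        if b_hat > 0:
            # data imply a decreasing curve under the stored convention
            flipped = True
        hess = approx_hess1(best.x, self.nloglike)
        cov, psd = _safe_inverse(hess)
        nobs = float(sum(d.sum() + cens for _, d, cens in self._cells))
        return EmergenceResults(
            model=self, b=float(b_hat), log_g50=float(lg50_hat),
            cov_params_=cov, llf=-float(best.fun),
            converged=bool((res.success or res2.success) and psd),
            n_units=len(self.units), nobs=nobs, sign_flipped=flipped,
        )


def _safe_inverse(hess: np.ndarray):
    """Invert an observed-information matrix, flagging non-PD Hessians."""
    try:
        eigvals = np.linalg.eigvalsh(hess)
        psd = bool(np.all(eigvals > 0))
        cov = np.linalg.inv(hess) if psd else np.linalg.pinv(hess)
    except np.linalg.LinAlgError:
        cov, psd = np.full((2, 2), np.nan), False
    return cov, psd


@dataclass
class EmergenceResults:
    """Fitted log-logistic emergence curve.

    ``cov_params_`` is the covariance of (b, ln GERM50); GERM50's own
    standard error follows from the delta method, se(g50) = g50 * se(ln g50).
    """

    model: EmergenceModel = field(repr=False)
    b: float
    log_g50: float
    cov_params_: np.ndarray = field(repr=False)
    llf: float
    converged: bool
    n_units: int
    nobs: float
    sign_flipped: bool = False

    @property
    def g50(self) -> float:
        return float(np.exp(self.log_g50))

    @property
    def params(self) -> pd.Series:
        return pd.Series({"b": self.b, "g50": self.g50})

    @property
    def bse(self) -> pd.Series:
        se_b = float(np.sqrt(self.cov_params_[0, 0]))
        se_lg = float(np.sqrt(self.cov_params_[1, 1]))
        return pd.Series({"b": se_b, "g50": self.g50 * se_lg})

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov_params_, index=["b", "log_g50"],
                            columns=["b", "log_g50"])

    def predict(self, t):
        """Fitted cumulative emergence proportion at thermal time t."""
        return loglogistic_cdf(t, self.b, self.g50)

    def quantile(self, p: float, alpha: float = 0.05) -> QuantileEstimate:
        """GERM100p with a delta-method CI on the log scale.

        ln t_p = ln g50 + ln((1-p)/p) / b; the gradient with respect to
        (b, ln g50) is (-ln((1-p)/p)/b^2, 1).
        """
        t_p = loglogistic_quantile(p, self.b, self.g50)
        k = np.log((1.0 - p) / p)
        grad = np.array([-k / self.b ** 2, 1.0])
        var_log = float(grad @ self.cov_params_ @ grad)
        se_log = float(np.sqrt(max(var_log, 0.0)))
        z = stats.norm.ppf(1 - alpha / 2)
        return QuantileEstimate(
            p=float(p), estimate=float(t_p),
            ci_lo=float(t_p * np.exp(-z * se_log)),
            ci_hi=float(t_p * np.exp(z * se_log)),
            se_log=se_log,
        )

    def summary(self) -> str:
        q10, q50, q90 = (self.quantile(p) for p in (0.1, 0.5, 0.9))
        lines = [
            "Log-logistic emergence fit (grouped time-to-event ML)",
            f"  units: {self.n_units}   seedlings: {self.nobs:.0f}   "
            f"logL: {self.llf:.2f}   converged: {self.converged}",
            f"  b      = {self.b:8.3f}  (se {self.bse['b']:.3f})",
            f"  GERM50 = {self.g50:8.1f}  (se {self.bse['g50']:.1f})",
            f"  GERM10 = {q10.estimate:8.1f}  (95% CI {q10.ci_lo:.1f}-{q10.ci_hi:.1f})",
            f"  GERM90 = {q90.estimate:8.1f}  (95% CI {q90.ci_lo:.1f}-{q90.ci_hi:.1f})",
        ]
        if self.sign_flipped:
            lines.append("  warning: fitted slope positive; data imply a "
                         "decreasing curve under the stored sign convention")
        return "\n".join(lines)


def compare_parameters(result_a: EmergenceResults, result_b: EmergenceResults,
                       which: str = "g50", p: float | None = None
                       ) -> WaldTestResult:
    """Wald t-test comparing a parameter (or quantile) of two fits.

    ``which`` is one of ``"b"``, ``"g50"`` or ``"quantile"`` (the latter
    requiring ``p``). Quantiles are compared on the original (degree-day)
    scale using delta-method standard errors.
    """
    require_converged(result_a, result_b)
    if which == "b":
        return wald_compare(result_a.b, result_a.bse["b"],
                            result_b.b, result_b.bse["b"])
    if which == "g50":
        return wald_compare(result_a.g50, result_a.bse["g50"],
                            result_b.g50, result_b.bse["g50"])
    if which == "quantile":
        if p is None:
            raise ValueError("p is required for which='quantile'")
        qa, qb = result_a.quantile(p), result_b.quantile(p)
        return wald_compare(qa.estimate, qa.estimate * qa.se_log,
                            qb.estimate, qb.estimate * qb.se_log)
    raise ValueError(f"unknown parameter {which!r}")
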