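"""Sigmoid biomass-accumulation curves and crop-suppression ratios.

Per-plant dry matter Y as a function of thermal time t is fitted with one of
two three-parameter families:

* Weibull (Gompertz-type):  Y = d * exp(-exp(-c (ln t - ln e)))
* log-logistic:             Y = d / (1 + exp(c (ln t - ln TIME50)))

``d`` is the upper asymptote (total per-plant biomass, g), ``c`` the rate
parameter and the third parameter locates the curve on the thermal-time
axis. The Weibull rate is reported as a positive number while the curve is
kept increasing by applying the rate to ln e - ln t internally; the
log-logistic is increasing for c < 0, matching the sign convention of the
reported tables.

Fits are ordinary (homoscedastic) least squares on the original response
scale. :class:`GrowthResults` provides TIME50 (the half-biomass thermal
time; the fitted location for the log-logistic, e * ln(2)^(-1/c) for the
Weibull), a lack-of-fit F-test against the saturated one-mean-per-time
model, and :func:`suppression_ratio` compares total biomass d between
plants grown with and without a crop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._wald import require_converged
from .exceptions import (ConvergenceError, DomainError, InsufficientDataError)

__all__ = [
    "weibull_curve", "loglogistic_curve", "GrowthModel", "GrowthResults",
    "RatioEstimate", "suppression_ratio", "FAMILIES",
]

FAMILIES = ("weibull", "loglogistic")


def weibull_curve(t, c: float, d: float, e: float):
    """Increasing Weibull growth curve d*exp(-exp(-|c|(ln t - ln e))).

    Equals d/e^1 ~ 0.3679 d at t = e; tends to d as t grows and to 0 at 0+.
    The rate is used as |c| so the curve is increasing for either sign.
    """
    t_a = np.asarray(t, dtype=float)
    if np.any(t_a <= 0):
        raise DomainError("thermal time must be positive")
    if e <= 0:
        raise DomainError("scale parameter e must be positive")
    out = d * np.exp(-np.exp(-abs(c) * (np.log(t_a) - np.log(e))))
    return float(out) if np.isscalar(t) else out


def loglogistic_curve(t, c: float, d: float, t50: float):
    """Log-logistic growth curve d/(1+exp(c(ln t - ln t50))); increasing for c<0."""
    t_a = np.asarray(t, dtype=float)
    if np.any(t_a <= 0):
        raise DomainError("thermal time must be positive")
    if t50 <= 0:
        raise DomainError("t50 must be positive")
    out = d / (1.0 + np.exp(c * (np.log(t_a) - np.log(t50))))
    return float(out) if np.isscalar(t) else out


_CURVES = {"weibull": weibull_curve, "loglogistic": loglogistic_curve}
_TIMING_NAME = {"weibull": "e", "loglogistic": "t50"}


class GrowthModel:
    """Nonlinear least-squares biomass model for one species x treatment.

    Parameters
    ----------
    t, y : array-like
        Thermal times (degree C, positive) and per-plant dry matter (g,
        nonnegative), one row per destructive sample.
    family : str
        ``"weibull"`` or ``"loglogistic"``.
    """

    def __init__(self, t, y, family: str):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise InsufficientDataError("t and y must be 1-d arrays of equal length")
        if np.any(t <= 0):
            raise DomainError("thermal times must be positive")
        if np.any(y < 0):
            raise DomainError("biomass must be nonnegative")
        if len(np.unique(t)) < 4:
            raise InsufficientDataError(
                "need >=4 distinct sampling times for a 3-parameter curve")
        if np.all(y == 0):
            raise InsufficientDataError("all biomass values are zero")
        self.t, self.y, self.family = t, y, family
        self.curve = _CURVES[family]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, family: str) -> "GrowthModel":
        """Build from a frame with columns cum_tt_c and dm_per_plant_g."""
        return cls(df["cum_tt_c"].to_numpy(), df["dm_per_plant_g"].to_numpy(),
                   family)

    def _start_values(self):
        d0 = 1.05 * float(self.y.max())
        # half-biomass crossing of the per-time mean profile
        means = pd.Series(self.y).groupby(pd.Series(self.t)).mean()
        above = means[means >= d0 / 2]
        timing0 = float(above.index[0]) if len(above) else float(np.median(self.t))
        # rate is weakly identified from sparse schedules; coarse profile
        # over |c| with (d, timing) pinned picks a sensible basin
        sign = 1.0 if self.family == "weibull" else -1.0
        best_c, best_rss = sign * 5.0, np.inf
        for mag in (1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 18.0, 25.0):
            resid = self.y - self.curve(self.t, sign * mag, d0, timing0)
            rss = float(resid @ resid)
            if rss < best_rss:
                best_c, best_rss = sign * mag, rss
        return np.array([best_c, d0, timing0])

    def fit(self, start=None) -> "GrowthResults":
        """Least-squares fit; asymptotic covariance from the Jacobian."""
        p0 = np.asarray(start, float) if start is not None else self._start_values()

        def f(t, c, d, timing):
            return self.curve(t, c, d, timing)

        try:
            popt, pcov = optimize.curve_fit(
                f, self.t, self.y, p0=p0, maxfev=20000,
                bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]))
        except (RuntimeError, optimize.OptimizeWarning) as err:
            raise ConvergenceError(f"growth fit failed: {err}") from err
        c, d, timing = popt
        if self.family == "weibull":
            c = abs(c)  # reported positive; curve is sign-symmetric in c
        resid = self.y - f(self.t, *popt)
        rss = float(resid @ resid)
        df_resid = len(self.y) - 3
        converged = bool(np.all(np.isfinite(pcov)))
        return GrowthResults(
            model=self, family=self.family,
            params_=np.array([c, d, timing]), cov_params_=pcov,
            rss=rss, df_resid=df_resid, converged=converged)


@dataclass
class GrowthResults:
    """Fitted biomass curve with least-squares diagnostics."""

    model: GrowthModel = field(repr=False)
    family: str
    params_: np.ndarray
    cov_params_: np.ndarray = field(repr=False)
    rss: float
    df_resid: int
    converged: bool

    @property
    def c(self) -> float:
        return float(self.params_[0])

    @property
    def d(self) -> float:
        return float(self.params_[1])

    @property
    def timing(self) -> float:
        """Location parameter: t50 (log-logistic) or scale e (Weibull)."""
        return float(self.params_[2])

    @property
    def params(self) -> pd.Series:
        return pd.Series({"c": self.c, "d": self.d,
                          _TIMING_NAME[self.family]: self.timing})

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov_params_))
        return pd.Series({"c": se[0], "d": se[1],
                          _TIMING_NAME[self.family]: se[2]})

    def predict(self, t):
        return self.model.curve(t, *self.params_)

    def time50(self) -> float:
        """Thermal time at which the curve reaches d/2.

        Identity for the log-logistic; for the Weibull the closed form is
        e * ln(2)^(-1/|c|) (so TIME50 > e since ln 2 < 1).
        """
        if self.family == "loglogistic":
            return self.timing
        return float(self.timing * np.log(2.0) ** (-1.0 / abs(self.c)))

    def lack_of_fit(self):
        """F-test of the curve against the saturated one-mean-per-time model.

        Returns (F, p). Requires replicate observations at shared times;
        p > 0.05 is read as model adequacy.
        """
        t, y = self.model.t, self.model.y
        df_frame = pd.DataFrame({"t": t, "y": y})
        groups = df_frame.groupby("t")["y"]
        n_times = groups.ngroups
        df_pe = len(y) - n_times            # pure error df
        if df_pe <= 0:
            raise InsufficientDataError(
                "lack-of-fit test needs replicate measurements at shared times")
        df_lof = n_times - 3                 # saturated vs 3-parameter curve
        if df_lof <= 0:
            raise InsufficientDataError(
                "lack-of-fit test needs more distinct times than parameters")
        sse_sat = float(((df_frame["y"] - groups.transform("mean")) ** 2).sum())
        ss_lof = self.rss - sse_sat
        f_stat = (ss_lof / df_lof) / (sse_sat / df_pe) if sse_sat > 0 else np.inf
        p = float(stats.f.sf(f_stat, df_lof, df_pe))
        return float(f_stat), p

    def summary(self) -> str:
        name = _TIMING_NAME[self.family]
        return "\n".join([
            f"{self.family.capitalize()} growth fit (least squares)",
            f"  n: {len(self.model.y)}   RSS: {self.rss:.3f}   "
            f"converged: {self.converged}",
            f"  c      = {self.c:9.2f}  (se {self.bse['c']:.2f})",
            f"  d      = {self.d:9.2f} g (se {self.bse['d']:.2f})",
            f"  {name:<6} = {self.timing:9.1f}  (se {self.bse[name]:.1f})",
            f"  TIME50 = {self.time50():9.1f} degree C",
        ])


@dataclass(frozen=True)
class RatioEstimate:
    """A +crop / -crop suppression ratio with delta-method uncertainty.

    Ratios below 1 indicate suppression by the crop; the Wald test is of
    ratio = 1.
    """

    ratio: float
    se: float
    ci_lo: float
    ci_hi: float
    pvalue: float


def suppression_ratio(result_minus: GrowthResults,
                      result_plus: GrowthResults) -> RatioEstimate:
    """Ratio of total biomass d (+crop over -crop) between two fits.

    First-order delta method from the two independent d standard errors:
    se(r) = r * sqrt((se_plus/d_plus)^2 + (se_minus/d_minus)^2); two-sided
    Wald test of ratio = 1 against a normal reference.
    """
    require_converged(result_minus, result_plus)
    d_m, d_p = result_minus.d, result_plus.d
    if d_m <= 0:
        raise DomainError("denominator (no-crop) total biomass must be positive")
    se_m, se_p = result_minus.bse["d"], result_plus.bse["d"]
    ratio = d_p / d_m
    se = abs(ratio) * float(np.hypot(se_p / d_p if d_p != 0 else 0.0,
                                     se_m / d_m))
    z = (ratio - 1.0) / se if se > 0 else (0.0 if ratio == 1.0 else np.inf)
    pvalue = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    return RatioEstimate(ratio=float(ratio), se=float(se),
                         ci_lo=float(ratio - half), ci_hi=float(ratio + half),
                         pvalue=pvalue)
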