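"""Hyperbolic target-neighborhood competition model.

In a target-neighborhood pot experiment a single target weed grows amid
winter wheat neighbors at density x (plants per square metre). Its response
Y (dry matter or estimated seed production) declines hyperbolically:

    Y = a / (1 + x / DENS50)

where ``a`` is the response of the target growing alone and ``DENS50`` the
wheat density that halves it. Larger DENS50 means a more competitive weed
(more wheat needed to suppress it).

The fit is homoscedastic least squares with DENS50 optimized on the log
scale to enforce positivity; DENS50 comparisons across species, crop stages
or harvests use the shared Wald machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._wald import WaldTestResult, require_converged, wald_compare
from .exceptions import (ConvergenceError, DomainError, InsufficientDataError,
                         UnidentifiableError)

__all__ = [
    "hyperbolic_curve", "HyperbolicModel", "HyperbolicResults",
    "compare_dens50", "PAPER_DENSITIES",
]

#: Wheat densities (plants per m^2) of the reference pot design
#: (0, 2, 4, 8, 12, 24 plants in a 23-cm pot).
PAPER_DENSITIES = (0.0, 48.0, 96.0, 192.0, 288.0, 576.0)

# fitted dens50 beyond this multiple of the largest design density is
# treated as divergent (flat response)
_DIVERGENCE_FACTOR = 1e4


def hyperbolic_curve(x, a: float, dens50: float):
    """Rectangular-hyperbola response a / (1 + x/DENS50).

    Equals a at x = 0, a/2 at x = DENS50 and a/4 at x = 3 DENS50; strictly
    decreasing and convex in x.
    """
    x_a = np.asarray(x, dtype=float)
    if np.any(x_a < 0):
        raise DomainError("neighbor density must be nonnegative")
    if dens50 <= 0:
        raise DomainError("DENS50 must be positive")
    out = a / (1.0 + x_a / dens50)
    return float(out) if np.isscalar(x) else out


class HyperbolicModel:
    """Least-squares hyperbolic competition model.

    Parameters
    ----------
    x : array-like
        Neighbor (wheat) densities, plants/m^2, nonnegative.
    y : array-like
        Target-plant responses (g dry matter or seeds), nonnegative.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise InsufficientDataError("x and y must be equal-length 1-d arrays")
        if np.any(x < 0):
            raise DomainError("densities must be nonnegative")
        if np.any(y < 0):
            raise DomainError("responses must be nonnegative")
        if len(x) < 4:
            raise InsufficientDataError("need at least 4 observations")
        if len(np.unique(x)) < 2:
            raise UnidentifiableError(
                "a single neighbor density cannot identify (a, DENS50)")
        self.x, self.y = x, y

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "HyperbolicModel":
        """Build from a pot frame with columns density_m2 and response."""
        return cls(df["density_m2"].to_numpy(), df["response"].to_numpy())

    def _start_values(self):
        x, y = self.x, self.y
        x0 = x.min()
        a0 = float(y[x == x0].mean())
        if a0 <= 0:
            a0 = max(float(y.mean()), 1e-6)
        # density whose mean response is nearest a0/2
        means = pd.Series(y).groupby(pd.Series(x)).mean()
        pos = means[means.index > 0]
        if len(pos):
            d0 = float(pos.index[np.argmin(np.abs(pos.to_numpy() - a0 / 2))])
        else:
            d0 = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
        if d0 <= 0:
            d0 = 1.0
        return a0, d0

    def fit(self, start=None) -> "HyperbolicResults":
        """Least squares over (a, ln DENS50); covariance from the Jacobian."""
        if start is not None:
            a0, d0 = start
        else:
            a0, d0 = self._start_values()
        x, y = self.x, self.y
        xmax = max(x.max(), 1.0)
        upper_ld = np.log(_DIVERGENCE_FACTOR * xmax)

        def resid(theta):
            a, ld = theta
            return y - a / (1.0 + x / np.exp(ld))

        sol = optimize.least_squares(
            resid, x0=[a0, np.log(d0)],
            bounds=([0.0, np.log(1e-9)], [np.inf, upper_ld]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if not sol.success:
            raise ConvergenceError("hyperbolic fit failed to converge", trace=sol)
        a_hat, ld_hat = sol.x
        r = sol.fun
        dof = len(y) - 2
        s2 = float(r @ r) / dof if dof > 0 else np.nan
        jtj = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            finite_cov = bool(np.all(np.isfinite(cov)))
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
            finite_cov = False
        diverged = ld_hat >= upper_ld - 1e-6
        return HyperbolicResults(
            model=self, a=float(a_hat), log_dens50=float(ld_hat),
            cov_params_=cov, rss=float(r @ r), df_resid=dof,
            converged=bool(sol.success and finite_cov and not diverged))


@dataclass
class HyperbolicResults:
    """Fitted hyperbolic competition curve.

    ``cov_params_`` is the covariance of (a, ln DENS50); the DENS50
    standard error is delta-method, se = DENS50 * se(ln DENS50).
    """

    model: HyperbolicModel = field(repr=False)
    a: float
    log_dens50: float
    cov_params_: np.ndarray = field(repr=False)
    rss: float
    df_resid: int
    converged: bool

    @property
    def dens50(self) -> float:
        return float(np.exp(self.log_dens50))

    @property
    def params(self) -> pd.Series:
        return pd.Series({"a": self.a, "dens50": self.dens50})

    @property
    def bse(self) -> pd.Series:
        se_a = float(np.sqrt(self.cov_params_[0, 0]))
        se_ld = float(np.sqrt(self.cov_params_[1, 1]))
        return pd.Series({"a": se_a, "dens50": self.dens50 * se_ld})

    def predict(self, x):
        return hyperbolic_curve(x, self.a, self.dens50)

    def summary(self) -> str:
        return "\n".join([
            "Hyperbolic competition fit (least squares)",
            f"  n: {len(self.model.y)}   RSS: {self.rss:.3f}   "
            f"converged: {self.converged}",
            f"  a      = {self.a:8.2f}  (se {self.bse['a']:.2f})",
            f"  DENS50 = {self.dens50:8.1f} plants/m^2 (se {self.bse['dens50']:.1f})",
        ])


def compare_dens50(result_a: HyperbolicResults,
                   result_b: HyperbolicResults) -> WaldTestResult:
    """Wald t-test of equal DENS50 between two independent fits."""
    require_converged(result_a, result_b)
    return wald_compare(result_a.dens50, result_a.bse["dens50"],
                        result_b.dens50, result_b.bse["dens50"])
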