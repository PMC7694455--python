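"""Shared Wald-type comparison of two independently fitted parameters."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConvergenceError


@dataclass(frozen=True)
class WaldTestResult:
    """Two-sample Wald test of equality of two independent estimates.

    The statistic is (estimate_a - estimate_b) / sqrt(se_a^2 + se_b^2) with a
    standard-normal reference, i.e. the large-sample t-test used for post-hoc
    comparison of nonlinear regression parameters.
    """

    estimate_a: float
    estimate_b: float
    difference: float
    se: float
    statistic: float
    pvalue: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WaldTestResult(diff={self.difference:.4g}, se={self.se:.4g}, "
            f"z={self.statistic:.3f}, p={self.pvalue:.4g})"
        )


def wald_compare(estimate_a: float, se_a: float,
                 estimate_b: float, se_b: float) -> WaldTestResult:
    """Wald test of ``estimate_a == estimate_b`` for independent fits."""
    se = float(np.hypot(se_a, se_b))
    diff = float(estimate_a - estimate_b)
    if se == 0.0:
        # identical degenerate SEs: equal estimates -> no evidence at all
        stat = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        stat = diff / se
    p = float(2.0 * stats.norm.sf(abs(stat)))
    return WaldTestResult(float(estimate_a), float(estimate_b), diff, se,
                          float(stat), p)


def require_converged(*results) -> None:
    """Raise ConvergenceError if any input fit did not converge."""
    for r in results:
        if not getattr(r, "converged", True):
            raise ConvergenceError(
                "comparison requires converged fits; got a non-converged input")
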