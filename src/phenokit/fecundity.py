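"""Seed-production estimation from panicle length and suppression tests.

Counting every seed on every plant is infeasible, so fecundity is estimated
indirectly: seeds are counted on a calibration sample of panicles (or seed
heads) of known length, a straight line of seed count on length is fitted
per species, and each plant's seed production is the sum of the predicted
counts over its panicle inventory (negative per-panicle predictions clamp
to zero; the plant total is rounded to the nearest seed).

Crop suppression of fecundity is expressed as the ratio of mean seeds per
plant with crop over without, tested by a label-permutation test on the
group mean difference and accompanied by a percentile-bootstrap CI of the
ratio (plants resampled within group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DomainError, InsufficientDataError

__all__ = [
    "SeedCalibration", "calibrate", "estimate_plant", "mean_seed_production",
    "fecundity_ratio_test", "FecundityRatio",
]


@dataclass(frozen=True)
class SeedCalibration:
    """Fitted seeds-on-length regression line for one species."""

    species: str
    slope: float       # seeds per cm
    intercept: float   # seeds
    r_squared: float
    n: int

    def predict(self, length_cm):
        """Predicted seeds for a single panicle, clamped at zero."""
        raw = self.slope * np.asarray(length_cm, dtype=float) + self.intercept
        return np.maximum(raw, 0.0)


def calibrate(lengths_cm, seed_counts, species: str = "") -> SeedCalibration:
    """OLS line of counted seeds on panicle length.

    Requires >= 3 records over >= 2 distinct lengths. R^2 is the ordinary
    coefficient of determination (equal to the squared Pearson correlation
    of the two variables for a straight-line fit).
    """
    x = np.asarray(lengths_cm, dtype=float)
    y = np.asarray(seed_counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("lengths and seed counts must be equal-length 1-d arrays")
    if np.any(x <= 0):
        raise DomainError("panicle lengths must be positive")
    if np.any(y < 0):
        raise DomainError("seed counts must be nonnegative")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 calibration records")
    if len(np.unique(x)) < 2:
        raise InsufficientDataError("all panicle lengths equal; line is rank-deficient")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SeedCalibration(species=species, slope=float(res.params[1]),
                           intercept=float(res.params[0]),
                           r_squared=float(res.rsquared), n=len(x))


def estimate_plant(calibration: SeedCalibration, lengths_cm) -> int:
    """Estimated seeds for one plant from its panicle-length inventory.

    Sum of per-panicle clamped predictions, rounded to the nearest integer
    at the plant level. An empty inventory gives zero (with a warning).
    """
    lengths = np.asarray(lengths_cm, dtype=float)
    if lengths.size == 0:
        warnings.warn("plant has no panicles; estimated seed production is 0",
                      stacklevel=2)
        return 0
    return int(round(float(calibration.predict(lengths).sum())))


def mean_seed_production(seed_counts) -> float:
    """Arithmetic mean seeds per plant over a collection of plants."""
    values = np.asarray(seed_counts, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("no plants")
    return float(values.mean())


@dataclass(frozen=True)
class FecundityRatio:
    """Crop-suppression ratio of mean seed production with inference.

    ``ratio`` = mean(+crop) / mean(-crop); ``pvalue`` from the permutation
    test of equal group means (add-one estimator); ``ci_lo``/``ci_hi`` a
    percentile-bootstrap interval of the ratio.
    """

    mean_minus: float
    mean_plus: float
    ratio: float
    pvalue: float
    ci_lo: float
    ci_hi: float
    n_perm: int
    n_boot: int
    seed: int | None = None


def fecundity_ratio_test(seeds_minus, seeds_plus, n_perm: int = 1000,
                         n_boot: int = 10000, coverage: float = 0.95,
                         rng: np.random.Generator | None = None,
                         seed: int | None = None) -> FecundityRatio:
    """Permutation test + bootstrap CI for the +crop/-crop fecundity ratio.

    The permutation test permutes plant labels between the two groups and
    compares |mean difference|; the bootstrap resamples plants with
    replacement within each group and takes the percentile interval of the
    resampled ratio of means. Permutation and bootstrap use independent
    RNG substreams spawned from the caller's generator.
    """
    x_m = np.asarray(seeds_minus, dtype=float)
    x_p = np.asarray(seeds_plus, dtype=float)
    if x_m.size == 0 or x_p.size == 0:
        raise InsufficientDataError("both groups must be nonempty")
    mean_m, mean_p = float(x_m.mean()), float(x_p.mean())
    if mean_m == 0:
        raise DomainError("no-crop group mean is zero; ratio undefined")
    ratio = mean_p / mean_m

    if rng is None:
        rng = np.random.default_rng(seed)
    perm_rng, boot_rng = rng.spawn(2)

    pooled = np.concatenate([x_m, x_p])
    n_m, n_p = len(x_m), len(x_p)
    s_obs = abs(mean_m - mean_p)
    perms = perm_rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    s = np.abs(perms[:, :n_m].mean(axis=1) - perms[:, n_m:].mean(axis=1))
    tol = 1e-9 * (1.0 + s_obs)  # count exact-tie permutations as extreme
    pvalue = (1 + int(np.sum(s >= s_obs - tol))) / (1 + n_perm)

    bm = x_m[boot_rng.integers(0, n_m, size=(n_boot, n_m))].mean(axis=1)
    bp = x_p[boot_rng.integers(0, n_p, size=(n_boot, n_p))].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(bm != 0, bp / bm, np.nan)
    alpha = 1.0 - coverage
    lo, hi = np.nanquantile(ratios, [alpha / 2, 1 - alpha / 2])
    return FecundityRatio(mean_minus=mean_m, mean_plus=mean_p,
                          ratio=float(ratio), pvalue=float(pvalue),
                          ci_lo=float(lo), ci_hi=float(hi),
                          n_perm=n_perm, n_boot=n_boot, seed=seed)


def parse_length_list(text: str) -> np.ndarray:
    """Parse a semicolon-joined panicle-length field from the plant CSV.

    Empty fields (including the NaN a zero-panicle plant round-trips to
    through pandas) give an empty inventory.
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return np.array([], dtype=float)
    text = str(text).strip()
    if not text or text.lower() == "nan":
        return np.array([], dtype=float)
    return np.array([float(v) for v in text.split(";") if v.strip() != ""])
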