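"""Independent oracles shared by the test suite.

These are deliberately naive implementations (enumeration, brute-force
loops, textbook formulas) kept separate from the package code paths they
check.
"""

from itertools import combinations

import numpy as np


def exhaustive_permutation_p(x, y, tol: float = 1e-12) -> float:
    """Exact two-sided permutation p-value by enumerating all label splits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n_a = len(pooled), len(x)
    s_obs = abs(x.mean() - y.mean())
    count = total = 0
    for idx in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        s = abs(pooled[mask].mean() - pooled[~mask].mean())
        total += 1
        if s >= s_obs - tol:
            count += 1
    return count / total


def textbook_percentile_bootstrap(x, n_boot: int, seed: int,
                                  coverage: float = 0.95):
    """Plain percentile bootstrap of a mean, on phenokit's resampling stream.

    Draws the resampling index matrix from the first child stream spawned
    from ``seed`` (the contract phenokit's interval bootstrap documents), so
    with point data the two procedures see identical resamples.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    boot_rng, _ = np.random.default_rng(seed).spawn(2)
    idx = boot_rng.integers(0, n, size=(n_boot, n))
    means = x[idx].mean(axis=1)
    alpha = 1.0 - coverage
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(means.mean()), float(lo), float(hi)


def daily_loop_accumulation(tmin, tmax, base: float = 1.0) -> np.ndarray:
    """Brute-force day-by-day cumulative degree days."""
    out = []
    total = 0.0
    for lo, hi in zip(tmin, tmax):
        mean = (lo + hi) / 2.0
        total += max(0.0, mean - base)
        out.append(total)
    return np.array(out)


def grid_search_ml(nloglike, b_grid, logg50_grid):
    """Coarse grid-search maximum-likelihood oracle over (b, ln g50)."""
    best, best_val = None, np.inf
    for b in b_grid:
        for lg in logg50_grid:
            val = nloglike((b, lg))
            if val < best_val:
                best, best_val = (b, lg), val
    return np.array(best), best_val
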