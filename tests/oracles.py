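"""Independent oracles used by the test suite.

Each function here re-derives an expected result by brute force, enumeration
or direct event-level simulation, without touching the implementation paths
it is used to check.
"""

import numpy as np
from scipy import stats


def full_affine_dp_score(read: str, ref: str, match=1.0, mismatch=-1.0,
                         gap_open=-3.0, gap_ext=-1.0) -> float:
    """Unbanded three-state affine-gap global alignment, score only."""
    m, n = len(read), len(ref)
    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = gap_open + (i - 1) * gap_ext
    for j in range(1, n + 1):
        Y[0, j] = gap_open + (j - 1) * gap_ext
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1],
                              Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_ext,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_ext,
                          X[i, j - 1] + gap_open)
    return float(max(M[m, n], X[m, n], Y[m, n]))


def simulate_ld_counts(m: float, n_cultures: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Event-level Luria-Delbrück culture counts.

    Mutations arise as Poisson(m) events, each while the (exponentially
    growing) population is at a uniform random fraction u of its final size;
    the resulting clone contributes floor(1/u) mutant cells, giving clone
    sizes j with probability 1/(j(j+1)).
    """
    counts = np.zeros(n_cultures, dtype=np.int64)
    n_mut = rng.poisson(m, n_cultures)
    for i, k in enumerate(n_mut):
        if k:
            u = rng.uniform(size=k)
            counts[i] = int(np.floor(1.0 / u).sum())
    return counts


def clopper_pearson_by_inversion(k: int, n: int, alpha: float = 0.05):
    """Exact binomial interval by direct tail inversion (no Beta quantiles):
    the bounds are the p solving the binomial tail equations."""
    from scipy.optimize import brentq

    if k == 0:
        lo = 0.0
    else:
        lo = brentq(
            lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 1e-12,
            1 - 1e-12,
        )
    if k == n:
        hi = 1.0
    else:
        hi = brentq(
            lambda p: stats.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12
        )
    return lo, hi


def grid_search_m(counts, ld_pmf, lo=0.0, hi=5.0, step=1e-3) -> float:
    """Brute-force maximiser of the Luria-Delbrück joint likelihood."""
    counts = np.asarray(counts)
    k_max = int(counts.max()) + 10
    grid = np.arange(max(lo, step), hi, step)
    best_m, best_ll = 0.0, -np.inf
    for m in grid:
        p = ld_pmf(m, k_max)
        ll = float(np.sum(np.log(np.maximum(p[counts], 1e-300))))
        if ll > best_ll:
            best_ll, best_m = ll, m
    if np.all(counts == 0):
        return 0.0
    return best_m
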