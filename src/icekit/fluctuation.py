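"""Per-cell transposition/mutation rates from plating counts.

Two estimation routes, matching the two induction regimes:

* ``mss_mle`` — Luria–Delbrück fluctuation analysis of low-density cultures
  via the Ma–Sandri–Sarkar (MSS) maximum-likelihood method. The observed
  colony counts across parallel cultures follow the Luria–Delbrück
  distribution, whose probability mass is computed by the MSS recursion; the
  expected number of mutational events per culture, m, is found by maximising
  the joint log-likelihood, with a profile-likelihood 95% interval.
* ``direct_frequency`` — high-density inductions where growth during exposure
  is negligible: the per-cell frequency is simply the mean plated-corrected
  colony count over the number of exposed cells.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import optimize, stats

from .types import ColonyCountTable, RateEstimate

_LOG_FLOOR = 1e-300
_CHI2_95_HALF = 1.9207  # chi-square(1) 95% quantile / 2, profile-CI drop


@njit(cache=True)
def _ld_pmf_kernel(m: float, k_max: int) -> np.ndarray:
    p = np.zeros(k_max + 1)
    p[0] = np.exp(-m)
    for k in range(1, k_max + 1):
        acc = 0.0
        for i in range(k):
            acc += p[i] / (k - i + 1)
        p[k] = (m / k) * acc
    return p


def ld_pmf(m: float, k_max: int) -> np.ndarray:
    """Luria–Delbrück probabilities p_0..p_k_max via the MSS recursion.

    p_0 = exp(-m);  p_k = (m/k) * sum_{i=0}^{k-1} p_i / (k - i + 1).
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    return _ld_pmf_kernel(float(m), int(k_max))


def _log_likelihood(m: float, counts: np.ndarray, k_max: int,
                    n_censored: int = 0) -> float:
    """Joint log-likelihood; ``n_censored`` replicates observed >= k_max+1
    enter through the right-tail probability (jackpot censoring)."""
    if m == 0:
        if n_censored or np.any(counts > 0):
            return -np.inf
        return 0.0
    p = ld_pmf(m, k_max)
    ll = float(np.sum(np.log(np.maximum(p[counts], _LOG_FLOOR))))
    if n_censored:
        tail = max(1.0 - float(p.sum()), _LOG_FLOOR)
        ll += n_censored * np.log(tail)
    return ll


def mss_mle(
    table: ColonyCountTable,
    *,
    correct_plating: bool = True,
    tol: float = 1e-6,
    k_cap: int = 512,
) -> RateEstimate:
    """MSS maximum-likelihood estimate of m with a profile-likelihood CI.

    Requires >= 2 low-density replicates. When the cultures were only
    partially plated and ``correct_plating`` is on, the estimate obtained on
    the observed counts is rescaled by ``plating_correction``. Jackpot
    replicates with more than ``k_cap`` colonies are censored at the cap
    (they contribute P(K > k_cap)), which bounds the O(k^2) recursion cost
    without biasing the estimate.
    """
    if table.mode != "low_density":
        raise ValueError("mss_mle requires low_density colony counts")
    counts = np.asarray(table.selective_count, dtype=np.int64)
    if len(counts) < 2:
        raise ValueError("need at least 2 replicate cultures")

    # censor jackpots at k_cap, but always keep the smallest count exact so
    # the likelihood retains a finite maximum
    k_max = int(min(counts.max(), max(k_cap, counts.min()))) + 10
    n_censored = int(np.sum(counts > k_max))
    counts = counts[counts <= k_max]

    if np.all(counts == 0) and n_censored == 0:
        # Only an upper bound is identifiable: LL(m) - LL(0) = -m*R.
        r = len(counts)
        m_hi = _CHI2_95_HALF / r
        m_hat, m_lo = 0.0, 0.0
    else:
        def nll(m):
            return -_log_likelihood(m, counts, k_max, n_censored)

        mean = np.concatenate([counts, [k_max] * n_censored]).mean()
        hi = max(5.0 * mean + 5.0, 30.0)
        # coarse log-grid bracket first: the likelihood is unimodal but can
        # plateau at the underflow floor for large m, which traps a plain
        # golden-section search
        grid = np.geomspace(1e-3, hi, 80)
        vals = np.array([nll(m) for m in grid])
        best = int(np.argmin(vals))
        lo_b = grid[best - 1] if best > 0 else 1e-9
        hi_b = grid[best + 1] if best < len(grid) - 1 else hi
        res = optimize.minimize_scalar(
            nll, bounds=(lo_b, hi_b), method="bounded",
            options={"xatol": tol},
        )
        if not res.success:
            raise RuntimeError(f"MSS likelihood maximisation failed: {res}")
        m_hat = float(res.x)
        # Tie-break toward smaller m on an exactly flat likelihood plateau
        # (bounded scan; smooth likelihoods stop immediately).
        for _ in range(100):
            if m_hat > tol and nll(m_hat - tol) == nll(m_hat):
                m_hat -= tol
            else:
                break
        ll_max = -nll(m_hat)

        def drop(m):
            return (
                _log_likelihood(m, counts, k_max, n_censored)
                - (ll_max - _CHI2_95_HALF)
            )

        lo_bracket = 1e-12
        if drop(lo_bracket) >= 0:
            m_lo = 0.0
        else:
            m_lo = float(optimize.brentq(drop, lo_bracket, m_hat))
        hi_bracket = max(2 * m_hat, 1.0)
        while drop(hi_bracket) > 0:
            hi_bracket *= 2
            if hi_bracket > 1e6:
                raise RuntimeError("profile CI upper bound did not bracket")
        m_hi = float(optimize.brentq(drop, m_hat, hi_bracket))

    fractions = np.unique(table.plating_fraction)
    scale = 1.0
    if correct_plating and not np.allclose(fractions, 1.0):
        if len(fractions) != 1:
            raise ValueError(
                "plating correction requires a common plating fraction"
            )
        scale = 1.0 / float(fractions[0])
    m_hat, m_lo, m_hi = m_hat * scale, m_lo * scale, m_hi * scale

    return RateEstimate(
        rate=m_hat,
        ci_low=m_lo,
        ci_high=m_hi,
        method="mss_mle",
        m=m_hat,
        m_ci_low=m_lo,
        m_ci_high=m_hi,
        divisor_mode="none",
    )


def plating_correction(m_observed: float, plating_fraction: float,
                       *, method: str = "simple",
                       enabled: bool = True) -> float:
    """Rescale m estimated from a partial plating to the whole culture.

    ``simple`` divides by the fraction (near-unbiased for gentle thinning,
    increasingly anticonservative below ~50% plating); ``stewart`` applies
    the classical m_obs * (f - 1) / (f ln f) correction for strong
    thinning. The chosen method should be reported alongside the estimate.
    """
    if not 0 < plating_fraction <= 1:
        raise ValueError("plating_fraction must lie in (0,1]")
    if not enabled or plating_fraction == 1.0:
        return m_observed
    if method == "simple":
        return m_observed / plating_fraction
    if method == "stewart":
        f = plating_fraction
        return m_observed * (f - 1.0) / (f * np.log(f))
    raise ValueError(f"unknown plating correction method {method!r}")


def rate_from_m(
    estimate: RateEstimate,
    n_final: float,
    divisor_mode: str = "days",
    elapsed: float = 3.0,
) -> RateEstimate:
    """Convert an m-estimate into a per-cell rate.

    rate = m / n_final, further divided by ``elapsed`` generations or days
    depending on ``divisor_mode`` (``none`` leaves the per-cell frequency).
    The divisor convention is always recorded in the result because the two
    normalisations differ materially.
    """
    if n_final <= 0:
        raise ValueError("n_final must be positive")
    if divisor_mode not in ("generations", "days", "none"):
        raise ValueError(f"unknown divisor_mode {divisor_mode!r}")
    if divisor_mode == "none":
        divisor = 1.0
    else:
        if elapsed <= 0:
            raise ValueError("elapsed must be positive")
        divisor = float(elapsed)
    if estimate.m is None:
        raise ValueError("estimate does not carry m (not an MSS result)")
    scale = 1.0 / (n_final * divisor)
    return RateEstimate(
        rate=estimate.m * scale,
        ci_low=estimate.m_ci_low * scale,
        ci_high=estimate.m_ci_high * scale,
        method=estimate.method,
        m=estimate.m,
        m_ci_low=estimate.m_ci_low,
        m_ci_high=estimate.m_ci_high,
        divisor_mode=divisor_mode,
        divisor=divisor,
    )


def direct_frequency(
    table: ColonyCountTable,
    *,
    ci_method: str = "t",
    alpha: float = 0.05,
) -> RateEstimate:
    """Per-cell transposition frequency from high-density platings.

    frequency = mean(selective_count / plating_fraction) / total_cells.
    The default CI is a t-interval over replicate frequencies; the exact
    binomial (Clopper–Pearson) interval on the pooled counts is available
    with ``ci_method='clopper-pearson'``.
    """
    if table.mode != "high_density":
        raise ValueError("direct_frequency requires high_density counts")
    if np.any(table.total_cells <= 0):
        raise ValueError("total_cells must be positive")
    freqs = (
        table.selective_count / table.plating_fraction
    ) / table.total_cells
    mean = float(freqs.mean())

    if ci_method == "t":
        n = len(freqs)
        if n >= 2 and freqs.std(ddof=1) > 0:
            half = stats.t.ppf(1 - alpha / 2, n - 1) * freqs.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        lo, hi = max(0.0, mean - half), mean + half
    elif ci_method == "clopper-pearson":
        from .spectrum import clopper_pearson

        k = int(table.selective_count.sum())
        n_trials = int(round((table.total_cells * table.plating_fraction).sum()))
        lo, hi = clopper_pearson(k, n_trials, alpha)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return RateEstimate(
        rate=mean,
        ci_low=min(lo, mean),
        ci_high=max(hi, mean),
        method="direct",
        divisor_mode="none",
    )
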