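"""Growth-curve statistics and nonparametric library comparisons.

``fit_growth_curve`` extracts the maximum specific growth rate (max sliding-
window slope of ln OD), the lag time (tangent construction) and the maximum
smoothed OD from an OD time series. ``mann_whitney_u`` and
``fishers_method`` provide the rank test and p-value combination used to
compare mutant libraries; ``compare_libraries`` applies them across group
pairs, metrics and conditions.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal, stats

from .types import GrowthStats, ODSeries


def fit_growth_curve(
    series: ODSeries,
    window_points: int = 9,
    od_floor: float = 1e-4,
    flat_slope: float = 1e-3,
) -> GrowthStats:
    """Growth statistics from one OD600 curve.

    mu_max is the maximum slope over sliding ``window_points``-point
    least-squares fits to ln(OD); the lag time is where the tangent at the
    max-slope window meets the initial OD level; od_max is the maximum of
    the median-smoothed curve. A curve whose best slope is below
    ``flat_slope`` (1/h) is reported as non-growing: mu_max 0, lag NaN.
    """
    t = series.time_h
    od = series.corrected_od(floor=od_floor)
    n = len(t)
    if n < window_points:
        raise ValueError(
            f"need at least window_points={window_points} samples, got {n}"
        )
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    ln_od = np.log(od)

    w = window_points
    slopes = np.empty(n - w + 1)
    intercepts = np.empty(n - w + 1)
    for i in range(n - w + 1):
        tt = t[i:i + w]
        yy = ln_od[i:i + w]
        slope, intercept = np.polyfit(tt, yy, 1)
        slopes[i] = slope
        intercepts[i] = intercept

    smooth = signal.medfilt(od, kernel_size=min(5, n - (n + 1) % 2))
    od_max = float(smooth.max())

    best = int(np.argmax(slopes))
    mu = float(slopes[best])
    if mu < flat_slope:
        return GrowthStats(mu_max=0.0, lag_h=math.nan, od_max=od_max,
                           fit_window=(0, 0))
    # tangent y = mu*t + b meets the initial level ln(od_init) at the lag
    od_init = float(np.median(od[:w]))
    lag = (math.log(od_init) - intercepts[best]) / mu
    lag = float(min(max(lag, 0.0), t[-1]))
    return GrowthStats(
        mu_max=mu,
        lag_h=lag,
        od_max=od_max,
        fit_window=(best, best + w),
    )


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x (number of (x_i, y_j) pairs with x_i > y_j; ties count 1/2)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    exact_limit: int = 12,
) -> tuple[float, float]:
    """Mann–Whitney U test of x against y.

    Exact p by enumerating all label assignments when n_x + n_y <=
    ``exact_limit`` (mid-ranks for ties); otherwise the normal approximation
    with tie correction. ``alternative='greater'`` tests whether x tends to
    exceed y. Returns (U_x, p).
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    u_obs = _u_statistic(x, y)

    if nx + ny <= exact_limit:
        pooled = np.concatenate([x, y])
        n = nx + ny
        us = []
        for idx in itertools.combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-9
        p_greater = float(np.mean(us >= u_obs - eps))
        p_less = float(np.mean(us <= u_obs + eps))
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return u_obs, p

    # normal approximation with tie correction
    n = nx + ny
    mean_u = nx * ny / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return u_obs, 1.0
    sd = math.sqrt(var_u)
    if alternative == "greater":
        z = (u_obs - mean_u - 0.5) / sd
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        z = (u_obs - mean_u + 0.5) / sd
        p = float(stats.norm.cdf(z))
    else:
        z = (u_obs - mean_u) / sd
        z = abs(z) - 0.5 / sd if abs(z) > 0.5 / sd else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
    return u_obs, min(p, 1.0)


def fishers_method(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: X^2 = -2 sum ln p_i ~ chi2(2k)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError(
            "p-values must lie in (0, 1]; floor exact zeros explicitly "
            "before combining"
        )
    x2 = -2.0 * float(np.sum(np.log(p)))
    return float(stats.chi2.sf(x2, 2 * len(p)))


# ---------------------------------------------------------------------------
# Library comparison matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ComparisonCell:
    metric: str
    condition: object
    group_a: str
    group_b: str
    u: Optional[float]
    p: Optional[float]          # one-tailed, a > b
    significant: Optional[bool]
    testable: bool


@dataclasses.dataclass
class ComparisonResult:
    cells: list
    n_significant: int
    n_on_par_or_better: int
    n_total: int
    combined_p: Optional[float]

    def significant_fraction(self) -> float:
        return self.n_significant / self.n_total if self.n_total else 0.0


_METRIC_SENSE = {"mu_max": +1, "od_max": +1, "lag_h": -1}  # -1: lower better


def compare_libraries(
    groups: Mapping[str, Mapping[object, Sequence[GrowthStats]]],
    metrics: Sequence[str] = ("mu_max", "od_max", "lag_h"),
    alpha: float = 0.05,
    combine: bool = False,
) -> ComparisonResult:
    """One-tailed Mann–Whitney comparisons across ordered group pairs.

    ``groups`` maps group name -> condition -> replicate GrowthStats. Each
    (metric, condition, group_a, group_b) cell tests whether a outperforms b
    (for lag time, 'outperform' means shorter). Cells with fewer than 2
    members on either side are marked untestable. "On par or better" counts
    cells where a is not significantly worse than b at ``alpha``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for m in metrics:
        if m not in _METRIC_SENSE:
            raise ValueError(f"unknown metric {m!r}")
    cells: list[ComparisonCell] = []
    n_sig = 0
    n_par = 0
    ps = []
    for a, b in itertools.permutations(names, 2):
        conditions = sorted(
            set(groups[a]) & set(groups[b]), key=str
        )
        for cond in conditions:
            for metric in metrics:
                va = [getattr(g, metric) for g in groups[a][cond]]
                vb = [getattr(g, metric) for g in groups[b][cond]]
                va = [v for v in va if not math.isnan(v)]
                vb = [v for v in vb if not math.isnan(v)]
                if len(va) < 2 or len(vb) < 2:
                    cells.append(ComparisonCell(
                        metric, cond, a, b, None, None, None, False
                    ))
                    continue
                sense = _METRIC_SENSE[metric]
                alt = "greater" if sense > 0 else "less"
                u, p = mann_whitney_u(va, vb, alternative=alt)
                _, p_worse = mann_whitney_u(
                    va, vb, alternative="less" if sense > 0 else "greater"
                )
                sig = p < alpha
                n_sig += sig
                n_par += not (p_worse < alpha)
                ps.append(p)
                cells.append(ComparisonCell(
                    metric, cond, a, b, u, p, sig, True
                ))
    combined = fishers_method(ps) if (combine and ps) else None
    return ComparisonResult(
        cells=cells,
        n_significant=n_sig,
        n_on_par_or_better=n_par,
        n_total=len(cells),
        combined_p=combined,
    )
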