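"""Convergence and dispersion diagnostics for swarm fitness traces.

Different inertia-weight schedules converge at different generations, so
raw Euclidean norms of the best-minus-average fitness gap are not
comparable across runs: a later convergence leaves a shorter error
vector.  The normalized error norm fixes this by taking the *root mean
square* of the gap from the convergence generation t to the end,

    F_gy = sqrt( sum_{k=t}^{T} (V_best(k) - V_ave(k))^2 / (T - t + 1) ),

which is dimensionless in the window length.  The convergence generation
itself is detected as the first generation after which the average
fitness curve stays inside a tolerance band around its final value; a
trace still oscillating at the penultimate generation has no convergence
generation (as happens with a constant inertia weight).

Boxplot statistics follow the Tukey convention: quartiles by linear
interpolation, whisker fences at Q1 - 1.5*IQR and Q3 + 1.5*IQR, adjacent
values the extreme data points inside the fences, outliers the points
outside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pso import FitnessTrace

__all__ = [
    "CurveSummary",
    "BoxplotStats",
    "normalized_error_norm",
    "convergence_generation",
    "curve_summary",
    "boxplot_stats",
]


@dataclass(frozen=True)
class CurveSummary:
    """Scalar summaries of one fitness trace (all fitness fields in percent)."""

    max_vbest: float
    mean_vave: float
    median_vave: float
    global_error_norm: float
    convergence_generation: int | None
    fgy: float | None


@dataclass(frozen=True)
class BoxplotStats:
    median: float
    lower_adjacent: float
    upper_adjacent: float
    outlier_count: int


def normalized_error_norm(v_best, v_ave, t: int) -> float:
    """RMS gap between the best and average curves from generation t on.

    Generations are 1-based; ``t`` must lie in [1, len(curve)].
    """
    v_best = np.asarray(v_best, dtype=float).ravel()
    v_ave = np.asarray(v_ave, dtype=float).ravel()
    if v_best.shape != v_ave.shape:
        raise ValueError("V_best and V_ave must have equal length")
    maxgen = v_best.shape[0]
    if not 1 <= t <= maxgen:
        raise ValueError(f"convergence generation {t} outside [1, {maxgen}]")
    gap = v_best[t - 1 :] - v_ave[t - 1 :]
    return float(np.sqrt(np.mean(gap**2)))


def convergence_generation(v_ave, epsilon: float = 0.01) -> int | None:
    """First generation after which V_ave stays within a band of its final value.

    The band is ``epsilon`` times the trace's range (a flat trace
    converges at generation 1).  Returns None when only the very last
    generation sits inside the band, i.e. the curve is still oscillating
    at the end and no convergence generation can be identified.
    """
    v_ave = np.asarray(v_ave, dtype=float).ravel()
    if v_ave.size == 0:
        raise ValueError("empty trace")
    spread = float(v_ave.max() - v_ave.min())
    if spread == 0.0:
        return 1
    band = epsilon * spread
    inside = np.abs(v_ave - v_ave[-1]) <= band
    bad = np.flatnonzero(~inside)
    t = 1 if bad.size == 0 else int(bad[-1]) + 2  # 1-based, after last excursion
    if t >= v_ave.size:  # only the final generation qualifies
        return None
    return t


def curve_summary(trace: FitnessTrace, epsilon: float = 0.01) -> CurveSummary:
    """All trace summaries: extremes, central values, error norms, convergence."""
    v_best, v_ave = trace.v_best, trace.v_ave
    if len(trace) == 0:
        raise ValueError("empty trace")
    t = convergence_generation(v_ave, epsilon)
    fgy = None if t is None else normalized_error_norm(v_best, v_ave, t)
    return CurveSummary(
        max_vbest=float(v_best.max()),
        mean_vave=float(v_ave.mean()),
        median_vave=float(np.median(v_ave)),
        global_error_norm=float(np.linalg.norm(v_best - v_ave)),
        convergence_generation=t,
        fgy=fgy,
    )


def boxplot_stats(values) -> BoxplotStats:
    """Tukey boxplot statistics of a sample (>= 4 values required)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        raise ValueError(f"need at least 4 values, got {values.size}")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = (values >= lo_fence) & (values <= hi_fence)
    return BoxplotStats(
        median=float(med),
        lower_adjacent=float(values[inside].min()),
        upper_adjacent=float(values[inside].max()),
        outlier_count=int(np.sum(~inside)),
    )
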