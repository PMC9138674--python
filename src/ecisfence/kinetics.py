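"""Attachment/spreading and fence-release migration kinetics.

Three scalar summaries are extracted from single-well time series:

* ``Sc = |-dC/dt|`` — the capacitance decline rate during attachment, from an
  ordinary least-squares fit restricted to the band between two capacitance
  thresholds (defaults 3 -> 1.5 for single-electrode wells, 30 -> 10 for
  ten-electrode wells, in the unit of the trace).
* ``Sr = |dR/dt|`` — the resistance rise rate after the electric fence is
  released, from an OLS fit over the central fraction of the baseline-to-
  plateau excursion.
* ``T50`` — the time at which the trace first crosses the midpoint between
  its baseline and plateau levels, linearly interpolated between samples.

A fourth operation segments an adhesion time course into the four canonical
stages (initial adhesion, spreading, remodeling, steady state) with an exact
continuous piecewise-linear least-squares search over breakpoint positions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesTrace",
    "KineticsResult",
    "StageSegmentation",
    "IncompleteTraceError",
    "UnsaturatedTraceWarning",
    "extract_capacitance_slope",
    "extract_resistance_slope",
    "extract_t50",
    "segment_adhesion_stages",
    "DEFAULT_CAP_THRESHOLDS",
]

#: Default capacitance threshold band (upper, lower) per array type, in the
#: unit of the trace values.
DEFAULT_CAP_THRESHOLDS = {"8W1E": (3.0, 1.5), "8W10E": (30.0, 10.0)}

MODALITIES = ("attachment_capacitance", "migration_resistance", "micromotion_resistance")


class IncompleteTraceError(ValueError):
    """Raised when a trace never crosses a required threshold or midpoint."""


class UnsaturatedTraceWarning(UserWarning):
    """The trace has not plateaued; the reported slope uses the available window."""


@dataclass
class TimeSeriesTrace:
    """One well's readout vs. time at a single frequency.

    Time is in hours with t = 0 at inoculation (attachment traces) or at
    fence release (migration traces; a pre-release hold may occupy t < 0).
    """

    time_h: np.ndarray
    values: np.ndarray
    frequency_hz: float
    modality: str
    well_id: str = "A1"

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_h.shape != self.values.shape:
            raise ValueError("time and value vectors must have equal length")
        if self.time_h.size < 3:
            raise ValueError("a trace needs at least 3 samples")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class KineticsResult:
    slope: float  # |dV/dt| in value-units per hour
    t50_h: float | None = None
    thresholds: tuple | None = None
    baseline: float | None = None
    plateau: float | None = None
    r_squared: float | None = None
    window: tuple | None = None  # (t_start, t_end) of the regression window


@dataclass
class StageSegmentation:
    """Four-stage continuous piecewise-linear decomposition of adhesion."""

    breakpoints_h: np.ndarray  # 3 interior breakpoints, strictly increasing
    durations_h: np.ndarray  # 4 per-stage durations, summing to the trace span
    slopes: np.ndarray  # per-stage slopes of the fitted line
    sse: float
    stage_names: tuple = ("initial_adhesion", "spreading", "remodeling", "steady_state")


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r^2 of an ordinary least-squares line."""
    tm, ym = t.mean(), y.mean()
    stt = float(np.sum((t - tm) ** 2))
    if stt == 0.0:
        raise ValueError("degenerate regression window (single time point)")
    sty = float(np.sum((t - tm) * (y - ym)))
    slope = sty / stt
    resid = y - (ym + slope * (t - tm))
    syy = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else 1.0
    return slope, ym - slope * tm, r2


def _cross_time(t: np.ndarray, y: np.ndarray, level: float, downward: bool) -> float:
    """First linearly interpolated crossing of ``level``."""
    y0 = y - level
    if downward:
        y0 = -y0
    # first index i where the value passes from below to at/above the level
    for i in range(len(y0) - 1):
        if y0[i] < 0 <= y0[i + 1]:
            frac = -y0[i] / (y0[i + 1] - y0[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    if y0[0] >= 0:
        return float(t[0])
    raise IncompleteTraceError(f"trace never crosses level {level:g}")


def extract_capacitance_slope(
    trace: TimeSeriesTrace,
    upper_c: float = 3.0,
    lower_c: float = 1.5,
) -> KineticsResult:
    """Attachment rate Sc from the threshold band of a capacitance decline.

    All samples with value in [lower_c, upper_c] enter one OLS fit; the
    reported slope is the absolute value.  Crossing times of both thresholds
    (downward) are located by linear interpolation and define the window.
    """
    if upper_c <= lower_c:
        raise ValueError("upper_C must exceed lower_C")
    t, y = trace.time_h, trace.values
    for name, level in (("upper", upper_c), ("lower", lower_c)):
        if y.min() > level or y.max() < level:
            raise IncompleteTraceError(
                f"incomplete trace: capacitance never crosses the {name} threshold {level:g}"
            )
    t_upper = _cross_time(t, y, upper_c, downward=True)
    t_lower = _cross_time(t, y, lower_c, downward=True)
    mask = (y >= lower_c) & (y <= upper_c)
    if mask.sum() < 2:
        raise IncompleteTraceError("fewer than 2 samples inside the threshold band")
    slope, _, r2 = _ols(t[mask], y[mask])
    return KineticsResult(
        slope=abs(slope),
        thresholds=(upper_c, lower_c),
        r_squared=r2,
        window=(t_upper, t_lower),
    )


def _levels(trace: TimeSeriesTrace, k: int) -> tuple[float, float]:
    if trace.values.size < 2 * k:
        raise ValueError(f"need at least {2 * k} samples to estimate baseline and plateau")
    baseline = float(trace.values[:k].mean())
    plateau = float(trace.values[-k:].mean())
    if baseline == plateau:
        raise ValueError("baseline equals plateau; no excursion to analyse")
    return baseline, plateau


def extract_resistance_slope(
    trace: TimeSeriesTrace,
    baseline_frac: float = 0.1,
    plateau_frac: float = 0.9,
    k: int = 5,
) -> KineticsResult:
    """Migration rate Sr from the central rise of a resistance recovery.

    Baseline/plateau are means of the first/last ``k`` samples; the OLS
    window holds the samples between ``baseline_frac`` and ``plateau_frac``
    of the excursion.  An unsaturated trace (still rising at the end) yields
    a warning and the slope over the available window.
    """
    if not 0.0 <= baseline_frac < plateau_frac <= 1.0:
        raise ValueError("require 0 <= baseline_frac < plateau_frac <= 1")
    baseline, plateau = _levels(trace, k)
    t, y = trace.time_h, trace.values
    span = plateau - baseline
    lo = baseline + baseline_frac * span
    hi = baseline + plateau_frac * span
    # still climbing at the end => the plateau estimate is provisional
    tail_slope, _, _ = _ols(t[-k:], y[-k:])
    mask = (y >= min(lo, hi)) & (y <= max(lo, hi))
    if mask.sum() < 2:
        raise IncompleteTraceError("fewer than 2 samples inside the regression window")
    slope, _, r2 = _ols(t[mask], y[mask])
    if abs(tail_slope) > 0.05 * abs(slope):
        warnings.warn(
            "unsaturated trace: plateau not reached; slope uses the available window",
            UnsaturatedTraceWarning,
        )
    tw = t[mask]
    return KineticsResult(
        slope=abs(slope),
        thresholds=(baseline_frac, plateau_frac),
        baseline=baseline,
        plateau=plateau,
        r_squared=r2,
        window=(float(tw[0]), float(tw[-1])),
    )


def extract_t50(trace: TimeSeriesTrace, k: int = 5) -> float:
    """Halfway time between baseline and plateau, linearly interpolated.

    Resistance recoveries cross upward, capacitance declines downward; the
    direction follows the sign of the excursion.
    """
    baseline, plateau = _levels(trace, k)
    mid = 0.5 * (baseline + plateau)
    downward = plateau < baseline
    try:
        return _cross_time(trace.time_h, trace.values, mid, downward=downward)
    except IncompleteTraceError:
        raise IncompleteTraceError("trace never crosses the baseline/plateau midpoint") from None


# ---------------------------------------------------------------------------
# stage segmentation
# ---------------------------------------------------------------------------

def _pwl_sse(t: np.ndarray, y: np.ndarray, bk: tuple) -> tuple[float, np.ndarray]:
    """SSE and coefficients of the continuous PWL fit with given breakpoints."""
    cols = [np.ones_like(t), t] + [np.maximum(t - t[j], 0.0) for j in bk]
    x = np.column_stack(cols)
    coef, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if res.size:
        sse = float(res[0])
    else:
        sse = float(np.sum((x @ coef - y) ** 2))
    return sse, coef


def segment_adhesion_stages(
    trace: TimeSeriesTrace,
    n_stages: int = 4,
    min_seg: int = 2,
    max_exhaustive: int = 120,
) -> StageSegmentation:
    """Optimal continuous piecewise-linear segmentation into adhesion stages.

    Breakpoints are restricted to sample times.  For traces up to
    ``max_exhaustive`` samples every admissible breakpoint combination is
    scored (exact search); longer traces use a coarse grid followed by
    coordinate-descent refinement at full resolution, which reaches the same
    optimum on signals with distinct per-stage slopes.
    """
    if n_stages != 4:
        raise ValueError("the adhesion decomposition has exactly 4 stages")
    t, y = trace.time_h, trace.values
    n = t.size
    n_bk = n_stages - 1
    if n < 2 * n_stages:
        raise ValueError(f"need at least {2 * n_stages} samples for {n_stages} stages")

    def admissible(idx):
        prev = 0
        for j in idx:
            if j - prev < min_seg:
                return False
            prev = j
        return n - 1 - idx[-1] >= min_seg

    candidates = list(range(min_seg, n - min_seg))

    def best_over(combos):
        best = None
        for combo in combos:
            if not admissible(combo):
                continue
            sse, coef = _pwl_sse(t, y, combo)
            key = (sse, combo)
            if best is None or key < best[0]:
                best = (key, combo, coef)
        if best is None:
            raise ValueError("no admissible breakpoint combination")
        return best[1], best[2], best[0][0]

    if n <= max_exhaustive:
        bk, coef, sse = best_over(itertools.combinations(candidates, n_bk))
    else:
        stride = max(1, n // 40)
        coarse = candidates[::stride]
        bk, coef, sse = best_over(itertools.combinations(coarse, n_bk))
        # coordinate descent at full resolution around the coarse optimum
        for _ in range(20):
            improved = False
            for pos in range(n_bk):
                lo = max(min_seg, bk[pos] - stride)
                hi = min(n - 1 - min_seg, bk[pos] + stride)
                combos = [
                    tuple(j if q == pos else bk[q] for q in range(n_bk))
                    for j in range(lo, hi + 1)
                ]
                combos = [c for c in combos if all(c[i] < c[i + 1] for i in range(n_bk - 1))]
                new_bk, new_coef, new_sse = best_over(combos)
                if new_sse < sse - 1e-15 * max(1.0, sse):
                    bk, coef, sse = new_bk, new_coef, new_sse
                    improved = True
            if not improved:
                break

    bk_times = t[list(bk)]
    edges = np.concatenate([[t[0]], bk_times, [t[-1]]])
    durations = np.diff(edges)
    slopes = np.cumsum(np.concatenate([[coef[1]], coef[2:]]))
    return StageSegmentation(
        breakpoints_h=bk_times,
        durations_h=durations,
        slopes=slopes,
        sse=sse,
    )
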