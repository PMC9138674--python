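"""Micromotion fluctuation analysis of rapid-time-collection (RTC) series.

A confluent layer of live cells continually reshapes its cell-substrate and
cell-cell contacts, which shows up as small fluctuations in the 4 kHz
resistance sampled once per second.  The Var32 statistic summarises these
fluctuations: the 2048-point series is split into 64 consecutive 32-point
segments, each segment is divided by its own mean, and the per-segment
population variances are averaged.  Per-segment normalization makes the
statistic dimensionless and invariant to the absolute resistance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MicromotionSeries",
    "MicromotionResult",
    "var32",
    "normalize_trace",
]


@dataclass
class MicromotionSeries:
    """Resistance sampled at a fixed interval for fluctuation analysis."""

    values: np.ndarray  # Ohm, all positive
    interval_s: float = 1.0
    frequency_hz: float = 4000.0
    well_id: str = "A1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values <= 0):
            raise ValueError("resistance values must be positive")
        if self.interval_s <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_points(self) -> int:
        return self.values.size


@dataclass
class MicromotionResult:
    var32: float
    n_segments: int
    segment_length: int


def normalize_trace(series: MicromotionSeries) -> np.ndarray:
    """Divide every point by the whole-series mean; output mean is exactly 1."""
    mean = series.values.mean()
    if mean <= 0:
        raise ValueError("series mean must be positive")
    out = series.values / mean
    # enforce exact unit mean against accumulated rounding
    return out / out.mean()


def var32(
    series: MicromotionSeries,
    segment_length: int = 32,
    per_segment_normalization: bool = True,
) -> MicromotionResult:
    """Mean per-segment variance of the mean-normalized series.

    The series is partitioned into consecutive non-overlapping segments of
    ``segment_length`` points (a trailing remainder is dropped with a
    warning).  With ``per_segment_normalization`` each segment is divided by
    its own mean (the default, scale-invariant reading); otherwise the whole
    series is divided by its global mean first.  Variances are population
    variances (divisor = segment length).
    """
    if segment_length < 2:
        raise ValueError("segment_length must be at least 2")
    v = series.values
    if v.size < segment_length:
        raise ValueError("series shorter than one segment")
    n_segments, rem = divmod(v.size, segment_length)
    if rem:
        warnings.warn(
            f"dropping {rem} trailing points not filling a {segment_length}-point segment",
            UserWarning,
        )
        v = v[: n_segments * segment_length]
    seg = v.reshape(n_segments, segment_length)
    if per_segment_normalization:
        seg = seg / seg.mean(axis=1, keepdims=True)
    else:
        seg = seg / v.mean()
    value = float(np.mean(np.var(seg, axis=1)))
    return MicromotionResult(var32=value, n_segments=n_segments, segment_length=segment_length)
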