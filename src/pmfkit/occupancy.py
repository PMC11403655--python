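"""Per-window ligand-pocket occupancy statistics.

A ligand that stays lodged in the hydrophobic pocket keeps a small
pocket-ligand minimum distance with small fluctuations; a window where it
abandons the pocket shows a large mean, a large standard deviation (the
"large error bars" signature), or a tail that settles at the unbound level.
These routines turn per-window minimum-distance traces into occupancy
reports, smoothed traces, and bound-residence segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import TimeSeries

__all__ = [
    "DistanceTrace",
    "AbandonmentCriteria",
    "OccupancyReport",
    "window_stats",
    "classify_abandonment",
    "abandonment_probability",
    "moving_average",
    "residence_segments",
]


@dataclass(frozen=True)
class DistanceTrace:
    """Pocket-ligand minimum-distance time series for one umbrella window."""

    window: str
    series: TimeSeries
    restraint_xi: float = float("nan")

    def __post_init__(self) -> None:
        if np.any(self.series.values < 0):
            raise ValueError(f"window {self.window}: distances must be >= 0")


@dataclass(frozen=True)
class AbandonmentCriteria:
    """Operational rule for "the ligand left the pocket".

    A window counts as abandoned when the post-burn-in mean exceeds
    distance_cutoff, OR the standard deviation exceeds std_cutoff (the
    visual large-error-bar signature), OR the mean over the final
    tail_fraction of the trace exceeds distance_cutoff (late abandonment
    that a whole-trace mean would dilute).  All comparisons are strict.
    """

    distance_cutoff: float = 0.6  # nm
    std_cutoff: float = 0.3  # nm
    tail_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.std_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.tail_fraction <= 1:
            raise ValueError("tail_fraction must be in (0, 1]")


@dataclass(frozen=True)
class OccupancyReport:
    windows: tuple[str, ...]
    means: np.ndarray  # nm
    stds: np.ndarray  # nm
    abandoned: np.ndarray  # bool
    criteria: AbandonmentCriteria

    @property
    def probability(self) -> float:
        """Fraction of windows classified abandoned."""
        return float(np.mean(self.abandoned))


def window_stats(trace: DistanceTrace, burn_in_fraction: float = 0.0
                 ) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of the
    post-burn-in minimum distance, in nm."""
    series = trace.series.discard_burn_in(burn_in_fraction)
    if len(series) < 2:
        raise ValueError(
            f"window {trace.window}: need >= 2 post-burn-in points for stats"
        )
    return float(np.mean(series.values)), float(np.std(series.values, ddof=1))


def classify_abandonment(
    trace: DistanceTrace,
    criteria: AbandonmentCriteria = AbandonmentCriteria(),
    burn_in_fraction: float = 0.0,
) -> bool:
    mean, std = window_stats(trace, burn_in_fraction)
    tail_mean = float(np.mean(
        trace.series.discard_burn_in(burn_in_fraction)
        .tail(criteria.tail_fraction).values
    ))
    return (
        mean > criteria.distance_cutoff
        or std > criteria.std_cutoff
        or tail_mean > criteria.distance_cutoff
    )


def abandonment_probability(
    traces: Sequence[DistanceTrace],
    criteria: AbandonmentCriteria = AbandonmentCriteria(),
    burn_in_fraction: float = 0.0,
) -> OccupancyReport:
    """Classify every window and report the abandoned fraction."""
    if not traces:
        raise ValueError("need at least one trace")
    means, stds, flags = [], [], []
    for trace in traces:
        mean, std = window_stats(trace, burn_in_fraction)
        means.append(mean)
        stds.append(std)
        flags.append(classify_abandonment(trace, criteria, burn_in_fraction))
    return OccupancyReport(
        windows=tuple(t.window for t in traces),
        means=np.array(means),
        stds=np.array(stds),
        abandoned=np.array(flags, dtype=bool),
        criteria=criteria,
    )


def moving_average(series: TimeSeries, width_ps: float) -> TimeSeries:
    """Centered rolling mean over a time width (ps), edge-truncated.

    Each output point averages all samples within +-width/2 of its time
    (inclusive), so edges use a shortened window rather than padding.
    A width of one frame interval reduces to the identity.
    """
    times, values = series.times, series.values
    min_interval = float(np.min(np.diff(times))) if len(series) > 1 else 0.0
    if len(series) > 1 and width_ps < min_interval:
        raise ValueError(
            f"width {width_ps} ps is shorter than the frame interval "
            f"{min_interval} ps"
        )
    half = width_ps / 2.0
    lo = np.searchsorted(times, times - half, side="left")
    hi = np.searchsorted(times, times + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return TimeSeries(times, out)


def residence_segments(
    series: TimeSeries,
    bound_cutoff: float = 0.6,
    min_duration_ps: float = 0.0,
) -> list[tuple[float, float, float]]:
    """Maximal contiguous bound runs (distance < cutoff) lasting >= min_duration.

    Returns (start_ps, end_ps, duration_ps) tuples sorted by start time,
    where duration is end - start over the run's sample times.
    """
    below = series.values < bound_cutoff
    segments: list[tuple[float, float, float]] = []
    start_idx: int | None = None
    for i, flag in enumerate(below):
        if flag and start_idx is None:
            start_idx = i
        elif not flag and start_idx is not None:
            segments.append((start_idx, i - 1))
            start_idx = None
    if start_idx is not None:
        segments.append((start_idx, len(below) - 1))
    out = []
    for a, b in segments:
        t0, t1 = float(series.times[a]), float(series.times[b])
        if t1 - t0 >= min_duration_ps:
            out.append((t0, t1, t1 - t0))
    return out
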