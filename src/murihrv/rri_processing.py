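"""R-R interval series: construction from R peaks, analysis windows, screening.

Conventions (used by every HRV metric downstream):

* intervals are in milliseconds, beat times in seconds;
* ``beat_times[i]`` is the time of the beat that *ends* interval ``i``;
* analysis windows are half-open ``[t0, t0 + duration)`` over ending times;
* excluded intervals never contribute to any metric, and successive-difference
  metrics only use pairs of adjacent retained intervals with no exclusion
  between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, InsufficientDataError, ValidationError

LABEL_NORMAL = "normal"
LABEL_EXCLUDED = "excluded"


@dataclass
class RRISeries:
    """Ordered R-R intervals with per-interval quality labels.

    Parameters
    ----------
    intervals
        R-R intervals in ms, all > 0.
    beat_times
        Strictly increasing times (s) of the beat ending each interval.
    labels
        Per-interval quality flag, ``"normal"`` or ``"excluded"``.
        Defaults to all-normal.
    """

    intervals: np.ndarray
    beat_times: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.labels is None:
            self.labels = np.full(self.intervals.shape, LABEL_NORMAL, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.intervals.shape != self.beat_times.shape:
            raise ValidationError("intervals and beat_times must have equal length")
        if self.labels.shape != self.intervals.shape:
            raise ValidationError("labels must have one entry per interval")
        if np.any(self.intervals <= 0):
            raise ValidationError("all RR intervals must be > 0")
        if self.intervals.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValidationError("beat_times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.intervals)

    @property
    def retained_mask(self) -> np.ndarray:
        return self.labels == LABEL_NORMAL

    @property
    def retained(self) -> np.ndarray:
        """Intervals (ms) not flagged as excluded."""
        return self.intervals[self.retained_mask]

    def valid_pairs(self) -> np.ndarray:
        """Successive differences (ms) over adjacent retained intervals.

        A pair (i, i+1) is valid only when both members are retained, so an
        exclusion breaks the chain of differences on both sides.
        """
        m = self.retained_mask
        ok = m[:-1] & m[1:]
        return np.diff(self.intervals)[ok]

    @property
    def start_time(self) -> float:
        """Time (s) of the beat opening the first interval."""
        if self.n == 0:
            return 0.0
        return float(self.beat_times[0] - self.intervals[0] / 1000.0)

    @property
    def span(self) -> float:
        """Total time (s) covered, from first beat to last."""
        if self.n == 0:
            return 0.0
        return float(self.beat_times[-1] - self.start_time)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: ``duration`` seconds placed within the recording."""

    duration: float = 180.0
    placement: str = "center"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError(f"window duration must be > 0, got {self.duration}")
        if self.placement not in ("start", "center", "end"):
            raise ConfigurationError(f"unknown placement {self.placement!r}")


def peaks_to_rri(peaks) -> RRISeries:
    """Convert an :class:`~murihrv.rpeak_detection.RPeakSet` to intervals.

    ``intervals[i] = (times[i+1] - times[i]) * 1000`` ms; N = peaks - 1.
    """
    times = np.asarray(peaks.times, dtype=float)
    if times.size < 2:
        raise InsufficientDataError(
            f"insufficient beats: need >= 2 R peaks, got {times.size}"
        )
    intervals = np.diff(times) * 1000.0
    return RRISeries(intervals=intervals, beat_times=times[1:])


def window_rri(series: RRISeries, spec: WindowSpec = WindowSpec()) -> RRISeries:
    """Select the intervals whose ending beat falls in [t0, t0 + duration).

    t0 depends on ``spec.placement``: the recording start, the centered
    position, or ``end - duration``.
    """
    if series.span < spec.duration:
        raise InsufficientDataError(
            f"recording spans {series.span:.3f} s, shorter than the "
            f"{spec.duration:.3f} s window"
        )
    t_start = series.start_time
    if spec.placement == "start":
        t0 = t_start
    elif spec.placement == "end":
        t0 = series.beat_times[-1] - spec.duration
    else:  # center
        t0 = t_start + (series.span - spec.duration) / 2.0
    mask = (series.beat_times >= t0) & (series.beat_times < t0 + spec.duration)
    return RRISeries(
        intervals=series.intervals[mask],
        beat_times=series.beat_times[mask],
        labels=series.labels[mask],
    )


def screen_artifacts(
    series: RRISeries,
    min_rri: float = 50.0,
    max_rri: float = 300.0,
    max_rel_jump: float = 0.3,
) -> RRISeries:
    """Flag implausible intervals as excluded.

    An interval is excluded when it lies outside ``[min_rri, max_rri]`` ms or
    differs from the previous *retained* interval by more than
    ``max_rel_jump`` (relative).  Already-excluded intervals stay excluded.
    """
    if min_rri <= 0 or max_rri <= 0 or min_rri >= max_rri:
        raise ConfigurationError(
            f"screening bounds must satisfy 0 < min < max, got [{min_rri}, {max_rri}]"
        )
    labels = series.labels.copy()
    prev_retained: float | None = None
    for i, rri in enumerate(series.intervals):
        if labels[i] == LABEL_EXCLUDED:
            continue
        out_of_bounds = not (min_rri <= rri <= max_rri)
        jump = (
            prev_retained is not None
            and abs(rri - prev_retained) / prev_retained > max_rel_jump
        )
        if out_of_bounds or jump:
            labels[i] = LABEL_EXCLUDED
        else:
            prev_retained = rri
    return RRISeries(
        intervals=series.intervals.copy(),
        beat_times=series.beat_times.copy(),
        labels=labels,
    )
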