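"""RR-interval cleaning ahead of HRV feature extraction.

The chain, applied in this fixed order:

1. ``drop_nonbeats``      — strip the zero samples of the sparse RR channel
                            (zero encodes "no beat at this sample").
2. ``remove_outliers``    — exclude intervals <= 700 ms as outliers.
3. ``interpolate_gaps``   — fill excluded interior positions linearly
                            between the nearest retained neighbours.
4. ``remove_ectopic_malik`` — delete beats whose interval differs from the
                            previous accepted interval by more than 20%
                            (Malik criterion), refilling by the same linear
                            interpolation.

A centered moving-average trend (default window 10 beats) is exposed for
quality control. Interpolated beats keep their original beat times and are
flagged ``interpolated`` so downstream consumers can weight or drop them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FLAG_OBSERVED = "observed"
FLAG_INTERPOLATED = "interpolated"

DEFAULT_LOW_THRESHOLD_MS = 700.0
DEFAULT_MALIK_TOLERANCE = 0.2


@dataclass
class RRSeries:
    """Ordered normal-to-normal interval series.

    times: cumulative beat times in seconds (strictly increasing);
    intervals: NN intervals in ms; flags: per-beat provenance in
    {observed, interpolated}. ``np.nan`` intervals mark positions pending
    interpolation mid-pipeline; a fully cleaned series contains none.
    """

    times: np.ndarray
    intervals: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        if not (len(self.times) == len(self.intervals) == len(self.flags)):
            raise ValueError("times, intervals and flags must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beat_time_s": self.times, "rr_ms": self.intervals, "flag": self.flags}
        )

    @classmethod
    def from_intervals(cls, intervals, times=None) -> "RRSeries":
        intervals = np.asarray(intervals, dtype=float)
        if times is None:
            times = np.cumsum(intervals) / 1000.0
        return cls(np.asarray(times, float), intervals,
                   np.full(len(intervals), FLAG_OBSERVED, dtype=object))


def write_rr_series(rr: RRSeries, path) -> None:
    rr.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_rr_series(path) -> RRSeries:
    df = pd.read_csv(path)
    return RRSeries(df["beat_time_s"].to_numpy(), df["rr_ms"].to_numpy(),
                    df["flag"].to_numpy(dtype=object))


def drop_nonbeats(raw_rr_channel, times=None) -> RRSeries:
    """Extract the beat samples (non-zero entries) of a sparse RR channel.

    ``times`` gives the sample timestamps; beat times are taken at the
    non-zero samples. Without ``times``, beat times are the cumulative sum
    of the intervals. An all-zero channel yields an empty series with a
    warning rather than an exception.
    """
    raw = np.asarray(raw_rr_channel, dtype=float)
    mask = raw != 0
    intervals = raw[mask]
    if intervals.size == 0:
        warnings.warn("RR channel contains no beats", stacklevel=2)
        return RRSeries(np.empty(0), np.empty(0), np.empty(0, dtype=object))
    if times is not None:
        beat_times = np.asarray(times, dtype=float)[mask]
    else:
        beat_times = np.cumsum(intervals) / 1000.0
    return RRSeries(beat_times, intervals,
                    np.full(intervals.size, FLAG_OBSERVED, dtype=object))


def remove_outliers(rr: RRSeries, low_threshold: float = DEFAULT_LOW_THRESHOLD_MS) -> RRSeries:
    """Mark intervals <= ``low_threshold`` ms (default 700) as excluded.

    Excluded positions become NaN so :func:`interpolate_gaps` can refill
    them; order and beat times are preserved.
    """
    intervals = rr.intervals.copy()
    bad = intervals <= low_threshold
    if bad.all() and len(rr):
        warnings.warn(
            f"all {len(rr)} intervals are <= {low_threshold} ms; series is empty after cleaning",
            stacklevel=2,
        )
    intervals[bad] = np.nan
    return RRSeries(rr.times, intervals, rr.flags.copy())


def interpolate_gaps(rr: RRSeries) -> RRSeries:
    """Fill NaN (excluded) interior positions by linear interpolation.

    Each filled position is interpolated linearly in beat index between the
    nearest retained neighbours and flagged ``interpolated``. Leading and
    trailing excluded positions are dropped (no extrapolation).
    """
    good = ~np.isnan(rr.intervals)
    n_good = int(good.sum())
    if np.all(good):
        return RRSeries(rr.times.copy(), rr.intervals.copy(), rr.flags.copy())
    if n_good < 2:
        raise ValueError(f"insufficient beats: {n_good} retained, need >= 2 to interpolate")
    first, last = np.flatnonzero(good)[[0, -1]]
    sl = slice(first, last + 1)
    idx = np.arange(len(rr.intervals))[sl]
    intervals = rr.intervals[sl].copy()
    flags = rr.flags[sl].copy()
    hole = np.isnan(intervals)
    intervals[hole] = np.interp(idx[hole], idx[~hole], intervals[~hole])
    flags[hole] = FLAG_INTERPOLATED
    return RRSeries(rr.times[sl], intervals, flags)


def remove_ectopic_malik(rr: RRSeries, tolerance: float = DEFAULT_MALIK_TOLERANCE) -> RRSeries:
    """Delete ectopic beats by the Malik criterion and refill linearly.

    Interval i is ectopic when it differs from the previous *accepted*
    interval by more than ``tolerance`` (fraction, default 20%). The first
    interval is always kept. Deleted positions are refilled by the same
    linear interpolation as :func:`interpolate_gaps` (trailing deletions
    are dropped).
    """
    if len(rr) == 0:
        return RRSeries(rr.times.copy(), rr.intervals.copy(), rr.flags.copy())
    intervals = rr.intervals.copy()
    prev = intervals[0]
    for i in range(1, len(intervals)):
        if abs(intervals[i] - prev) > tolerance * prev:
            intervals[i] = np.nan
        else:
            prev = intervals[i]
    marked = RRSeries(rr.times, intervals, rr.flags.copy())
    if np.isnan(intervals).any() and (~np.isnan(intervals)).sum() >= 2:
        return interpolate_gaps(marked)
    if np.isnan(intervals).any():
        # fewer than two survivors: keep only the accepted beats
        good = ~np.isnan(intervals)
        return RRSeries(rr.times[good], intervals[good], rr.flags[good])
    return marked


def moving_average_trend(rr: RRSeries, window: int = 10) -> np.ndarray:
    """Centered simple moving average of the intervals (QC trend).

    Output length is ``len(rr) - window + 1``; no padding is applied.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(rr) < window:
        raise ValueError(f"series length {len(rr)} shorter than window {window}")
    return np.convolve(rr.intervals, np.ones(window) / window, mode="valid")


def clean_rr(
    raw_rr_channel,
    times=None,
    low_threshold: float = DEFAULT_LOW_THRESHOLD_MS,
    tolerance: float = DEFAULT_MALIK_TOLERANCE,
) -> RRSeries:
    """Run the full cleaning chain on a sparse RR channel."""
    rr = drop_nonbeats(raw_rr_channel, times=times)
    if len(rr) == 0:
        return rr
    rr = remove_outliers(rr, low_threshold=low_threshold)
    n_good = int((~np.isnan(rr.intervals)).sum())
    if n_good == 0:
        return RRSeries(np.empty(0), np.empty(0), np.empty(0, dtype=object))
    if n_good < 2:
        good = ~np.isnan(rr.intervals)
        rr = RRSeries(rr.times[good], rr.intervals[good], rr.flags[good])
    else:
        rr = interpolate_gaps(rr)
    return remove_ectopic_malik(rr, tolerance=tolerance)
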