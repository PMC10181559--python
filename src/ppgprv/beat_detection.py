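"""Windowed decision rule for cardiac event detection on the APG.

Candidates are strict local maxima of the APG.  Within each analysis
window (20 s default) a candidate fires when its height above a
window-neighbourhood reference exceeds a threshold; every other sample
is marked zero.  A refractory rule then suppresses the smaller of two
events closer than the minimum beat gap.  Peak-to-peak intervals are
sample distances divided by the device sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IBIOrigin, IBISeries, SampledSignal

__all__ = [
    "DetectorParams",
    "EventArray",
    "detect_events",
    "pp_intervals",
    "clean_intervals",
]


@dataclass(frozen=True)
class DetectorParams:
    """Decision-rule parameters.

    ``threshold_policy='quantile'`` derives the threshold per window as
    the given quantile of positive APG amplitudes (amplitude-scale
    invariant); ``'fixed'`` uses ``theta`` as an absolute amplitude.
    ``reference`` picks the neighbourhood value each candidate's height
    is measured against: ``'median'`` (default, the median of the
    samples between half a window either side of the candidate — robust
    to what the half-window samples happen to land on),
    ``'symmetric'`` (mean of the two samples exactly half a window
    away, clipped to the window), or ``'left'``/``'right'`` (the
    one-sided sample only).
    """

    window_length: float = 20.0  # s
    threshold_policy: str = "quantile"
    theta: float = 0.85  # quantile fraction, or amplitude when fixed
    refractory: float = 250.0  # ms
    reference: str = "median"

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if self.threshold_policy not in ("fixed", "quantile"):
            raise ValueError(f"unknown threshold_policy {self.threshold_policy!r}")
        if self.threshold_policy == "quantile" and not 0.0 < self.theta < 1.0:
            raise ValueError("quantile fraction must lie in (0, 1)")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")
        if self.reference not in ("median", "symmetric", "left", "right"):
            raise ValueError(f"unknown reference strategy {self.reference!r}")


@dataclass(frozen=True)
class EventArray:
    """Boolean per-sample event marks plus the event sample indices."""

    z: np.ndarray
    event_indices: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=bool))
        idx = np.asarray(self.event_indices, dtype=int)
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("event_indices must be strictly increasing")
        object.__setattr__(self, "event_indices", idx)

    def __len__(self) -> int:
        return self.event_indices.size


def _strict_local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; first sample of a plateau wins."""
    n = y.size
    if n < 3:
        return np.empty(0, dtype=int)
    peaks = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j + 1 < n and y[j + 1] < y[i]:
                peaks.append(i)  # plateau tie: first sample wins
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def _apply_refractory(
    indices: np.ndarray, heights: np.ndarray, gap_samples: float
) -> np.ndarray:
    """Greedy suppression: keep the larger of any two events within the gap."""
    if gap_samples <= 0 or indices.size < 2:
        return indices
    # Accept by descending height; ties broken by earlier index.
    order = np.lexsort((indices, -heights))
    accepted: list[int] = []
    for k in order:
        idx = indices[k]
        if all(abs(idx - a) >= gap_samples for a in accepted):
            accepted.append(idx)
    return np.sort(np.asarray(accepted, dtype=int))


def detect_events(apg: SampledSignal, params: DetectorParams | None = None) -> EventArray:
    """Run the windowed decision rule on a preprocessed APG signal."""
    params = params or DetectorParams()
    y = apg.values
    win = int(round(params.window_length * apg.sampling_rate))
    if y.size < 3:
        raise ValueError("APG signal too short for event detection")
    win = min(win, y.size)
    half = win // 2

    candidates = _strict_local_maxima(y)
    fired: list[int] = []
    for start in range(0, y.size, win):
        stop = min(start + win, y.size)
        in_window = candidates[(candidates >= start) & (candidates < stop)]
        if in_window.size == 0:
            continue
        if params.threshold_policy == "quantile":
            # Partial trailing windows borrow history so the quantile is
            # always taken over one full window length.
            seg = y[max(stop - win, 0) : stop]
            positive = seg[seg > 0]
            if positive.size == 0:
                continue
            theta = float(np.quantile(positive, params.theta))
        else:
            theta = params.theta
        last = stop - 1
        for k in in_window:
            if params.reference == "median":
                lo = max(k - half, start)
                hi = min(k + half, last) + 1
                ref = float(np.median(y[lo:hi]))
            else:
                left = y[max(k - half, start)]
                right = y[min(k + half, last)]
                if params.reference == "left":
                    ref = left
                elif params.reference == "right":
                    ref = right
                else:
                    ref = 0.5 * (left + right)
            if y[k] - ref > theta:
                fired.append(k)

    indices = np.asarray(fired, dtype=int)
    gap = params.refractory * apg.sampling_rate / 1000.0
    indices = _apply_refractory(indices, y[indices], gap)
    z = np.zeros(y.size, dtype=bool)
    z[indices] = True
    return EventArray(z=z, event_indices=indices, sampling_rate=apg.sampling_rate)


def pp_intervals(events: EventArray, sampling_rate: float | None = None) -> IBISeries:
    """Peak-to-peak intervals in ms: sample distance over sampling rate."""
    fs = sampling_rate if sampling_rate is not None else events.sampling_rate
    if len(events) < 2:
        raise ValueError("insufficient events: need at least 2 to form an interval")
    intervals = np.diff(events.event_indices) / fs * 1000.0
    times = events.event_indices / fs
    return IBISeries(intervals=intervals, event_times=times, origin=IBIOrigin.DETECTED)


def clean_intervals(
    ibi: IBISeries,
    min_ms: float = 300.0,
    max_ms: float = 2000.0,
    median_band: float = 0.3,
    median_window: int = 11,
) -> tuple[IBISeries, int]:
    """Drop physiologically implausible or locally deviant intervals.

    An interval is rejected when it falls outside ``[min_ms, max_ms]``
    or deviates from the running median (centered window, shrinking at
    the edges) by more than ``median_band`` as a fraction of that
    median.  ``median_band=0`` disables the median rule.  Returns the
    surviving series and the rejection count.
    """
    if len(ibi) == 0:
        raise ValueError("interval series is empty")
    x = ibi.intervals
    keep = (x >= min_ms) & (x <= max_ms)
    if median_band > 0:
        half = median_window // 2
        for i in range(x.size):
            window = x[max(i - half, 0) : i + half + 1]
            med = float(np.median(window))
            if med > 0 and abs(x[i] - med) > median_band * med:
                keep[i] = False
    cleaned = IBISeries(intervals=x[keep], origin=ibi.origin)
    return cleaned, int((~keep).sum())
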