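"""Core data containers shared by every pipeline stage.

A recording moves through the pipeline as a :class:`SampledSignal`
(uniform sample grid, possibly with missing slots) and leaves the beat
detector as an :class:`IBISeries` (beat-to-beat intervals in
milliseconds).  Both are thin, validated wrappers around numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = ["IBIOrigin", "IBISeries", "SampledSignal"]


class IBIOrigin(str, Enum):
    """Provenance of an interval series."""

    TRUTH = "truth"
    DETECTED = "detected"
    FILE = "file"


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled waveform.

    Parameters
    ----------
    values : ndarray
        Sample amplitudes (arbitrary units).  Missing slots hold NaN.
    sampling_rate : float
        Samples per second; must be positive.
    start_time : float
        Time of the first sample slot, seconds.
    missing_mask : ndarray of bool
        True where the slot is missing.  Same length as ``values``.
        Defaults to all-present.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.missing_mask is None:
            mask = np.zeros(values.shape, dtype=bool)
        else:
            mask = np.asarray(self.missing_mask, dtype=bool)
            if mask.shape != values.shape:
                raise ValueError(
                    f"missing_mask length {mask.size} != values length {values.size}"
                )
        object.__setattr__(self, "missing_mask", mask)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Recording duration in seconds (slot count / sampling rate)."""
        return self.values.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Time of each sample slot, seconds."""
        return self.start_time + np.arange(self.values.size) / self.sampling_rate

    def with_values(self, values: np.ndarray, **changes) -> "SampledSignal":
        """Copy of this signal with new sample values (grid metadata kept).

        A length change discards the missing mask unless a new one is
        supplied.
        """
        values = np.asarray(values, dtype=float)
        if "missing_mask" not in changes and values.shape != self.values.shape:
            changes["missing_mask"] = None
        return replace(self, values=values, **changes)


@dataclass(frozen=True)
class IBISeries:
    """An ordered series of beat-to-beat intervals.

    ``intervals`` holds N positive interval lengths in milliseconds;
    ``event_times`` — when known — holds the N+1 cardiac event times in
    seconds that delimit them.  Series loaded from interval files or
    produced by outlier cleaning carry synthetic cumulative times.
    """

    intervals: np.ndarray
    event_times: np.ndarray = field(default=None)  # type: ignore[assignment]
    origin: IBIOrigin = IBIOrigin.TRUTH

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if intervals.size and np.any(intervals <= 0):
            raise ValueError("all intervals must be positive")
        if self.event_times is None:
            times = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
        else:
            times = np.asarray(self.event_times, dtype=float)
            if times.size != intervals.size + 1:
                raise ValueError(
                    f"event_times length {times.size} != n_intervals+1 "
                    f"({intervals.size + 1})"
                )
            if times.size > 1 and np.any(np.diff(times) <= 0):
                raise ValueError("event_times must be strictly increasing")
        object.__setattr__(self, "event_times", times)
        if not isinstance(self.origin, IBIOrigin):
            object.__setattr__(self, "origin", IBIOrigin(self.origin))

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def n_events(self) -> int:
        return self.event_times.size

    @property
    def duration(self) -> float:
        """Span from first to last event, seconds."""
        return float(self.event_times[-1] - self.event_times[0])
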