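"""Ultra-short-term time-domain indicators and the data-loss statistic.

All indicators are computed over the full recording (no sub-windowing):
mean heart rate, SDNN (sample SD of intervals, denominator N-1) and
RMSSD (root mean square of successive differences).  A paper-literal
RMSSD variant dividing by N-2 instead of the number of differences is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .core import IBISeries, SampledSignal

__all__ = ["PRVSummary", "mean_hr", "sdnn", "rmssd", "data_loss", "summarize"]


@dataclass(frozen=True)
class PRVSummary:
    """Per-recording indicator bundle."""

    mean_hr: float  # bpm
    mean_ibi: float  # ms
    sdnn: float  # ms
    rmssd: float  # ms
    n_events: int
    duration: float  # s
    data_loss: float  # %

    def to_dict(self) -> dict:
        d = asdict(self)
        return {
            "mean_hr_bpm": d["mean_hr"],
            "mean_ibi_ms": d["mean_ibi"],
            "sdnn_ms": d["sdnn"],
            "rmssd_ms": d["rmssd"],
            "n_events": d["n_events"],
            "duration_s": d["duration"],
            "data_loss_pct": d["data_loss"],
        }


def mean_hr(ibi: IBISeries, instantaneous: bool = False) -> float:
    """Mean heart rate in beats per minute.

    Default convention: 60000 / mean(IBI in ms).  ``instantaneous=True``
    averages the per-interval rates 60000/IBI_i instead.
    """
    if len(ibi) < 1:
        raise ValueError("need at least one interval")
    if instantaneous:
        return float(np.mean(60000.0 / ibi.intervals))
    return 60000.0 / float(np.mean(ibi.intervals))


def sdnn(ibi: IBISeries) -> float:
    """Sample standard deviation of the intervals (denominator N-1), ms."""
    if len(ibi) < 2:
        raise ValueError("need at least two intervals for SDNN")
    return float(np.std(ibi.intervals, ddof=1))


def rmssd(ibi: IBISeries, paper_literal: bool = False) -> float:
    """Root mean square of successive interval differences, ms.

    Default divides the sum of squared differences by the number of
    differences (N-1).  ``paper_literal=True`` divides by N-2 and
    requires at least three intervals.
    """
    n = len(ibi)
    if paper_literal and n < 3:
        raise ValueError("paper-literal RMSSD needs at least three intervals")
    if n < 2:
        raise ValueError("need at least two intervals for RMSSD")
    diffs = np.diff(ibi.intervals)
    denom = n - 2 if paper_literal else diffs.size
    return float(np.sqrt(np.sum(diffs**2) / denom))


def data_loss(signal: SampledSignal) -> float:
    """Percentage of missing sample slots in the recording."""
    n = len(signal)
    if n < 1:
        raise ValueError("signal has no sample slots")
    return 100.0 * float(np.count_nonzero(signal.missing_mask)) / n


def summarize(
    ibi: IBISeries,
    signal: SampledSignal | None = None,
    paper_literal_rmssd: bool = False,
) -> PRVSummary:
    """Bundle all indicators for one recording."""
    mean_ibi = float(np.mean(ibi.intervals))
    return PRVSummary(
        mean_hr=mean_hr(ibi),
        mean_ibi=mean_ibi,
        sdnn=sdnn(ibi),
        rmssd=rmssd(ibi, paper_literal=paper_literal_rmssd),
        n_events=ibi.n_events,
        duration=signal.duration if signal is not None else ibi.duration,
        data_loss=data_loss(signal) if signal is not None else 0.0,
    )
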