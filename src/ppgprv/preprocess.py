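"""Signal conditioning chain for raw PPG.

Order of operations: fill missing slots, moving average, baseline
correction by adaptive iteratively reweighted penalized least squares
(airPLS), sixth-order Butterworth low-pass (18 Hz default), second
derivative (APG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .core import SampledSignal

__all__ = [
    "FilterSpec",
    "fill_missing",
    "moving_average",
    "baseline_correct_airpls",
    "lowpass_iir",
    "second_derivative",
    "preprocess_signal",
]


@dataclass(frozen=True)
class FilterSpec:
    """Parameters of the conditioning chain."""

    ma_window: int = 5  # samples; odd
    airpls_lambda: float = 1e5
    airpls_max_iter: int = 15
    lowpass_cutoff: float = 18.0  # Hz
    lowpass_order: int = 6
    mode: str = "offline"  # offline (zero-phase) or streaming (causal)

    def __post_init__(self) -> None:
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise ValueError("ma_window must be odd and >= 1")
        if self.airpls_lambda <= 0:
            raise ValueError("airpls_lambda must be positive")
        if self.airpls_max_iter < 1:
            raise ValueError("airpls_max_iter must be >= 1")
        if self.lowpass_cutoff <= 0 or self.lowpass_order < 1:
            raise ValueError("invalid low-pass parameters")
        if self.mode not in ("offline", "streaming"):
            raise ValueError(f"mode must be 'offline' or 'streaming', got {self.mode!r}")


def fill_missing(signal: SampledSignal) -> SampledSignal:
    """Linearly interpolate missing sample slots.

    Leading/trailing gaps are held at the nearest observed value.  The
    missing mask is preserved so data-loss accounting stays intact.
    """
    values = signal.values
    missing = signal.missing_mask | np.isnan(values)
    if not missing.any():
        return signal
    if missing.all():
        raise ValueError("cannot fill a signal with no observed samples")
    idx = np.arange(values.size)
    filled = values.copy()
    filled[missing] = np.interp(idx[missing], idx[~missing], values[~missing])
    return signal.with_values(filled, missing_mask=missing)


def moving_average(signal: SampledSignal, window: int) -> SampledSignal:
    """Centered moving average; edges use shrinking windows.

    Missing slots must be filled first (see :func:`fill_missing`).
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd (center ambiguity), got {window}")
    n = len(signal)
    if not 1 <= window <= n:
        raise ValueError(f"window must lie in [1, {n}], got {window}")
    if np.isnan(signal.values).any():
        raise ValueError("signal contains NaN; call fill_missing first")
    if window == 1:
        return signal
    half = window // 2
    # Shrinking-window mean via cumulative sums: out[i] = mean(y[lo:hi]).
    csum = np.concatenate([[0.0], np.cumsum(signal.values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return signal.with_values(out)


def _airpls_baseline(y: np.ndarray, lam: float, max_iter: int) -> np.ndarray:
    """Fit the airPLS baseline of ``y``.

    Iteratively reweighted penalized least squares with a
    second-difference penalty; points above the running baseline lose
    weight each iteration so the fit settles underneath the pulses.
    """
    n = y.size
    diff = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (diff.T @ diff)
    w = np.ones(n)
    baseline = y
    for it in range(1, max_iter + 1):
        weights = sparse.diags(w, format="csc")
        baseline = spsolve((weights + penalty).tocsc(), w * y)
        resid = y - baseline
        neg = resid[resid < 0]
        neg_sum = np.abs(neg).sum()
        # Offset-invariant stop: scale by the centered signal magnitude.
        if neg_sum < 1e-3 * np.abs(y - y.mean()).sum() + 1e-300:
            break
        w = np.zeros(n)
        below = resid < 0
        w[below] = np.exp(it * np.abs(resid[below]) / neg_sum)
    return baseline


def baseline_correct_airpls(
    signal: SampledSignal, lam: float = 1e5, max_iter: int = 15
) -> SampledSignal:
    """Subtract an airPLS-estimated smooth baseline."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if len(signal) < 3:
        raise ValueError("signal too short for baseline estimation")
    if not signal.values.any():
        return signal
    baseline = _airpls_baseline(signal.values, lam, max_iter)
    return signal.with_values(signal.values - baseline)


def lowpass_iir(signal: SampledSignal, spec: FilterSpec) -> SampledSignal:
    """Butterworth low-pass.

    Offline mode runs forward-backward passes (zero net phase);
    streaming mode is a single causal pass.
    """
    nyquist = signal.sampling_rate / 2.0
    if spec.lowpass_cutoff >= nyquist:
        raise ValueError(
            f"cutoff {spec.lowpass_cutoff} Hz must be below the Nyquist "
            f"frequency {nyquist} Hz"
        )
    sos = sps.butter(
        spec.lowpass_order, spec.lowpass_cutoff, btype="low",
        fs=signal.sampling_rate, output="sos",
    )
    if spec.mode == "offline":
        out = sps.sosfiltfilt(sos, signal.values)
    else:
        out = sps.sosfilt(sos, signal.values)
    return signal.with_values(out)


def streaming_group_delay(spec: FilterSpec, sampling_rate: float) -> float:
    """Mean passband group delay of the causal filter, in samples."""
    b, a = sps.butter(
        spec.lowpass_order, spec.lowpass_cutoff, btype="low", fs=sampling_rate
    )
    freqs = np.linspace(0.0, spec.lowpass_cutoff * 0.8, 64)
    _, gd = sps.group_delay((b, a), w=freqs, fs=sampling_rate)
    return float(np.mean(gd))


def second_derivative(signal: SampledSignal) -> SampledSignal:
    """Second difference scaled by the sampling interval squared (APG).

    Interior points use the central stencil; endpoints reuse the
    one-sided stencil of their nearest interior neighbour, so output
    length equals input length.
    """
    y = signal.values
    if y.size < 3:
        raise ValueError("signal too short for a second derivative")
    dt = 1.0 / signal.sampling_rate
    out = np.empty_like(y)
    out[1:-1] = (y[2:] - 2.0 * y[1:-1] + y[:-2]) / dt**2
    out[0] = (y[2] - 2.0 * y[1] + y[0]) / dt**2
    out[-1] = (y[-1] - 2.0 * y[-2] + y[-3]) / dt**2
    return signal.with_values(out)


def preprocess_signal(signal: SampledSignal, spec: FilterSpec | None = None) -> SampledSignal:
    """Run the full conditioning chain, raw PPG in, APG out."""
    spec = spec or FilterSpec()
    out = fill_missing(signal)
    out = moving_average(out, spec.ma_window)
    out = baseline_correct_airpls(out, spec.airpls_lambda, spec.airpls_max_iter)
    out = lowpass_iir(out, spec)
    return second_derivative(out)
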