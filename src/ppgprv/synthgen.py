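"""Ground-truthed synthetic PPG recordings.

Interval series are drawn from a stationary AR(1) process plus a
respiration-locked sinusoid, so the target SDNN / RMSSD pair maps onto
the process parameters in closed form::

    RMSSD^2 = 2 * SDNN^2 * (1 - rho1)

The rendered waveform places a fixed two-lobe pulse template at each
beat time, with optional additive noise, baseline wander and Bernoulli
sample dropout, and reports the true event sample indices so detector
output can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .core import IBIOrigin, IBISeries, SampledSignal

__all__ = [
    "BeatTemplate",
    "ScenarioPreset",
    "PRESETS",
    "load_presets",
    "dump_presets",
    "generate_ibi_series",
    "render_ppg",
    "apply_dropout",
    "simulate_recording",
]

IBI_CLIP_MS = (300.0, 2000.0)  # physiological plausibility bounds


@dataclass(frozen=True)
class ScenarioPreset:
    """Named simulation parameter set for one posture/breathing scenario."""

    name: str
    target_mean_ibi: float  # ms
    target_sdnn: float  # ms
    target_rmssd: float  # ms
    respiration_rate: float = 15.0  # breaths/min
    rsa_amplitude: float = 0.0  # ms
    dropout_rate: float = 0.01
    duration: float = 180.0  # s

    def __post_init__(self) -> None:
        if self.target_mean_ibi <= 0:
            raise ValueError("target_mean_ibi must be positive")
        if self.target_sdnn < 0 or self.target_rmssd < 0:
            raise ValueError("target_sdnn and target_rmssd must be non-negative")
        if self.target_sdnn > 0 and self.target_rmssd > 2.0 * self.target_sdnn:
            raise ValueError(
                "target_rmssd must not exceed 2*target_sdnn "
                f"(got rmssd={self.target_rmssd}, sdnn={self.target_sdnn})"
            )
        if not 0.0 <= self.dropout_rate < 0.5:
            raise ValueError("dropout_rate must lie in [0, 0.5)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def lag1_autocorrelation(self) -> float:
        """AR(1) lag-1 autocorrelation implied by the SDNN/RMSSD targets."""
        if self.target_sdnn == 0:
            return 0.0
        rho = 1.0 - self.target_rmssd**2 / (2.0 * self.target_sdnn**2)
        if not -1.0 <= rho <= 1.0:
            raise ValueError(
                f"targets imply lag-1 autocorrelation {rho:.3f} outside [-1, 1]"
            )
        return rho

    @property
    def respiration_hz(self) -> float:
        return self.respiration_rate / 60.0


def _preset_registry() -> dict[str, ScenarioPreset]:
    with resources.files("ppgprv").joinpath("data/presets.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {name: ScenarioPreset(name=name, **params) for name, params in raw.items()}


def load_presets(path) -> dict[str, ScenarioPreset]:
    """Load a scenario-preset registry from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ValueError(f"no presets found in {path}")
    return {name: ScenarioPreset(name=name, **params) for name, params in raw.items()}


def dump_presets(presets: dict[str, ScenarioPreset], path) -> None:
    """Write a preset registry to YAML; inverse of :func:`load_presets`."""
    out = {}
    for name, p in presets.items():
        out[name] = {
            "target_mean_ibi": p.target_mean_ibi,
            "target_sdnn": p.target_sdnn,
            "target_rmssd": p.target_rmssd,
            "respiration_rate": p.respiration_rate,
            "rsa_amplitude": p.rsa_amplitude,
            "dropout_rate": p.dropout_rate,
            "duration": p.duration,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


PRESETS: dict[str, ScenarioPreset] = _preset_registry()


def generate_ibi_series(
    preset: ScenarioPreset, n_beats: int, seed: int
) -> IBISeries:
    """Draw a ground-truth interval series for one scenario.

    The series is ``mu + RSA*sin(2*pi*f_resp*t_k) + eps_k`` with ``eps``
    an AR(1) process whose marginal SD equals ``target_sdnn`` and whose
    lag-1 autocorrelation is solved from the RMSSD target.  Intervals
    are clipped to physiological bounds and the result is reproducible
    for a fixed seed.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be at least 2")
    rho = preset.lag1_autocorrelation  # validates the target pair
    rng = np.random.default_rng(seed)
    sigma = preset.target_sdnn
    n_beats = n_beats - 1  # n_beats cardiac events delimit n_beats-1 intervals

    eps = np.zeros(n_beats)
    if sigma > 0:
        innovation_sd = sigma * np.sqrt(max(1.0 - rho**2, 0.0))
        eps[0] = rng.normal(0.0, sigma)
        shocks = rng.normal(0.0, innovation_sd, size=n_beats - 1)
        for k in range(1, n_beats):
            eps[k] = rho * eps[k - 1] + shocks[k - 1]

    intervals = np.empty(n_beats)
    t = 0.0  # running event time, seconds
    f_resp = preset.respiration_hz
    for k in range(n_beats):
        ibi = preset.target_mean_ibi + eps[k]
        if preset.rsa_amplitude:
            ibi += preset.rsa_amplitude * np.sin(2.0 * np.pi * f_resp * t)
        intervals[k] = min(max(ibi, IBI_CLIP_MS[0]), IBI_CLIP_MS[1])
        t += intervals[k] / 1000.0

    return IBISeries(intervals=intervals, origin=IBIOrigin.TRUTH)


@dataclass(frozen=True)
class BeatTemplate:
    """Fixed pulse shape placed at each beat time.

    The systolic lobe is an asymmetric Gaussian (steep upstroke, slower
    decay) so the second derivative of the pulse has a single dominant
    positive peak; the dicrotic lobe is a smaller, broader bump on the
    falling edge.
    """

    width_ms: float = 450.0
    amplitude: float = 1.0
    systolic_pos: float = 0.28  # peak location, fraction of width
    systolic_rise: float = 0.09  # left-side sigma, fraction of width
    systolic_fall: float = 0.22  # right-side sigma, fraction of width
    dicrotic_pos: float = 0.62
    dicrotic_width: float = 0.16
    dicrotic_amplitude_frac: float = 0.30

    def waveform(self, sampling_rate: float) -> np.ndarray:
        """Render the template on the device sample grid."""
        n = max(int(round(self.width_ms / 1000.0 * sampling_rate)), 3)
        t = np.arange(n) / sampling_rate  # s
        w = self.width_ms / 1000.0
        mu = self.systolic_pos * w
        sig = np.where(t < mu, self.systolic_rise * w, self.systolic_fall * w)
        pulse = self.amplitude * np.exp(-0.5 * ((t - mu) / sig) ** 2)
        mu_d = self.dicrotic_pos * w
        sig_d = self.dicrotic_width * w
        pulse += (
            self.amplitude
            * self.dicrotic_amplitude_frac
            * np.exp(-0.5 * ((t - mu_d) / sig_d) ** 2)
        )
        return pulse

    def apg_peak_offset(self, sampling_rate: float) -> int:
        """Sample offset of the dominant positive APG peak within the template."""
        wave = self.waveform(sampling_rate)
        if not wave.any():
            return 0
        curvature = np.diff(wave, 2)  # interior second differences
        return int(np.argmax(curvature)) + 1


def render_ppg(
    ibi: IBISeries,
    sampling_rate: float = 40.0,
    template: BeatTemplate | None = None,
    noise_sd: float = 0.0,
    wander_amplitude: float = 0.0,
    wander_freq: float = 0.25,
    seed: int = 0,
    lead_pad: float = 0.5,
    tail_pad: float = 0.5,
) -> tuple[SampledSignal, np.ndarray]:
    """Render an interval series as a sampled PPG waveform.

    ``lead_pad``/``tail_pad`` seconds of baseline surround the pulse
    train so filter edge effects stay clear of the beats.  Returns the
    signal and the ground-truth event sample indices (one per beat, at
    the dominant positive APG peak of each placed template) for
    detector scoring.
    """
    if sampling_rate < 20.0:
        raise ValueError("sampling_rate must be at least 20 Hz")
    if len(ibi) == 0:
        raise ValueError("interval series is empty")
    template = template or BeatTemplate()
    shortest = float(np.min(ibi.intervals))
    if template.amplitude != 0 and template.width_ms > shortest:
        raise ValueError(
            f"beat template width {template.width_ms} ms exceeds shortest "
            f"interval {shortest:.1f} ms; pulses would merge"
        )

    beat_times = ibi.event_times - ibi.event_times[0] + lead_pad
    total = beat_times[-1] + template.width_ms / 1000.0 + tail_pad
    n_samples = int(np.ceil(total * sampling_rate))
    values = np.zeros(n_samples)

    wave = template.waveform(sampling_rate)
    onsets = np.round(beat_times * sampling_rate).astype(int)
    for onset in onsets:
        stop = min(onset + wave.size, n_samples)
        values[onset:stop] += wave[: stop - onset]

    rng = np.random.default_rng(seed)
    if wander_amplitude:
        t = np.arange(n_samples) / sampling_rate
        phase = rng.uniform(0.0, 2.0 * np.pi)
        values += wander_amplitude * np.sin(2.0 * np.pi * wander_freq * t + phase)
    if noise_sd:
        values += rng.normal(0.0, noise_sd, size=n_samples)

    truth = onsets + template.apg_peak_offset(sampling_rate)
    return SampledSignal(values=values, sampling_rate=sampling_rate), truth


def apply_dropout(
    signal: SampledSignal,
    dropout_rate: float,
    seed: int,
    burst_mean_length: float = 1.0,
) -> SampledSignal:
    """Mark a random subset of sample slots missing.

    Per-slot i.i.d. Bernoulli by default; ``burst_mean_length > 1``
    switches to geometric bursts with the same expected loss fraction.
    Missing slots keep their grid position with a NaN value.
    """
    if not 0.0 <= dropout_rate < 0.5:
        raise ValueError("dropout_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = len(signal)
    if dropout_rate == 0.0 or n == 0:
        return signal
    if burst_mean_length <= 1.0:
        mask = rng.random(n) < dropout_rate
    else:
        # Bursts start at rate r/L and run geometric(mean L) samples.
        mask = np.zeros(n, dtype=bool)
        starts = rng.random(n) < dropout_rate / burst_mean_length
        for idx in np.nonzero(starts)[0]:
            length = rng.geometric(1.0 / burst_mean_length)
            mask[idx : idx + length] = True
    values = signal.values.copy()
    values[mask] = np.nan
    return signal.with_values(values, missing_mask=mask | signal.missing_mask)


def simulate_recording(
    preset: ScenarioPreset,
    sampling_rate: float = 40.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    wander_amplitude: float = 0.0,
    dropout_rate: float | None = None,
    template: BeatTemplate | None = None,
) -> tuple[SampledSignal, IBISeries, np.ndarray]:
    """Generate one full scenario recording.

    Convenience wrapper: draws enough beats to cover ``preset.duration``,
    renders the waveform, applies dropout, and returns
    ``(signal, truth_ibi, truth_event_indices)``.  All randomness is
    derived from ``seed``.
    """
    # Over-provision beats, then trim to the requested duration.
    n_beats = int(np.ceil(preset.duration * 1000.0 / preset.target_mean_ibi * 1.5)) + 6
    ibi = generate_ibi_series(preset, n_beats=n_beats, seed=seed)
    keep = np.searchsorted(ibi.event_times, preset.duration, side="left")
    keep = max(int(keep), 2)
    ibi = IBISeries(
        intervals=ibi.intervals[:keep],
        event_times=ibi.event_times[: keep + 1],
        origin=IBIOrigin.TRUTH,
    )
    signal, truth = render_ppg(
        ibi,
        sampling_rate=sampling_rate,
        template=template,
        noise_sd=noise_sd,
        wander_amplitude=wander_amplitude,
        seed=seed + 1,
    )
    rate = preset.dropout_rate if dropout_rate is None else dropout_rate
    signal = apply_dropout(signal, rate, seed=seed + 2)
    return signal, ibi, truth
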