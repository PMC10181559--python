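"""File formats: the `t_s,ppg` signal CSV dialect, RR/PP interval text
files (one millisecond value per line, Kubios-compatible), cohort CSVs,
and the run configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beat_detection import DetectorParams
from .core import IBIOrigin, IBISeries, SampledSignal
from .preprocess import FilterSpec

__all__ = [
    "RunConfig",
    "read_signal_csv",
    "write_signal_csv",
    "read_rr_text",
    "write_rr_text",
    "read_cohort_csv",
]

SCHEMA_VERSION = 1
_JITTER_TOLERANCE = 0.01  # fractional grid jitter accepted before erroring


def read_signal_csv(path, fs_override: float | None = None) -> SampledSignal:
    """Read a `t_s,ppg` CSV into a sampled signal.

    The sampling rate is inferred from the median time step (override
    with ``fs_override`` when the grid is too jittery).  Empty value
    fields become missing slots; skipped grid slots are expanded into
    missing slots so data-loss accounting sees them.
    """
    frame = pd.read_csv(path)
    if list(frame.columns[:2]) != ["t_s", "ppg"]:
        raise ValueError(f"expected header 't_s,ppg', got {list(frame.columns)}")
    if len(frame) < 2:
        raise ValueError("signal file needs at least two rows")
    t = frame["t_s"].to_numpy(dtype=float)
    v = frame["ppg"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt < 0):
        raise ValueError("time column must be monotone non-decreasing")
    if fs_override is not None:
        fs = fs_override
        step = 1.0 / fs
    else:
        positive = dt[dt > 0]
        if positive.size == 0:
            raise ValueError("cannot infer sampling rate from repeated times")
        # Median of the smallest-step cluster: robust both to grid jitter
        # and to skipped slots (which show up as multi-step gaps).
        smallest = float(np.min(positive))
        cluster = positive[positive <= smallest * (1.0 + _JITTER_TOLERANCE)]
        step = float(np.median(cluster))
        # Off-grid steps must be near-integer multiples of the median step.
        multiples = positive / step
        if np.any(np.abs(multiples - np.round(multiples)) > _JITTER_TOLERANCE):
            raise ValueError(
                "inconsistent sample grid (jitter > 1%); pass fs_override"
            )
        fs = 1.0 / step

    slots = np.round((t - t[0]) / step).astype(int)
    n = int(slots[-1]) + 1
    values = np.full(n, np.nan)
    values[slots] = v
    mask = np.isnan(values)
    return SampledSignal(
        values=values, sampling_rate=fs, start_time=float(t[0]), missing_mask=mask
    )


def write_signal_csv(signal: SampledSignal, path) -> None:
    """Write the `t_s,ppg` dialect; missing slots keep their row with an
    empty value field."""
    times = signal.times
    with open(path, "w", newline="\n") as fh:
        fh.write("t_s,ppg\n")
        for t, v, missing in zip(times, signal.values, signal.missing_mask):
            if missing or np.isnan(v):
                fh.write(f"{t:.6f},\n")
            else:
                fh.write(f"{t:.6f},{v:.8g}\n")


def read_rr_text(path, origin: IBIOrigin = IBIOrigin.FILE) -> IBISeries:
    """Read an interval file: one ms value per line, blank lines ignored."""
    intervals = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                intervals.append(float(line))
            except ValueError:
                raise ValueError(f"{path}: non-numeric value on line {lineno}: {line!r}")
    if not intervals:
        raise ValueError(f"{path}: no intervals found")
    return IBISeries(intervals=np.asarray(intervals), origin=origin)


def write_rr_text(ibi: IBISeries, path) -> None:
    """Write intervals one per line, newline-terminated."""
    with open(path, "w", newline="\n") as fh:
        for value in ibi.intervals:
            if float(value).is_integer():
                fh.write(f"{int(value)}\n")
            else:
                fh.write(f"{value:.10g}\n")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a paired cohort table (subject_id,scenario,indicator,ecg_value,ppg_value)."""
    frame = pd.read_csv(path)
    required = {"subject_id", "scenario", "indicator", "ecg_value", "ppg_value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return frame


@dataclass
class RunConfig:
    """Serializable bundle of every pipeline knob."""

    presets_path: str | None = None
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    detector: DetectorParams = field(default_factory=DetectorParams)
    clean_min_ms: float = 300.0
    clean_max_ms: float = 2000.0
    clean_median_band: float = 0.3
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "presets_path": self.presets_path,
            "filter_spec": asdict(self.filter_spec),
            "detector": asdict(self.detector),
            "clean_min_ms": self.clean_min_ms,
            "clean_max_ms": self.clean_max_ms,
            "clean_median_band": self.clean_median_band,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        raw.pop("schema_version", None)
        filter_spec = FilterSpec(**raw.pop("filter_spec", {}))
        detector = DetectorParams(**raw.pop("detector", {}))
        return cls(filter_spec=filter_spec, detector=detector, **raw)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def write_json(obj: dict, path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")
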