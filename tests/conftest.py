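import numpy as np
import pytest

from ppgprv import PRESETS, simulate_recording
from ppgprv.preprocess import preprocess_signal


@pytest.fixture(scope="session")
def clean_recordings():
    """One noise-free, dropout-free recording per preset (seed 0)."""
    out = {}
    for name, preset in PRESETS.items():
        signal, ibi, truth = simulate_recording(preset, seed=0, dropout_rate=0.0)
        out[name] = {"signal": signal, "ibi": ibi, "truth": truth}
    return out


@pytest.fixture(scope="session")
def clean_apg(clean_recordings):
    """Preprocessed APG for each clean recording."""
    return {
        name: preprocess_signal(rec["signal"])
        for name, rec in clean_recordings.items()
    }


def match_events(detected: np.ndarray, truth: np.ndarray, tol: int = 2):
    """(tp, fp, fn) with a +/-tol sample matching window."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    tp = sum(1 for t in truth if detected.size and np.min(np.abs(detected - t)) <= tol)
    fp = len(detected) - sum(
        1 for d in detected if truth.size and np.min(np.abs(truth - d)) <= tol
    )
    fn = len(truth) - tp
    return tp, fp, fn
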