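import numpy as np
import pandas as pd
import pytest

from gazepref.io_formats import GazeRecording


def make_recording(
    pupil,
    x=None,
    y=None,
    valid=None,
    fs=30.0,
    trial_id=1,
    phase="stimulus",
    participant_id="P001",
):
    """Build a small GazeRecording from raw arrays; NaN pupil means invalid."""
    pupil = np.asarray(pupil, dtype=float)
    n = len(pupil)
    if valid is None:
        valid = np.isfinite(pupil)
    valid = np.asarray(valid, dtype=bool)
    x = np.full(n, 960.0) if x is None else np.asarray(x, dtype=float)
    y = np.full(n, 540.0) if y is None else np.asarray(y, dtype=float)
    samples = pd.DataFrame(
        {
            "t": np.arange(n) / fs,
            "x": np.where(valid, x, np.nan),
            "y": np.where(valid, y, np.nan),
            "pupil": np.where(valid, pupil, np.nan),
            "valid": valid,
            "trial_id": np.full(n, trial_id, dtype=int),
            "phase": np.full(n, phase, dtype=object),
        }
    )
    return GazeRecording(participant_id=participant_id, samples=samples, fs=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
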