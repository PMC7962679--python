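import numpy as np
import pytest

from msaccade.io import GazeRecording


def make_recording(x_l=None, y_l=None, x_r=None, y_r=None,
                   pupil_l=None, pupil_r=None, n=None, rate=1000.0):
    """Small binocular recording with sensible defaults for unit tests."""
    if n is None:
        n = len(next(a for a in (x_l, y_l, x_r, y_r, pupil_l, pupil_r)
                     if a is not None))
    def arr(a, fill):
        return np.full(n, fill, dtype=float) if a is None else np.asarray(a, float)
    return GazeRecording(
        t_ms=np.arange(n) * (1000.0 / rate),
        x_l=arr(x_l, 0.0), y_l=arr(y_l, 0.0),
        x_r=arr(x_r, 0.0), y_r=arr(y_r, 0.0),
        pupil_l=arr(pupil_l, 1000.0), pupil_r=arr(pupil_r, 1000.0),
        sampling_rate=rate)


@pytest.fixture
def quiet_trial():
    """60 s artifact-free trial with microsaccades, shared across tests."""
    from msaccade.simulate import SimConfig, simulate_trial
    cfg = SimConfig(ms_rate=1.0, blink_rate=0.0, semiblink_rate=0.0)
    return simulate_trial(cfg, seed=42)


@pytest.fixture
def default_trial():
    """60 s trial with the default artifact load (blinks + semi-blinks)."""
    from msaccade.simulate import SimConfig, simulate_trial
    return simulate_trial(SimConfig(ms_rate=1.0), seed=7)
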