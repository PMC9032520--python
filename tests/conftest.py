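import numpy as np
import pytest

from gazeauth.core import GazeRecording, ScreenGeometry


@pytest.fixture
def geom():
    return ScreenGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(theta_x, theta_y, sample_rate=1000.0, task="FXS", subject="S000"):
    theta_x = np.asarray(theta_x, dtype=float)
    return GazeRecording(
        subject_id=subject,
        task=task,
        round=1,
        session=1,
        timestamps=np.arange(len(theta_x)) * (1000.0 / sample_rate),
        theta_x=theta_x,
        theta_y=np.asarray(theta_y, dtype=float),
        sample_rate=sample_rate,
    )
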