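import numpy as np
import pytest

from hfital import AccelRecording, AlgorithmParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hfital_params():
    return AlgorithmParams.hfital()


@pytest.fixture
def moxal_params():
    return AlgorithmParams.moxal()


def make_recording(longitudinal, anterior_posterior=None, medio_lateral=None, fs=25.0, subject_id="test"):
    """Recording with the default axis-role layout (x=long, y=ap, z=ml)."""
    longitudinal = np.asarray(longitudinal, dtype=float)
    n = longitudinal.size
    ap = np.zeros(n) if anterior_posterior is None else np.asarray(anterior_posterior, dtype=float)
    ml = np.zeros(n) if medio_lateral is None else np.asarray(medio_lateral, dtype=float)
    return AccelRecording(np.column_stack([longitudinal, ap, ml]), sample_rate_hz=fs, subject_id=subject_id)


@pytest.fixture
def still_standing():
    return make_recording(np.ones(1500))


@pytest.fixture
def still_sedentary():
    return make_recording(np.zeros(1500), anterior_posterior=np.ones(1500))
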