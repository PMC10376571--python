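import numpy as np
import pytest

from emgexo import synth


@pytest.fixture(scope="session")
def small_protocol() -> synth.AcquisitionProtocol:
    """One subject, one series: 50 recordings, 10 per gesture."""
    return synth.AcquisitionProtocol(n_subjects=1, n_series=1, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_protocol):
    return synth.generate_gesture_dataset(small_protocol)


@pytest.fixture(scope="session")
def rest_baseline() -> np.ndarray:
    rest = synth.generate_rest_recording(duration_s=5.0, seed=7)
    return np.sqrt(np.mean(rest.samples**2, axis=1))
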