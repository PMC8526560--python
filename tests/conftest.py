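import numpy as np
import pytest

from nvckit.sos import SecondOrderParams
from nvckit.synth import SubjectTruth, simulate_nvc_recording


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def clean_truth():
    """A noise- and artifact-free synthetic subject with known dynamics."""
    return SubjectTruth(
        group="control",
        sos=SecondOrderParams(K=15.0, Tv=0.0, omega=0.2, xi=0.4),
        baseline_systolic=45.0, hr_bpm=60.0,
        noise_sd_pct=0.0, artifact_rate=0.0)


@pytest.fixture(scope="session")
def clean_session(clean_truth):
    """One noiseless stimulation session (400 Hz), reused across tests."""
    return simulate_nvc_recording(clean_truth, fs=400.0, seed=7)
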