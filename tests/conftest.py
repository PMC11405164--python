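import numpy as np
import pytest

from pupilkit import build_default_timeline, simulate_subject
from pupilkit.simulate import SubjectParams, noiseless


@pytest.fixture(scope="session")
def timeline():
    return build_default_timeline()


@pytest.fixture(scope="session")
def clean_trace(timeline):
    """Noiseless symmetric subject: no hippus, noise, blinks or artifacts."""
    return simulate_subject(noiseless(), timeline)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240903)


def make_subject(**overrides) -> SubjectParams:
    return SubjectParams(**overrides)
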