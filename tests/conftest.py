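import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dsrna.config import RunConfig
from dsrna.stages import DEFAULT_STAGES
from dsrna.structure import ReactivityProfile

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def stages():
    return DEFAULT_STAGES


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_profile(tid, stage, values, missing=None, base=None):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros(values.size, dtype=bool)
    return ReactivityProfile(
        transcript_id=tid, stage=stage, reactivity=values,
        missing=np.asarray(missing, dtype=bool),
        base=None if base is None else np.asarray(base, dtype="U1"),
    )


@pytest.fixture
def profile_factory():
    return make_profile
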