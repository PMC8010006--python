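import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fareyrt import build_tree, devils_staircase


@pytest.fixture(scope="session")
def tree():
    return build_tree(5)


@pytest.fixture(scope="session")
def staircase():
    """Full 0.001-grid staircase at the analysis parameters, fixed seed."""
    return devils_staircase(rng=np.random.default_rng(123))


@pytest.fixture(scope="session")
def coarse_staircase():
    return devils_staircase(
        omega_grid=np.linspace(0.0, 1.0, 101), rng=np.random.default_rng(123)
    )


def make_stream(stimuli, responses=None, rts=None, participant="p1"):
    """Build a single-participant trial stream from letter strings."""
    stimuli = list(stimuli)
    responses = list(responses) if responses is not None else stimuli
    n = len(stimuli)
    rts = [500.0] * n if rts is None else list(rts)
    return pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(n),
            "stimulus": stimuli,
            "response": responses,
            "correct": [int(s == r) for s, r in zip(stimuli, responses)],
            "rt_ms": rts,
        }
    )


@pytest.fixture
def stream_factory():
    return make_stream
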