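import numpy as np
import pytest

from strainrl.environments import Environment, identity_transform


def make_stub_env(
    n_enzymes=3,
    n_state=4,
    state_value=5.0,
    response=2.0,
    raw_bounds=(0.1, 10.0),
    identity=False,
):
    """A constant environment: fixed state vector and fixed response."""
    kwargs = {}
    if identity:
        kwargs = {
            "raw_bounds": (0.0, 1.0),
            "transform": identity_transform[0],
            "inverse": identity_transform[1],
        }
    elif raw_bounds != (0.1, 10.0):
        kwargs = {"raw_bounds": raw_bounds}
    return Environment(
        name="stub",
        n_enzymes=n_enzymes,
        n_state=n_state,
        step_fn=lambda d, p: (np.full(n_state, state_value), response),
        **kwargs,
    )


@pytest.fixture
def stub_env():
    return make_stub_env()
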