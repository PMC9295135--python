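import numpy as np
import pytest

from eccrca.caller import CallerParams
from eccrca.simulate import SimParams, simulate_dataset


@pytest.fixture
def params() -> CallerParams:
    return CallerParams()


@pytest.fixture(scope="session")
def clean_sim():
    """Zero-noise, whole-pass simulation shared by end-to-end tests."""
    return simulate_dataset(
        SimParams(seed=11, n_circles=60, partial_passes=False, jitter=0, reread_poisson=0.0)
    )


@pytest.fixture(scope="session")
def variant_sim():
    """Zero-error simulation with planted template SNVs and deep passes."""
    return simulate_dataset(
        SimParams(
            seed=13,
            n_circles=40,
            partial_passes=False,
            jitter=0,
            snv_rate=0.003,
            pass_min=4,
            reread_poisson=0.0,
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
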