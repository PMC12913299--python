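import numpy as np
import pytest

from difflens import canonical_environment


@pytest.fixture(scope="session")
def env():
    return canonical_environment()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_experiment():
    """A small reproducible synthetic experiment shared across tests."""
    from difflens import StaticParams, SyntheticConfig, simulate_experiment

    config = SyntheticConfig(
        n_participants=6,
        preset="congruent",
        condition="congruent",
        statics=StaticParams(v0=0.0, b_tau=0.15, beta=0.5),
        seed=7,
    )
    return simulate_experiment(config)
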