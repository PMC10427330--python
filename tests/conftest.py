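import numpy as np
import pytest

from coopnorms import CommunityParams, NormSensitivity, naive_belief


@pytest.fixture(scope="session")
def coordination_ns() -> NormSensitivity:
    return NormSensitivity(mean=0.5, variance=0.04)


@pytest.fixture(scope="session")
def cooperation_ns() -> NormSensitivity:
    return NormSensitivity(mean=0.7, variance=0.04)


@pytest.fixture(scope="session")
def p_tilde(coordination_ns) -> float:
    """Naive belief: the high-cooperation root of the bistable reference."""
    return naive_belief(coordination_ns)


@pytest.fixture(scope="session")
def coordination_params(coordination_ns, p_tilde) -> CommunityParams:
    return CommunityParams(
        inflow_rate=1.0,
        learning_rate=1.0,
        outflow_rate=0.1,
        resusceptibility=1.0,
        K=1.0,
        p_tilde=p_tilde,
        norms=coordination_ns,
    )


@pytest.fixture(scope="session")
def cooperation_params(cooperation_ns, p_tilde) -> CommunityParams:
    return CommunityParams(
        inflow_rate=1.0,
        learning_rate=1.0,
        outflow_rate=0.5,
        resusceptibility=1.0,
        K=1.0,
        p_tilde=p_tilde,
        norms=cooperation_ns,
    )


def random_params(rng: np.random.Generator, p_tilde: float) -> CommunityParams:
    """A broad but admissible random parameterisation (cooperation regime)."""
    return CommunityParams(
        inflow_rate=float(rng.uniform(0.2, 2.0)),
        learning_rate=float(rng.uniform(0.3, 2.0)),
        outflow_rate=float(rng.uniform(0.05, 1.5)),
        resusceptibility=float(rng.uniform(0.2, 2.0)),
        K=1.0,
        p_tilde=p_tilde,
        norms=NormSensitivity(float(rng.uniform(0.55, 0.8)), float(rng.uniform(0.02, 0.09))),
    )
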