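import numpy as np
import pytest

from oralpk import (
    AbsorptionInput,
    Disposition3C,
    ErrorModel,
    IGInput,
    preset_design,
    simulate_study,
)


@pytest.fixture(scope="session")
def absorption():
    """A slow, clearly bimodal two-IG input (trospium-like truth)."""
    return AbsorptionInput(
        D=30.0,
        F=0.1,
        p=0.35,
        ig1=IGInput(MT=2.5, RD2=0.5),
        ig2=IGInput(MT=12.5, RD2=0.4),
    )


@pytest.fixture(scope="session")
def disposition():
    return Disposition3C(V1=50, CL=10, CLd2=20, V2=100, CLd3=5, V3=200)


@pytest.fixture(scope="session")
def trospium_design():
    return preset_design("trospium_like", seed=1)


@pytest.fixture(scope="session")
def trospium_sim(trospium_design):
    return simulate_study(trospium_design)


@pytest.fixture(scope="session")
def tiny_error():
    """Effectively noise-free residual model for deterministic fits."""
    return ErrorModel(sd_intercept=1e-6, sd_slope=1e-4)


@pytest.fixture
def rng():
    return np.random.default_rng(20230818)
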