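import numpy as np
import pytest

from fleffect import ModelParams


@pytest.fixture
def human_params() -> ModelParams:
    """Typical human-blood configuration: bulk viscosity 3.3, marginal
    fraction 0.1, exclusion half-thickness 1.2 μm."""
    return ModelParams(eta_c=3.3, alpha=0.1, a_star_um=1.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
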