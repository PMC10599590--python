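import numpy as np
import pytest

from eescreen import ParameterSpace, ParameterSpec


@pytest.fixture
def two_range_space() -> ParameterSpace:
    """The Y = X1 + X2 example space: equal means, very different ranges."""
    return ParameterSpace(
        [
            ParameterSpec("X1", min=0.0, max=20.0, levels=4),
            ParameterSpec("X2", min=9.0, max=11.0, levels=4),
        ]
    )


@pytest.fixture
def mixed_space() -> ParameterSpace:
    """Real + integer + boolean inputs with admissible level counts."""
    return ParameterSpace(
        [
            ParameterSpec("temp", vtype="real", min=5.0, max=35.0, levels=4, units="C"),
            ParameterSpec("n_layers", vtype="integer", min=1.0, max=7.0, levels=4),
            ParameterSpec("irrigated", vtype="boolean", min=0.0, max=1.0, levels=2),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
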