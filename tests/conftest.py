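import numpy as np
import pytest

from extrumech.synth import PopulationSpec, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def extruded_population():
    """Default extruded (unilamellar, 137 ± 15 nm) population, fixed seed."""
    return generate_population(PopulationSpec(seed=7))


@pytest.fixture
def labelled_population():
    """50/50 donor-only / acceptor-only population, fixed seed."""
    spec = PopulationSpec(
        seed=7,
        label_fractions={"donor": 0.5, "acceptor": 0.5, "dual": 0.0, "none": 0.0})
    return generate_population(spec)
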