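import numpy as np
import pytest

from hotspots.models import TrainingConfig
from hotspots.structure import read_complex
from hotspots.synthetic import ToyComplexSpec, generate_toy_complex

# Small grids keep the many inner-CV fits in selection tests fast without
# changing the search semantics.
FAST_CONFIG = TrainingConfig(C_grid=(0.1, 1.0, 10.0), class_weight_grid=(1.0, 2.0))


@pytest.fixture(scope="session")
def toy_spec() -> ToyComplexSpec:
    return ToyComplexSpec(
        chains={"A": "NKSWERYTQLD", "B": "LNDYKERWSTQ"},
        separation=10.0,
        planted={"A": {3: None, 5: None}, "B": {5: None, 8: None}},
        jitter_sd=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def toy_pdb(toy_spec):
    pdb_text, truth = generate_toy_complex(toy_spec)
    return pdb_text, truth


@pytest.fixture(scope="session")
def toy_complex(toy_pdb):
    pdb_text, _ = toy_pdb
    return read_complex(pdb_text, {"A"}, {"B"})


@pytest.fixture(scope="session")
def fast_config() -> TrainingConfig:
    return FAST_CONFIG


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
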