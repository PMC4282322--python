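import numpy as np
import pytest

from flexbind.mmpbsa import FreeEnergyOptions, SpeciesEnsemble
from flexbind.pb import PBOptions
from flexbind.synth import ToyComplexSpec, make_ensemble, make_toy_complex


@pytest.fixture(scope="session")
def toy():
    return make_toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_ensembles(toy):
    return make_ensemble(toy, n_frames=4, fluctuation_rms=0.03, seed=11)


@pytest.fixture(scope="session")
def complex_ensemble(toy, toy_ensembles):
    return SpeciesEnsemble(toy.structure, toy.topology, toy_ensembles["complex"])


@pytest.fixture
def fast_options():
    """MM+SA only (PB disabled), small SASA point set: fast bookkeeping runs."""
    return FreeEnergyOptions(pb=None, sasa_points=120)


@pytest.fixture
def pb_options_coarse():
    return PBOptions(spacing=1.0, padding=6.0, ionic_strength=0.0,
                     n_edge_samples=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
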