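"""Shared fixtures: synthetic ensembles at the scales the tests need."""

import numpy as np
import pytest

from phmem import BilayerSpec, EnsembleSet, ToyDynamicsSpec, generate_ensemble
from phmem.synthetic import make_protein


@pytest.fixture(scope="session")
def small_ensemble() -> EnsembleSet:
    """3 replicates x 300 frames over a 120-lipid PIP2 bilayer; binds fast."""
    bl = BilayerSpec(total_lipids=120)
    dyn = ToyDynamicsSpec(n_replicates=3, n_frames=300,
                          mean_binding_time=60.0, seed=42)
    return generate_ensemble(bl, dyn)


@pytest.fixture(scope="session")
def study_ensemble() -> EnsembleSet:
    """The full study-scale ensemble: 20 replicates x 1000 frames x 1 ns
    over the 356-lipid 75/20/5 PC/PS/PIP2 bilayer."""
    return generate_ensemble(BilayerSpec(), ToyDynamicsSpec(seed=2016))


@pytest.fixture(scope="session")
def protein():
    """Rigid 50-particle template protein (topology, coordinates)."""
    return make_protein(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
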