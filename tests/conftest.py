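import numpy as np
import pytest

from traitlink import ModelParams, Population, initialize_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Small but dynamically stable parameterization for fast tests."""
    return ModelParams(s=0.5, pf=0.6, K=100, L=20, mut_fraction=0.01,
                       generations=5, seed=7)


@pytest.fixture
def tiny_pop(tiny_params, rng):
    return initialize_population(tiny_params, rng)


def random_population(rng, n=50, L=20, pref_density=0.2):
    """A population with random trait alleles and random non-trait states.

    Non-trait loci are wild type with probability 1 - pref_density and
    otherwise uniform over the three mutant states.
    """
    genomes = np.zeros((n, 2, L), dtype=np.uint8)
    genomes[:, :, 0] = rng.integers(0, 2, size=(n, 2))
    mutant = rng.random((n, 2, L - 1)) < pref_density
    states = rng.integers(1, 4, size=(n, 2, L - 1)).astype(np.uint8)
    genomes[:, :, 1:] = np.where(mutant, states, 0)
    sex = rng.integers(0, 2, size=n).astype(np.uint8)
    habitat = rng.integers(0, 2, size=n).astype(np.uint8)
    return Population(genomes=genomes, sex=sex, habitat=habitat, generation=0)
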