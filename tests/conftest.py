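import numpy as np
import pytest

from cocultsim import load_species
from cocultsim.core import PathwayParams, SpeciesModel


@pytest.fixture(scope="session")
def ecoli():
    return load_species("ecoli_k12")


@pytest.fixture(scope="session")
def yeast():
    return load_species("scerevisiae_cenpk")


@pytest.fixture(scope="session")
def monod_mono():
    """Single-pathway glucose consumer in the classical Monod baseline:
    enzymes pinned at 1 and mu_max exactly equal to Yx*q_max, so the
    textbook chemostat/batch closed forms hold exactly."""
    p = PathwayParams(
        id="ferm", substrate="GLU", mu_max=0.4356, Ks=0.112, q_max=2.640, Yx=0.165
    )
    return SpeciesModel("monod_mono", [p], fixed_enzymes=True)


@pytest.fixture(scope="session")
def cybernetic_mono():
    """Same single pathway with live enzyme dynamics."""
    p = PathwayParams(
        id="ferm", substrate="GLU", mu_max=0.4356, Ks=0.112, q_max=2.640, Yx=0.165
    )
    return SpeciesModel("cyber_mono", [p])


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
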