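import numpy as np
import pytest

from omegascreen.codonmodel.fit import fit
from omegascreen.codonmodel.frequencies import CodonFrequencies
from omegascreen.synthgen import CodonSimScenario, simulate_codon_alignment
from omegascreen.trees import star_tree


@pytest.fixture(scope="session")
def equal_pi():
    return CodonFrequencies.equal().pi


@pytest.fixture(scope="session")
def star4():
    return star_tree(["crassa", "discreta", "intermedia", "tetrasperma"], 0.3)


@pytest.fixture(scope="session")
def sim_m0(star4):
    """One alignment simulated under the one-ratio model (omega=0.2)."""
    scen = CodonSimScenario(tree=star4, kappa=2.0, omega_mode=0.2, n_codons=500, seed=11)
    return simulate_codon_alignment(scen)


@pytest.fixture(scope="session")
def m0_fit(sim_m0, star4):
    return fit(sim_m0.alignment, star4, "M0", n_starts=1, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
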