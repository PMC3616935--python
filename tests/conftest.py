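import numpy as np
import pytest

from codonet import universal_code
from codonet.codon_model import uniform_pi
from codonet.io import CodonAlignment
from codonet.simulate import SimulationSpec, mammal9_fixture, simulate_alignment
from codonet.tree import parse_newick


@pytest.fixture(scope="session")
def code():
    return universal_code()


@pytest.fixture(scope="session")
def upi(code):
    return uniform_pi(code)


@pytest.fixture(scope="session")
def mammal_tree():
    return mammal9_fixture()


@pytest.fixture()
def quartet_tree():
    return parse_newick("((A:0.12,B:0.08):0.05,(C:0.2,D:0.15):0.07);")


def random_alignment(rng, code, taxa, n_sites, missing_frac=0.0):
    """Alignment of i.i.d. uniform sense codons (no phylogenetic signal)."""
    codons = rng.integers(0, code.n_states, size=(len(taxa), n_sites)).astype(np.int16)
    if missing_frac:
        mask = rng.random(codons.shape) < missing_frac
        codons[mask] = -1
    return CodonAlignment("random", list(taxa), codons)


@pytest.fixture()
def m0_alignment(mammal_tree):
    """A 300-codon alignment simulated under M0 (omega 0.3, kappa 2)."""
    spec = SimulationSpec(seed=42, n_codons=300, model_params={"omega": 0.3})
    return simulate_alignment(spec)
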