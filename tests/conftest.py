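import numpy as np
import pytest

from coevoscan import PhyloTree, SimSpecCodon, simulate_codon_alignment


@pytest.fixture(scope="session")
def sensu_tree() -> PhyloTree:
    """Default 5-taxon sensu-stricto-shaped tree used across tests."""
    return PhyloTree.five_taxon_default()


@pytest.fixture(scope="session")
def m0_alignment(sensu_tree):
    """A 1,000-codon alignment simulated under the one-ratio model."""
    spec = SimSpecCodon(sensu_tree, "M0", {"kappa": 2.0, "omega": 0.44},
                        n_codons=1000, seed=101)
    aln, truth = simulate_codon_alignment(spec)
    return aln, truth


def random_pi(rng: np.random.Generator) -> np.ndarray:
    pi = rng.dirichlet(np.full(61, 5.0))
    return pi / pi.sum()
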