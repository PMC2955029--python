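import numpy as np
import pytest

from cophylointron.formats_io import MultipleAlignment, SequenceRecord
from cophylointron.phylo_core import PhyloTree, SubstModel
from cophylointron.synthetic_data import simulate_alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def four_taxon_tree():
    return PhyloTree.from_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.05);")


@pytest.fixture
def small_alignment():
    return MultipleAlignment([
        SequenceRecord("a", "ACGTACGTAC"),
        SequenceRecord("b", "ACGTACGAAC"),
        SequenceRecord("c", "ACTTACGTTC"),
        SequenceRecord("d", "GCGTACGTAN"),
    ])


@pytest.fixture
def gtr_gi_model():
    return SubstModel(family="GTR", rates=[1.2, 3.0, 0.8, 1.1, 4.0, 1.0],
                      freqs=[0.3, 0.2, 0.2, 0.3], alpha=0.7, p_inv=0.2)


@pytest.fixture(scope="session")
def five_taxon_sim():
    """1 kb JC alignment simulated on a known 5-taxon tree."""
    tree = PhyloTree.from_newick(
        "((a:0.1,b:0.15):0.08,(c:0.12,d:0.2):0.06,e:0.3);")
    aln = simulate_alignment(tree, SubstModel(family="JC"), 1000, seed=11)
    return tree, aln
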