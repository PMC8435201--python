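import numpy as np
import pytest

from toposcope.alphabets import AMINO_ACID, BINARY
from toposcope.phylo_likelihood import SubstitutionModel
from toposcope.seqio import Alignment, parse_newick


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")


@pytest.fixture
def binary_model():
    return SubstitutionModel.poisson(BINARY)


@pytest.fixture
def lg_model():
    return SubstitutionModel.named("LG", gamma_shape=0.8)


@pytest.fixture
def tiny_aa_alignment():
    rng = np.random.default_rng(7)
    symbols = np.array(list(AMINO_ACID.states))
    data = symbols[rng.integers(0, 20, size=(3, 30))]
    return Alignment(["A", "B", "C"], data, AMINO_ACID)


def make_alignment(rows: dict[str, str], alphabet=AMINO_ACID) -> Alignment:
    return Alignment.from_sequences(list(rows.items()), alphabet)


@pytest.fixture
def make_aln():
    return make_alignment
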