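import pytest

from rnadegree import (
    NucleotideSequence,
    builtin_minimal,
    parse_sequence,
    zero_parameters,
)
from rnadegree.fixtures import TOY_ACGU12, TOY_GGGGCCC, Y_RNA_DOT_BRACKET, Y_RNA_SEQUENCE


@pytest.fixture(scope="session")
def gggg() -> NucleotideSequence:
    return parse_sequence(TOY_GGGGCCC)


@pytest.fixture(scope="session")
def acgu12() -> NucleotideSequence:
    return parse_sequence(TOY_ACGU12)


@pytest.fixture(scope="session")
def yrna() -> NucleotideSequence:
    return parse_sequence(Y_RNA_SEQUENCE)


@pytest.fixture(scope="session")
def yrna_db() -> str:
    return Y_RNA_DOT_BRACKET


@pytest.fixture(scope="session")
def zero_params():
    return zero_parameters()


@pytest.fixture(scope="session")
def minimal_params():
    return builtin_minimal()
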