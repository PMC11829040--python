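import pytest

from hydramass import Fragment, load_registry, tokenize

# Sequences used across the suite.
MALDI_20MER = "UGAGGCAGGAGGUUGAAUAG"          # synthetic Dharmacon oligo
HRMS_20MER = "GUAGUCGUGGCCGAGUGGUU"           # NASE database sequence
TRNA_PHE_ANTICODON = "A[Cm]U[Gm]AA[Y]A[Psi][m5C]UG"  # 2 U + 1 Psi
TRNA_PHE_M1A = "[m1A]UCCACAG"                 # 1 U


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def ecoli_registry():
    return load_registry(organism="ecoli")


def as_fragment(text, registry):
    oligo = tokenize(text, registry)
    return Fragment(oligo, oligo.name, 1, len(oligo))
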