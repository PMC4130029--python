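import pytest

from kmersim import get_alphabet

# The three aligned 23-residue kinase fragments used throughout as a
# worked conservation example (uppercased).
KINASE_FRAGMENTS = [
    "SAANILVGENLVCKVADFGLARL",
    "AARNILVGENYICKVADFGLARL",
    "AARNVLIGEDNVAKICDFGLARV",
]


@pytest.fixture(scope="session")
def kinase_fragments():
    return list(KINASE_FRAGMENTS)


@pytest.fixture(scope="session")
def dna():
    return get_alphabet("identity-dna")


@pytest.fixture(scope="session")
def protein():
    return get_alphabet("identity-protein")


@pytest.fixture(scope="session")
def sev10():
    return get_alphabet("se-v10")
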