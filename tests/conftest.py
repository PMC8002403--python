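import random

import pytest

from pepkit.monomers import CANONICAL_ALPHABET

#: D-tokens usable in round-trip tests (glycine is achiral, so dG cannot
#: survive a SMILES round trip and is excluded from random D sampling)
CHIRAL_D_TOKENS = tuple("d" + c for c in CANONICAL_ALPHABET if c != "G")


def random_sequence(rng: random.Random, length: int,
                    d_fraction: float = 0.0) -> str:
    """A random sequence string, optionally sprinkling bracketed D-tokens."""
    tokens = []
    for _ in range(length):
        if d_fraction and rng.random() < d_fraction:
            tokens.append(f"[{rng.choice(CHIRAL_D_TOKENS)}]")
        else:
            tokens.append(rng.choice(CANONICAL_ALPHABET))
    return "".join(tokens)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory):
    from pepkit.fixtures import make_fixture_complex

    path = tmp_path_factory.mktemp("fixtures") / "helix.pdb"
    return make_fixture_complex("helix", 0, path)


@pytest.fixture(scope="session")
def extended_pdb(tmp_path_factory):
    from pepkit.fixtures import make_fixture_complex

    path = tmp_path_factory.mktemp("fixtures") / "extended.pdb"
    return make_fixture_complex("extended", 0, path)


@pytest.fixture(scope="session")
def two_atom_pdb(tmp_path_factory):
    from pepkit.fixtures import make_fixture_complex

    path = tmp_path_factory.mktemp("fixtures") / "two_atom.pdb"
    return make_fixture_complex("two_atom", 0, path)


@pytest.fixture(scope="session")
def far_apart_pdb(tmp_path_factory):
    from pepkit.fixtures import make_fixture_complex

    path = tmp_path_factory.mktemp("fixtures") / "far_apart.pdb"
    return make_fixture_complex("far_apart", 0, path)
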