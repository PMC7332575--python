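import pytest

from plastosv.rearrange import SignedPermutation
from plastosv.simulate import AncestorConfig, generate_ancestor

# permutations as printed for the IR-lost clade (reference order is 1..13)
LOPHOPYXIS = "1, 2, 3, 4, -6, -5, 7, 8, 9, 10, -13, 11, 12"
DRYPETES = "1, 13, -10, 9, -8, 6, 7, -5, -4, 3, -2, 11, -12"


@pytest.fixture(scope="session")
def lophopyxis_perm() -> SignedPermutation:
    return SignedPermutation.from_text(LOPHOPYXIS)


@pytest.fixture(scope="session")
def drypetes_perm() -> SignedPermutation:
    return SignedPermutation.from_text(DRYPETES)


@pytest.fixture(scope="session")
def default_ancestor():
    """Full-size (150 kb) ancestor with the 112-gene catalog."""
    return generate_ancestor(AncestorConfig(seed=1))


@pytest.fixture(scope="session")
def compact_ancestor():
    """Scaled-down ancestor for simulation-heavy tests."""
    return generate_ancestor(AncestorConfig.compact(seed=1))
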