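import numpy as np
import pytest

from mapfp.io import make_fixture_molecules
from mapfp.minhash import HashSeeds


@pytest.fixture(scope="session")
def seeds1024() -> HashSeeds:
    return HashSeeds.generate(d=1024, seed=42)


@pytest.fixture(scope="session")
def seeds512() -> HashSeeds:
    return HashSeeds.generate(d=512, seed=42)


@pytest.fixture(scope="session")
def fixture_smiles() -> list[tuple[str, str]]:
    """200 deterministic synthetic drug-like molecules."""
    return make_fixture_molecules(n=200, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
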