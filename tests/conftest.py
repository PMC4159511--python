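import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from aformscan import ApeTable, make_test_ape_table


@pytest.fixture(scope="session")
def uniform_table() -> ApeTable:
    """All 64 triplets at -1.0 per strand: every interior position scores -2."""
    return make_test_ape_table("uniform_negative")


@pytest.fixture(scope="session")
def gc_table() -> ApeTable:
    """Central G/C -> negative; APS runs coincide exactly with G/C tracts."""
    return make_test_ape_table("gc_negative")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_817)
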