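import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from grnevol.genome import GenomeSpec, random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_spec():
    return GenomeSpec(n=3, density=0.4)


@pytest.fixture
def small_spec():
    return GenomeSpec(n=30, density=0.1)


@pytest.fixture
def toy_genome(toy_spec, rng):
    return random_genome(toy_spec, rng)
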