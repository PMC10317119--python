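import logging

import numpy as np
import pytest

from plasmidval.io import SequenceRecord
from plasmidval.simulate import SimConfig, make_pool, simulate_pool

logging.getLogger("plasmidval").setLevel(logging.ERROR)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def marker_pool():
    """Four plasmids sharing a backbone, distinct 24-bp markers."""
    return make_pool(4, 2000, 24, seed=101)


@pytest.fixture(scope="session")
def dissimilar_pool():
    """Three fully random, dissimilar circular plasmids."""
    return make_pool(3, 1500, 0, seed=102)


@pytest.fixture(scope="session")
def clean_reads(marker_pool):
    cfg = SimConfig(sub_rate=0, ins_rate=0, del_rate=0, seed=103)
    return simulate_pool(marker_pool, 15, cfg)


@pytest.fixture(scope="session")
def noisy_reads(marker_pool):
    return simulate_pool(marker_pool, 15, SimConfig(seed=104))
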