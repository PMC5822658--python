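from __future__ import annotations

import numpy as np
import pytest

from teratornscan import simulate as sim
from teratornscan.genome import GenomeAssembly

#: compact catalog for tests that only need a small element
SMALL_CATALOG = [
    ("pol", 250),
    ("hel", 200),
    ("mcp", 250),
    ("ORF60", 120),
    ("ORF54", 120),
]


@pytest.fixture(scope="session")
def small_template():
    return sim.build_viral_element(SMALL_CATALOG, "internal", tir_length=13, seed=11)


@pytest.fixture(scope="session")
def full_template():
    return sim.build_viral_element(sim.DEFAULT_CATALOG, "internal", tir_length=13, seed=11)


@pytest.fixture(scope="session")
def small_host():
    return sim.simulate_host_genome(1, 120_000, 0.45, 6, seed=5, gene_length=1200)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_genome(length: int, seed: int, name: str = "contig_1") -> GenomeAssembly:
    r = np.random.default_rng(seed)
    from teratornscan._seq import decode

    return GenomeAssembly({name: decode(r.choice(4, size=length).astype(np.uint8))})
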