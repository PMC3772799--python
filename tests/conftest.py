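import numpy as np
import pytest

import islandrad as ir

# emergence ages (my, end of shield building) used in stratified fixtures;
# the two older islands' ages are required config with no library default
EMERGENCE_AGES = {
    "Kauai": 5.1,
    "Oahu": 3.0,
    "Molokai": 1.9,
    "Maui": 1.3,
    "Hawaii": 0.5,
}


@pytest.fixture
def balanced4():
    return ir.read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def caterpillar3():
    return ir.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule20():
    return ir.simulate_chronogram(ir.TreeSimSpec(lam=0.5, n_tips=20), seed=421)


def random_ranges(chron, areas, rng, *, available_mask=None):
    """Uniform random non-empty ranges for every tip."""
    k = len(areas)
    full = (1 << k) - 1 if available_mask is None else available_mask
    states = [s for s in range(1, 1 << k) if not s & ~full]
    ranges = {}
    for tip in chron.tip_labels:
        mask = states[rng.integers(len(states))]
        ranges[tip] = frozenset(a for i, a in enumerate(areas) if mask >> i & 1)
    return ir.RangeTable(areas=tuple(areas), ranges=ranges)
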