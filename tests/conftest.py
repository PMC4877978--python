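import numpy as np
import pytest

from finebin import FineGrid, GroupedCounts
from finebin.simulate import SCENARIOS, make_replicate


@pytest.fixture
def toy_gc() -> GroupedCounts:
    """Two 5-year intervals with counts 10 and 20."""
    return GroupedCounts([0, 5, 10], [10, 20])


@pytest.fixture
def random_grouped():
    """Factory for random contiguous grouped-count tables."""

    def make(rng: np.random.Generator, max_bins: int = 8) -> GroupedCounts:
        nbins = int(rng.integers(1, max_bins + 1))
        widths = rng.integers(1, 6, size=nbins)
        edges = np.concatenate([[0], np.cumsum(widths)]).astype(float)
        counts = rng.integers(0, 50, size=nbins).astype(float)
        if counts.sum() == 0:
            counts[0] = 1
        return GroupedCounts(edges, counts)

    return make


@pytest.fixture(scope="session")
def scheme_b_replicate():
    """One seeded n=1000 open-ended-scheme replicate plus its fine grid."""
    gc, _ = make_replicate(SCENARIOS[4], rep=0, base_seed=42)
    return gc, FineGrid(0, 130)


@pytest.fixture(scope="session")
def scheme_a_replicate():
    gc, _ = make_replicate(SCENARIOS[2], rep=0, base_seed=42)
    return gc, FineGrid(0, 130)
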