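import numpy as np
import pandas as pd
import pytest

from bulkscan.cross_model import GeneticMap, arabidopsis_like_map
from bulkscan.pool_sim import SnpPanel, random_panel
from bulkscan.snp_filter import SnpTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture(scope="session")
def gmap():
    return arabidopsis_like_map()


@pytest.fixture(scope="session")
def two_chrom_map():
    return GeneticMap.uniform([("1", 100.0, 20_000_000), ("2", 80.0, 16_000_000)])


@pytest.fixture
def small_panel(two_chrom_map, rng):
    return random_panel(two_chrom_map, 500, rng)


def make_table(rows, pool=None, replicate=None):
    """Build a SnpTable from (chrom, pos, count_a, count_b) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "count_a", "count_b"])
    return SnpTable(df, pool=pool, replicate=replicate)


@pytest.fixture
def table_factory():
    return make_table


def random_rows(rng, n, chroms=("1", "2"), max_count=60):
    """Random (chrom, pos, a, b) rows, unique sorted positions per chromosome."""
    rows = []
    for chrom in chroms:
        k = int(rng.integers(1, max(2, n // len(chroms) + 1)))
        pos = np.sort(rng.choice(np.arange(1, 10 * n + 2), size=k, replace=False))
        a = rng.integers(0, max_count, size=k)
        b = rng.integers(0, max_count, size=k)
        rows += [(chrom, int(p), int(x), int(y)) for p, x, y in zip(pos, a, b)]
    return rows
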