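import numpy as np
import pandas as pd
import pytest

from mdnorm import (
    ContactTable,
    SimulationParams,
    default_bias_library,
    join_pair,
    simulate_replicate_pair,
)


def make_table(records, chrom="chr1", resolution=1_000_000):
    """records: iterable of (start1, start2, IF)."""
    df = pd.DataFrame(records, columns=["start1", "start2", "IF"])
    return ContactTable(chrom, resolution, df)


@pytest.fixture
def tiny_pair():
    """Handcrafted 4-record pair at 1 Mb with one partial-zero key."""
    t1 = make_table(
        [(0, 0, 8), (0, 1_000_000, 1), (1_000_000, 2_000_000, 10), (0, 3_000_000, 4)]
    )
    t2 = make_table(
        [(0, 0, 8), (0, 1_000_000, 10), (1_000_000, 2_000_000, 100), (0, 4_000_000, 7)]
    )
    return t1, t2


@pytest.fixture(scope="session")
def sim_null_pair():
    """Unbiased synthetic replicates at the default study scale."""
    params = SimulationParams(n_bins=250, seed=11)
    t1, t2, truth = simulate_replicate_pair(params)
    return t1, t2, truth


@pytest.fixture(scope="session")
def sim_null_joint(sim_null_pair):
    t1, t2, _ = sim_null_pair
    return join_pair(t1, t2)


@pytest.fixture(scope="session")
def sim_biased_pair():
    """Replicates with a smooth monotone distance-dependent bias, n_bins=500."""
    bias = default_bias_library()["linear_in_logD"]()
    params = SimulationParams(n_bins=500, seed=7, bias_fn=bias)
    t1, t2, truth = simulate_replicate_pair(params)
    return t1, t2, truth
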