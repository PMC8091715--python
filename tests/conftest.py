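import numpy as np
import pandas as pd
import pytest

from ecoassembly import (
    OtuTable,
    simulate_metacommunity,
    simulate_neutral_local,
    simulate_tree_with_traits,
)


@pytest.fixture
def small_table():
    """Handmade 4 samples × 5 OTUs table with known structure."""
    counts = pd.DataFrame(
        [
            [5, 5, 0, 1, 10],
            [5, 0, 3, 1, 10],
            [5, 0, 0, 1, 10],
            [5, 0, 0, 1, 10],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["a", "b", "c", "d", "e"],
    )
    return OtuTable(counts)


@pytest.fixture(scope="session")
def neutral_pool():
    """Log-normal metacommunity of 500 OTUs."""
    return simulate_metacommunity(500, 2.0, seed=11)


@pytest.fixture(scope="session")
def neutral_table(neutral_pool):
    """Neutral local communities: m=0.5, 48 samples × 1000 individuals."""
    table, truth = simulate_neutral_local(
        neutral_pool, n_individuals=1000, m=0.5, n_samples=48, seed=12
    )
    return table, truth


@pytest.fixture(scope="session")
def scenario_pool():
    """150-OTU pool with a matching Yule tree and Brownian traits."""
    meta = simulate_metacommunity(150, 2.0, seed=21)
    tree, traits = simulate_tree_with_traits(150, seed=22)
    return meta, tree, traits


def random_otu_table(rng, n_samples=5, n_otus=8, max_count=40):
    counts = rng.integers(0, max_count, size=(n_samples, n_otus))
    # ensure no empty sample
    counts[:, 0] += 1
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"o{j}" for j in range(n_otus)],
        )
    )
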