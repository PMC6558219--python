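import numpy as np
import pandas as pd
import pytest

from cobindsi.simulate import SimConfig, simulate_chip, simulate_expression, simulate_genome


def small_config(**overrides) -> SimConfig:
    """A reduced simulation for fast unit tests (same structure as defaults)."""
    base = dict(
        n_chroms=2,
        chrom_length=150_000,
        n_genes=20,
        mode_fractions={
            "none": 0.2, "GAS": 0.1, "ISRE": 0.1, "NFKB": 0.1, "GAS-ISRE": 0.1,
            "GAS-NFKB": 0.1, "ISRE-NFKB": 0.1, "GAS-ISRE-NFKB": 0.2,
        },
        tag_depth=50_000,
        seed=1,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_small():
    """(config, genome, genes, truth) for a small seeded simulation."""
    config = small_config()
    genome, genes, truth = simulate_genome(config)
    return config, genome, genes, truth


@pytest.fixture(scope="session")
def sim_small_counts(sim_small):
    config, _, _, truth = sim_small
    return simulate_expression(truth, config)


@pytest.fixture(scope="session")
def sim_small_chip(sim_small):
    config, _, _, truth = sim_small
    return simulate_chip(truth, config)


@pytest.fixture()
def tiny_counts():
    """A hand-sized count matrix: 1 cell type, control + one treatment."""
    samples = pd.DataFrame(
        {
            "sample": ["c1", "c2", "t1", "t2"],
            "cell_type": ["VSMC"] * 4,
            "condition": ["control", "control", "LPS", "LPS"],
            "replicate": [1, 2, 1, 2],
        }
    )
    counts = pd.DataFrame(
        {"c1": [10, 100, 4], "c2": [10, 100, 4], "t1": [40, 100, 4], "t2": [40, 100, 4]},
        index=["g1", "g2", "g3"],
    )
    from cobindsi.core import CountMatrix

    return CountMatrix(counts, samples)
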