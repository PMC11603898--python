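"""Shared fixtures: a small synthetic study bundle generated once per session."""

import numpy as np
import pandas as pd
import pytest

from xcimeth.methylome import CpGSiteTable, merge_symmetric_cpgs
from xcimeth.synthetic import SimConfig, generate_genome, simulate_methylomes


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def genome(sim_config):
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def truth(genome):
    return genome[2]


@pytest.fixture(scope="session")
def genes(genome):
    return genome[1]


@pytest.fixture(scope="session")
def sequences(genome):
    return genome[0]


@pytest.fixture(scope="session")
def methylomes(sim_config, truth):
    return simulate_methylomes(sim_config, truth)


@pytest.fixture(scope="session")
def site_table(methylomes):
    return CpGSiteTable.from_sample_frames(
        {s: merge_symmetric_cpgs(df) for s, df in methylomes.items()}
    )


@pytest.fixture(scope="session")
def sex_of(sim_config):
    return sim_config.sex_of()


def random_site_counts(rng, n_sites=50, n_samples=2, max_count=30, chrom="c1"):
    """A small random CpGSiteTable for oracle tests."""
    pos = np.sort(rng.choice(np.arange(10_000), size=n_sites, replace=False))
    frames = {}
    for i in range(n_samples):
        frames[f"s{i}"] = pd.DataFrame(
            {
                "chrom": chrom,
                "pos0": pos,
                "m": rng.integers(0, max_count, n_sites),
                "u": rng.integers(0, max_count, n_sites),
            }
        )
    return CpGSiteTable.from_sample_frames(frames), frames
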