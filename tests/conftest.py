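"""Shared fixtures: tiny hand-built datasets and small simulated experiments."""

import numpy as np
import pandas as pd
import pytest

from riploop.io import CountMatrix, SampleSheet
from riploop.simulate import SimulationConfig, generate_dataset


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """2 genes x 4 samples (one bait, 2 replicates, paired IP/Total)."""
    df = pd.DataFrame(
        {
            "b.rep1.Total": [5, 3],
            "b.rep1.IP": [4, 6],
            "b.rep2.Total": [7, 2],
            "b.rep2.IP": [8, 1],
        },
        index=["g1", "g2"],
    )
    df.index.name = "gene_id"
    return CountMatrix(df)


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    rows = []
    for rep in (1, 2):
        for frac in ("Total", "IP"):
            rows.append(
                {
                    "sample_id": f"b.rep{rep}.{frac}",
                    "protein": "b",
                    "replicate": rep,
                    "fraction": frac,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def small_config(**kwargs) -> SimulationConfig:
    """A fast six-bait configuration used across module tests."""
    defaults = dict(n_genes=400, mean_library_size=1e6, seed=11)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """One small six-bait simulated experiment shared by read-only tests."""
    return generate_dataset(SimulationConfig(n_genes=400, mean_library_size=1e6, seed=11))


def single_bait_config(**kwargs) -> SimulationConfig:
    """Single generic bait, no hub relation; for enrichment calibration tests."""
    defaults = dict(
        n_genes=500,
        proteins=("bait1",),
        hub=None,
        polya_binder=None,
        repressors=(),
        partners=(),
        beta_true=(),
        group_proportions={},
        n_outliers=0,
        mean_library_size=1e6,
        seed=7,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)
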