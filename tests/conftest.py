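"""Shared fixtures: small synthetic panels sized for fast unit tests."""

import numpy as np
import pandas as pd
import pytest

from tracseq.simulate import TESimConfig, TracSimConfig, simulate_trna_reference


@pytest.fixture(scope="session")
def small_trac_config() -> TracSimConfig:
    """20-species panel, half modified: the caller-validation condition."""
    return TracSimConfig(n_trnas=20, modified_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_trac_config):
    return simulate_trna_reference(small_trac_config)


@pytest.fixture(scope="session")
def small_te_config() -> TESimConfig:
    return TESimConfig(n_genes=400, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def brute_force_pileup(alignments: pd.DataFrame, length: int):
    """Per-read loop oracle for depth/start vectors (1-based inclusive)."""
    depth = np.zeros(length, dtype=int)
    starts = np.zeros(length, dtype=int)
    for _, row in alignments.iterrows():
        starts[row["start"] - 1] += 1
        for pos in range(row["start"], row["end"] + 1):
            depth[pos - 1] += 1
    return depth, starts
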