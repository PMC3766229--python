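"""Shared fixtures: a small synthetic dataset with a planted motif."""

from __future__ import annotations

import numpy as np
import pytest

from beemotif.genome_ucr import build_ucr_database
from beemotif.synthetic_data import benchmark_config, simulate_dataset


def make_planted_dataset(seed: int, motif_seed: int = 11, occupancy: float = 0.9):
    """60 genes, 400 bp UCRs, 20 foreground genes carrying a planted 8-mer."""
    cfg = benchmark_config(seed, motif_seed=motif_seed, occupancy=occupancy)
    data = simulate_dataset(cfg)
    records = build_ucr_database(data["annotation"], data["contigs"])
    ucrs = {r.gene_id: r.sequence for r in records}
    data["ucrs"] = ucrs
    data["group"] = {g: ucrs[g] for g in data["truth"].foreground_genes}
    data["config"] = cfg
    return data


@pytest.fixture(scope="session")
def planted_dataset():
    return make_planted_dataset(seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
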