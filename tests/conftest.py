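"""Shared fixtures: small synthetic datasets built once per session."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sigreverse import (
    SimulationConfig,
    differential_expression,
    extract_signature,
    generate_compendium,
    generate_expression,
)
from sigreverse.connectivity import PerturbagenProfile


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale-but-quick study conditions used across unit tests."""
    return SimulationConfig(
        n_genes=2000,
        n_control=20,
        n_disease=20,
        n_up_planted=150,
        n_down_planted=150,
        n_perturbagens=60,
        n_reversers=4,
        n_mimics=4,
        profile_noise=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_expression(small_config):
    return generate_expression(small_config)


@pytest.fixture(scope="session")
def small_dge(small_expression):
    matrix, _ = small_expression
    return differential_expression(matrix)


@pytest.fixture(scope="session")
def small_signature(small_dge):
    return extract_signature(small_dge)


@pytest.fixture(scope="session")
def small_compendium(small_config, small_signature):
    return generate_compendium(small_config, small_signature, n_ref=40)


def profile_from_positions(n: int, tag_genes: list[str], positions) -> PerturbagenProfile:
    """Build an n-gene profile placing ``tag_genes`` at the given 1-based
    ranks and filler genes everywhere else."""
    ranking = np.array([f"F{j:05d}" for j in range(n)], dtype=object)
    for gene, pos in zip(tag_genes, positions):
        ranking[pos - 1] = gene
    return PerturbagenProfile("constructed", ranking)


@pytest.fixture
def null_dge_table():
    """A differential-expression-shaped table with known entries for
    signature tests."""
    rng = np.random.default_rng(5)
    n = 600
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:06d}" for i in range(1, n + 1)],
            "log2fc": rng.normal(0, 1.2, n),
            "tstat": rng.normal(0, 2, n),
            "pvalue": rng.uniform(1e-6, 1, n),
            "adj_pvalue": rng.uniform(1e-4, 1, n),
        }
    )
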