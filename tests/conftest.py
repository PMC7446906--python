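"""Shared fixtures: small self-consistent studies built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from gsreg.datatypes import (
    EqtlWeightSet,
    ExpressionDataset,
    GeneSetCollection,
    GwasSummary,
    LdPanel,
)
from gsreg.scores import standardize_columns
from gsreg.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def consistent_study():
    """A study where beta, Sigma and A = XW all derive from one genotype matrix.

    Under the population (1/N) standardization convention the summary-level
    and individual-level routes to chi-square and gene-gene correlation must
    then agree exactly.
    """
    rng = np.random.default_rng(42)
    n, p, g = 200, 40, 6
    x = standardize_columns(rng.normal(size=(n, p)))
    w = np.zeros((p, g))
    for j in range(g):
        idx = rng.choice(p, size=3, replace=False)
        w[idx, j] = rng.normal(size=3)
    a = x @ w
    y = standardize_columns(a @ rng.normal(size=g) + rng.normal(size=n))
    snp_ids = [f"rs{i}" for i in range(p)]
    gene_ids = [f"G{j}" for j in range(g)]
    sigma = x.T @ x / n
    sigma = (sigma + sigma.T) / 2
    np.fill_diagonal(sigma, 1.0)
    return {
        "x": x,
        "y": y,
        "weights": EqtlWeightSet(snp_ids=snp_ids, gene_ids=gene_ids, weights=w),
        "gwas": GwasSummary(snp_ids=snp_ids, beta=x.T @ y / n, n_gwas=n),
        "ld": LdPanel(snp_ids=snp_ids, sigma=sigma),
        "expression": ExpressionDataset(
            gene_ids=gene_ids,
            sample_ids=[f"s{i}" for i in range(n)],
            values=a.T,
            phenotype=y,
        ),
    }


@pytest.fixture(scope="session")
def mini_config() -> SimulationConfig:
    """Miniature but complete simulation configuration for fast tests."""
    return SimulationConfig(
        n_blocks=3,
        snps_per_block=30,
        n_genes=6,
        n_ref=120,
        n_gwas=300,
        n_sets=5,
        set_size_range=(2, 3),
        causal_set_size=2,
        min_set_size=2,
        h2_gene=0.5,
        n_expression_cohort=80,
    )


@pytest.fixture(scope="session")
def mini_replicate(mini_config):
    """One miniature replicate with both summary and expression outputs."""
    return simulate_study(mini_config, seed=5, mode="both")


@pytest.fixture
def small_sets() -> GeneSetCollection:
    return GeneSetCollection(
        set_ids=["S1", "S2"],
        members={"S1": ["G0", "G1", "G2"], "S2": ["G3", "G4"]},
    )
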