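"""Per-gene chi-square statistics and gene scores.

Two equivalent routes produce the inputs to gene score regression:

* summary level — eQTL weights ``W``, GWAS marginal effects ``beta`` and a
  reference LD panel ``Sigma``: the TWAS statistic is
  ``chi2_j = N * (W_j' beta)^2`` and the gene-gene correlation is
  ``r_jk = W_j' Sigma W_k`` after each weight vector is rescaled so its
  predicted expression has unit variance under ``Sigma``;
* individual level — observed expression ``A`` and phenotype ``y``: by
  definition ``chi2_j = N * ((1/N) A_j'y)^2`` and ``r_jk = (1/N) A_j'A_k`` on
  standardized columns.

When ``beta``, ``Sigma`` and ``A = XW`` all derive from one genotype matrix
the two routes agree exactly; this identity is exercised by the test suite.

All standardization uses the population convention (denominator N).
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    ChiSquareStats,
    EqtlWeightSet,
    ExpressionDataset,
    GeneCorrelationMatrix,
    GeneScoreTable,
    GeneSetCollection,
    GwasSummary,
    LdPanel,
)
from .errors import UsageError, ValidationError

logger = logging.getLogger(__name__)

#: genes whose predicted-expression variance under the LD panel falls below
#: this are dropped (near-singular weight/LD combinations)
VARIANCE_TOL = 1e-8


def standardize_columns(matrix: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Center and scale columns to mean 0 and (1/N)-variance 1.

    Uses the population (1/N) convention so that for standardized columns
    ``(1/N) x'x == 1`` exactly.
    """
    x = np.asarray(matrix, dtype=float)
    one_dim = x.ndim == 1
    if one_dim:
        x = x[:, None]
    mean = x.mean(axis=0)
    centered = x - mean
    scale = np.sqrt((centered**2).mean(axis=0))
    if np.any(scale == 0):
        bad = np.flatnonzero(scale == 0)
        label = names[bad[0]] if names else f"column {bad[0]}"
        raise ValidationError(f"zero-variance column: {label}")
    out = centered / scale
    return out[:, 0] if one_dim else out


def _standardized_expression(data: ExpressionDataset) -> np.ndarray:
    """Return sample x gene standardized expression (transposed from storage)."""
    return standardize_columns(data.values.T, names=data.gene_ids)


def chi2_from_expression(data: ExpressionDataset) -> ChiSquareStats:
    """Marginal association chi-squares from observed expression and phenotype.

    chi2_j = N * alpha_hat_j^2 with alpha_hat_j = (1/N) A_j'y on standardized
    expression and phenotype.
    """
    if data.phenotype is None:
        raise UsageError("expression dataset has no phenotype")
    n = data.n_samples
    a = _standardized_expression(data)
    y = standardize_columns(data.phenotype, names=["phenotype"])
    alpha_hat = a.T @ y / n
    return ChiSquareStats(
        gene_ids=list(data.gene_ids), chi2=n * alpha_hat**2, n_effective=n
    )


def _normalized_weights(
    weights: EqtlWeightSet, ld: LdPanel, ridge: float = 0.0
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Rescale weight columns to unit predicted-expression variance under Sigma.

    Returns (normalized W, kept gene ids, Sigma used).  Genes whose variance
    W_j' Sigma W_j falls below VARIANCE_TOL are dropped with a warning.
    """
    if weights.snp_ids != ld.snp_ids:
        raise ValidationError("weights and LD panel are not SNP-aligned")
    sigma = ld.sigma
    if ridge:
        sigma = (sigma + ridge * np.eye(sigma.shape[0])) / (1.0 + ridge)
    w = weights.weights
    sw = sigma @ w
    var = np.einsum("sg,sg->g", w, sw)
    keep = np.flatnonzero(var > VARIANCE_TOL)
    if len(keep) < len(weights.gene_ids):
        lost = [g for i, g in enumerate(weights.gene_ids) if i not in set(keep)]
        logger.warning(
            "dropped %d gene(s) with non-positive predicted-expression variance: %s",
            len(lost),
            lost[:5],
        )
    if keep.size == 0:
        raise ValidationError("all genes have non-positive predicted-expression variance")
    w_norm = w[:, keep] / np.sqrt(var[keep])
    return w_norm, [weights.gene_ids[i] for i in keep], sigma


def chi2_from_sumstats(
    weights: EqtlWeightSet, gwas: GwasSummary, ld: LdPanel, ridge: float = 0.0
) -> ChiSquareStats:
    """TWAS chi-squares from GWAS marginal effects, eQTL weights and LD.

    chi2_j = N_gwas * (W~_j' beta)^2 where W~_j = W_j / sqrt(W_j' Sigma W_j),
    so the statistic matches the standardized-predictor association that the
    individual-level definition would give.
    """
    if weights.snp_ids != gwas.snp_ids:
        raise ValidationError("weights and sumstats are not SNP-aligned")
    w_norm, gene_ids, _ = _normalized_weights(weights, ld, ridge=ridge)
    alpha_hat = w_norm.T @ gwas.beta
    return ChiSquareStats(
        gene_ids=gene_ids, chi2=gwas.n_gwas * alpha_hat**2, n_effective=gwas.n_gwas
    )


def correlation_from_weights(
    weights: EqtlWeightSet, ld: LdPanel, ridge: float = 0.0
) -> GeneCorrelationMatrix:
    """Gene-gene correlation of genetically predicted expression, W' Sigma W."""
    w_norm, gene_ids, sigma = _normalized_weights(weights, ld, ridge=ridge)
    r = w_norm.T @ (sigma @ w_norm)
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return GeneCorrelationMatrix(gene_ids=gene_ids, r=r)


def correlation_from_expression(data: ExpressionDataset) -> GeneCorrelationMatrix:
    """In-sample gene-gene Pearson correlation, r_jk = (1/N) A_j'A_k."""
    if data.n_samples < 2:
        raise ValidationError("need at least 2 samples for expression correlation")
    sd = data.values.std(axis=1)
    keep = np.flatnonzero(sd > 0)
    gene_ids = [data.gene_ids[i] for i in keep]
    if len(keep) < data.n_genes:
        lost = [g for g in data.gene_ids if g not in set(gene_ids)]
        logger.warning("dropped %d zero-variance gene(s): %s", len(lost), lost[:5])
    a = standardize_columns(data.values[keep].T, names=gene_ids)
    r = a.T @ a / data.n_samples
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return GeneCorrelationMatrix(gene_ids=gene_ids, r=r)


def gene_scores(
    corr: GeneCorrelationMatrix,
    sets: GeneSetCollection,
    bias_n: int | None = None,
) -> GeneScoreTable:
    """Gene scores l(j,c) = sum over set members k of r_jk^2.

    Set members outside the analyzed gene universe contribute nothing; sets
    with no member in the universe are dropped with a warning.

    By default scores use raw squared correlations, letting the regression
    intercept absorb the E[r_hat^2] ~ r^2 + 1/N estimation bias.  Passing the
    correlation sample size as ``bias_n`` instead subtracts |C_c|/N from each
    score explicitly (clipped at zero).
    """
    gene_pos = {g: i for i, g in enumerate(corr.gene_ids)}
    r2 = corr.r**2
    kept_sets: list[str] = []
    cols: list[np.ndarray] = []
    for sid in sets.set_ids:
        idx = [gene_pos[g] for g in sets.members[sid] if g in gene_pos]
        if not idx:
            logger.warning("gene set %s has no genes in the analyzed universe", sid)
            continue
        kept_sets.append(sid)
        col = r2[:, idx].sum(axis=1)
        if bias_n:
            col = np.maximum(col - len(idx) / bias_n, 0.0)
        cols.append(col)
    if not kept_sets:
        raise ValidationError("no gene set overlaps the analyzed gene universe")
    return GeneScoreTable(
        gene_ids=list(corr.gene_ids),
        set_ids=kept_sets,
        scores=np.column_stack(cols),
    )


def dummy_complement(
    sets: GeneSetCollection, target_set: str, universe: list[str]
) -> list[str]:
    """Genes of the analyzed universe outside the target set.

    This is the membership list of the 'dummy' gene set regressed alongside
    each target set; genes shared between the target and any other set are
    still excluded (plain set difference against the target).
    """
    if target_set not in sets.members:
        raise UsageError(f"unknown gene set {target_set!r}")
    target = set(sets.members[target_set])
    return [g for g in universe if g not in target]
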