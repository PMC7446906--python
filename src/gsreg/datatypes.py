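"""Domain containers for gene score regression.

All containers are thin, validated wrappers around numpy arrays plus ordered
identifier lists.  Matrices follow the orientations used throughout the
package: eQTL weights are SNP x gene, LD panels are SNP x SNP, expression is
gene x sample, gene correlation matrices are gene x gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "GwasSummary",
    "EqtlWeightSet",
    "LdPanel",
    "GeneSetCollection",
    "ExpressionDataset",
    "ChiSquareStats",
    "GeneCorrelationMatrix",
    "GeneScoreTable",
    "ENRICHMENT_COLUMNS",
]

#: Column order of an enrichment result table (a pandas DataFrame).
ENRICHMENT_COLUMNS = [
    "set_id",
    "n_genes_in_set",
    "tau_hat",
    "variance_explained",
    "se_tau",
    "t_stat",
    "p_value",
    "p_adjusted",
    "intercept",
    "tau_dummy",
    "status",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class GwasSummary:
    """Per-SNP standardized marginal effect sizes from a GWAS.

    ``beta[p]`` is the marginal effect of the p-th standardized SNP on the
    standardized trait, i.e. beta = (1/N) X'y, together with the GWAS sample
    size ``n_gwas``.
    """

    snp_ids: list[str]
    beta: np.ndarray
    n_gwas: int

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 1 or len(self.beta) != len(self.snp_ids):
            raise ValidationError("beta must be a vector matching snp_ids")
        _check_unique(self.snp_ids, "SNP id")
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("beta contains non-finite values")
        if int(self.n_gwas) < 2:
            raise ValidationError("n_gwas must be >= 2")
        self.n_gwas = int(self.n_gwas)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class EqtlWeightSet:
    """SNP x gene eQTL weight matrix mapping genotype to predicted expression."""

    snp_ids: list[str]
    gene_ids: list[str]
    weights: np.ndarray
    gene_positions: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.gene_ids = list(self.gene_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.snp_ids), len(self.gene_ids)):
            raise ValidationError(
                f"weights shape {self.weights.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.gene_ids)} genes"
            )
        _check_unique(self.snp_ids, "SNP id")
        _check_unique(self.gene_ids, "gene id")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("weights contain non-finite values")
        empty = [g for g, col in zip(self.gene_ids, self.weights.T) if not np.any(col)]
        if empty:
            raise ValidationError(f"genes with all-zero weights: {empty[:5]}")


@dataclass
class LdPanel:
    """Reference SNP-SNP Pearson correlation matrix."""

    snp_ids: list[str]
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.sigma = np.asarray(self.sigma, dtype=float)
        p = len(self.snp_ids)
        if self.sigma.shape != (p, p):
            raise ValidationError("sigma must be square and match snp_ids")
        _check_unique(self.snp_ids, "SNP id")
        if float(np.abs(self.sigma - self.sigma.T).max()) > 1e-8:
            raise ValidationError("sigma is not symmetric")
        if float(np.abs(np.diag(self.sigma) - 1.0).max()) > 1e-8:
            raise ValidationError("sigma diagonal is not 1")
        if float(np.abs(self.sigma).max()) > 1.0 + 1e-8:
            raise ValidationError("sigma has entries outside [-1, 1]")


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT-style)."""

    set_ids: list[str]
    members: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.set_ids = list(self.set_ids)
        _check_unique(self.set_ids, "set id")
        for sid in self.set_ids:
            genes = self.members.get(sid)
            if not genes:
                raise ValidationError(f"gene set {sid!r} is empty")
            _check_unique(genes, f"gene in set {sid!r}")

    def __len__(self) -> int:
        return len(self.set_ids)

    def size(self, set_id: str) -> int:
        return len(self.members[set_id])


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with an optional per-sample phenotype."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    phenotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("values must be gene x sample")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression contains non-finite values")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=float)
            if self.phenotype.shape != (len(self.sample_ids),):
                raise ValidationError("phenotype length must match sample_ids")
            if not np.all(np.isfinite(self.phenotype)):
                raise ValidationError("phenotype contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ChiSquareStats:
    """Per-gene association chi-square statistics, chi2_j = N * alpha_hat_j^2."""

    gene_ids: list[str]
    chi2: np.ndarray
    n_effective: int

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.chi2 = np.asarray(self.chi2, dtype=float)
        if self.chi2.shape != (len(self.gene_ids),):
            raise ValidationError("chi2 must be a vector matching gene_ids")
        _check_unique(self.gene_ids, "gene id")
        if not np.all(np.isfinite(self.chi2)) or np.any(self.chi2 < 0):
            raise ValidationError("chi2 must be finite and non-negative")
        self.n_effective = int(self.n_effective)


@dataclass
class GeneCorrelationMatrix:
    """Gene x gene Pearson correlation of (predicted or observed) expression."""

    gene_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.r = np.asarray(self.r, dtype=float)
        g = len(self.gene_ids)
        if self.r.shape != (g, g):
            raise ValidationError("r must be square and match gene_ids")
        _check_unique(self.gene_ids, "gene id")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValidationError("r is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValidationError("r diagonal is not 1")
        if np.max(np.abs(self.r)) > 1.0 + 1e-12:
            raise ValidationError("r has entries outside [-1, 1]")


@dataclass
class GeneScoreTable:
    """Gene x set table of gene scores l(j, c) = sum_{k in C_c} r_jk^2."""

    gene_ids: list[str]
    set_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.set_ids = list(self.set_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids), len(self.set_ids)):
            raise ValidationError("scores must be gene x set")
        if np.any(self.scores < -1e-12) or not np.all(np.isfinite(self.scores)):
            raise ValidationError("gene scores must be finite and non-negative")
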