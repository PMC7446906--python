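"""Two-stage synthetic study generator.

The generator emulates the benchmark a summary-level transcriptome method
needs: block-structured genotypes, a cis-eQTL expression architecture, noisy
LASSO-estimated weights, and a pathway-driven polygenic phenotype.

Stage 1 (reference cohort): founder genotypes with block-diagonal LD are
block-bootstrapped to ``n_ref`` individuals; each gene receives ``k`` causal
cis-SNPs with weights drawn N(0, h2_gene/k); expression is the genetic value
plus Gaussian noise scaled so genotype explains ``h2_gene`` of expression
variance; per-gene LASSO (5-fold cross-validated penalty) re-estimates the
weights from the reference cohort, as an eQTL study would.

Stage 2 (GWAS cohort): an independent cohort of ``n_gwas`` individuals is
resampled from the same founders; a causal pathway's genes receive trait
effects alpha ~ N(0, sigma2_alpha / G_c); the phenotype is the standardized
causal expression times alpha plus noise scaled so the causal expression
explains ``sigma2_alpha`` of trait variance; marginal SNP effects
beta = (1/N) X'y complete the summary statistics.

Founder haplotypes are synthetic: within each LD block every haplotype is a
switching mosaic of a small pool of ancestral haplotypes, which yields strong
within-block LD and exact between-block independence.  Blocks are separated
by more than two cis-window widths so no cis window crosses a block boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from sklearn.linear_model import LassoCV

from .datatypes import (
    EqtlWeightSet,
    ExpressionDataset,
    GeneSetCollection,
    GwasSummary,
    LdPanel,
)
from .errors import UsageError, ValidationError
from .io import ld_from_genotypes
from .scores import standardize_columns

logger = logging.getLogger(__name__)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults follow the benchmark's standard conditions: 500 reference
    individuals, 50,000 GWAS individuals, 100 LD blocks, one causal cis-SNP
    per gene, expression heritability 0.1, trait variance explained by the
    causal pathway 0.1, one causal pathway, non-causal pathways pruned of
    causal genes and dropped below 5 members.
    """

    n_ref: int = 500
    n_gwas: int = 50_000
    n_blocks: int = 100
    snps_per_block: int = 200
    n_genes: int = 300
    k_causal_snps: int | str = 1  # 1, 2, 3, ... or "all"
    h2_gene: float = 0.1
    sigma2_alpha: float = 0.1  # 0.0 simulates the null (no causal genes)
    cis_window_bp: int = 500_000
    n_sets: int = 100
    set_size_range: tuple[int, int] = (5, 30)
    causal_set_size: int | None = None  # None: drawn from set_size_range
    min_set_size: int = 5
    allow_overlap: bool = False
    n_expression_cohort: int = 1000
    # founder-panel architecture
    n_founders: int = 489
    n_ancestors: int = 8
    snp_spacing_bp: int = 5000
    switch_prob: float = 0.02
    anc_flip_prob: float = 0.25
    mutation_prob: float = 0.005
    maf_floor: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_ref", "n_gwas", "n_blocks", "snps_per_block", "n_genes",
                     "n_sets", "n_founders", "n_ancestors", "cis_window_bp"):
            if getattr(self, name) < 1:
                raise UsageError(f"{name} must be >= 1")
        if not (0.0 < self.h2_gene <= 1.0):
            raise UsageError("h2_gene must lie in (0, 1]")
        if not (0.0 <= self.sigma2_alpha <= 1.0):
            raise UsageError("sigma2_alpha must lie in [0, 1]")
        if self.k_causal_snps != "all" and int(self.k_causal_snps) < 1:
            raise UsageError("k_causal_snps must be >= 1 or 'all'")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise UsageError("set_size_range must satisfy 1 <= lo <= hi <= n_genes")

    @classmethod
    def reduced(cls, **overrides) -> "SimulationConfig":
        """Desk-scale study: 20 blocks, 60 genes, ~50 pathways, N_gwas=5000."""
        base = dict(
            n_blocks=20,
            n_genes=60,
            n_gwas=5000,
            n_sets=50,
            set_size_range=(5, 15),
            causal_set_size=10,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class FounderPanel:
    """Synthetic founder haplotypes with block-diagonal LD."""

    haplotypes: np.ndarray  # (2 * n_founders) x n_snps, uint8
    block_bounds: list[tuple[int, int]]
    snp_positions: np.ndarray
    snp_ids: list[str]
    gene_ids: list[str]
    gene_positions: np.ndarray
    gene_blocks: np.ndarray
    cis_windows: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def genotypes(self) -> np.ndarray:
        """Diploid founder genotypes (n_founders x n_snps, dosage 0/1/2)."""
        return self.haplotypes[0::2] + self.haplotypes[1::2]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class SimulationTruth:
    """Ground truth of one replicate."""

    true_weights: np.ndarray  # n_snps x n_genes
    causal_snps: dict[str, list[str]]
    alpha: np.ndarray  # per gene; nonzero only on causal-set genes
    causal_set_id: str
    sets: GeneSetCollection
    gene_ids: list[str]


@dataclass
class Replicate:
    """One complete synthetic study."""

    index: int
    sets: GeneSetCollection
    truth: SimulationTruth
    gwas: GwasSummary | None = None
    weights: EqtlWeightSet | None = None
    ld: LdPanel | None = None
    expression: ExpressionDataset | None = None


# ---------------------------------------------------------------------------
# founder panel


def _mosaic_block(n_haps: int, n_snps: int, config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Haplotypes for one block as switching mosaics of ancestral haplotypes.

    Ancestral haplotypes are Markov chains along the SNP axis (allele flip
    probability ``anc_flip_prob`` between neighbours), so LD decays smoothly
    with distance instead of dropping to the mosaic-sharing baseline.
    """
    flips = rng.random((config.n_ancestors, n_snps)) < config.anc_flip_prob
    flips[:, 0] = rng.random(config.n_ancestors) < 0.5
    ancestors = np.cumsum(flips, axis=1).astype(np.uint8) % 2
    choice = rng.integers(0, config.n_ancestors, size=(n_haps, n_snps))
    switch = rng.random((n_haps, n_snps)) < config.switch_prob
    switch[:, 0] = True
    # index of the most recent switch point, per haplotype and SNP
    last = np.maximum.accumulate(
        np.where(switch, np.arange(n_snps)[None, :], 0), axis=1
    )
    anc = np.take_along_axis(choice, last, axis=1)
    haps = ancestors[anc, np.arange(n_snps)[None, :]]
    mut = rng.random((n_haps, n_snps)) < config.mutation_prob
    haps = np.where(mut, 1 - haps, haps).astype(np.uint8)
    return haps


def _enforce_maf_floor(haps: np.ndarray, floor: float, rng: np.random.Generator) -> None:
    """Flip random alleles so every SNP's founder MAF reaches the floor."""
    n_haps = haps.shape[0]
    freq = haps.mean(axis=0)
    for s in np.flatnonzero((freq < floor) | (freq > 1.0 - floor)):
        minor = 1 if freq[s] < 0.5 else 0
        need = int(np.ceil(floor * n_haps)) - int((haps[:, s] == minor).sum())
        if need > 0:
            major_rows = np.flatnonzero(haps[:, s] != minor)
            flip = rng.choice(major_rows, size=need, replace=False)
            haps[flip, s] = minor


def make_founders(config: SimulationConfig, seed) -> FounderPanel:
    """Generate the founder panel, SNP map, and gene placement."""
    rng = _rng(seed)
    s_per, spacing = config.snps_per_block, config.snp_spacing_bp
    block_span = (s_per - 1) * spacing
    gap = 2 * config.cis_window_bp + spacing  # cis windows cannot cross blocks
    n_haps = 2 * config.n_founders

    blocks, bounds, positions = [], [], []
    for b in range(config.n_blocks):
        start = b * s_per
        bounds.append((start, start + s_per))
        origin = b * (block_span + gap)
        positions.append(origin + spacing * np.arange(s_per))
        blocks.append(_mosaic_block(n_haps, s_per, config, rng))
    haps = np.concatenate(blocks, axis=1)
    _enforce_maf_floor(haps, config.maf_floor, rng)
    snp_positions = np.concatenate(positions)
    snp_ids = [f"snp{b:03d}_{i:04d}" for b, (lo, hi) in enumerate(bounds) for i in range(hi - lo)]

    # distribute genes across blocks as evenly as possible
    per_block = np.full(config.n_blocks, config.n_genes // config.n_blocks)
    per_block[: config.n_genes % config.n_blocks] += 1
    gene_ids, gene_positions, gene_blocks, cis_windows = [], [], [], {}
    k_int = 2 if config.k_causal_snps == "all" else int(config.k_causal_snps)
    g = 0
    for b, count in enumerate(per_block):
        lo, hi = bounds[b]
        for i in range(count):
            gid = f"gene{g:04d}"
            pos = positions[b][0] + block_span * (i + 1) / (count + 1)
            window = np.flatnonzero(
                np.abs(snp_positions[lo:hi] - pos) <= config.cis_window_bp
            ) + lo
            if len(window) < max(k_int, 2):
                raise UsageError(
                    f"snps_per_block={s_per} too small to host a "
                    f"{config.cis_window_bp} bp cis window"
                )
            gene_ids.append(gid)
            gene_positions.append(pos)
            gene_blocks.append(b)
            cis_windows[gid] = window
            g += 1
    return FounderPanel(
        haplotypes=haps,
        block_bounds=bounds,
        snp_positions=snp_positions,
        snp_ids=snp_ids,
        gene_ids=gene_ids,
        gene_positions=np.array(gene_positions),
        gene_blocks=np.array(gene_blocks),
        cis_windows=cis_windows,
    )


def resample_genotypes(panel: FounderPanel, n: int, seed) -> np.ndarray:
    """Block-bootstrap ``n`` diploid individuals from the founder panel.

    For each individual and each LD block independently, one founder's diploid
    genotype for that block is copied, preserving within-block LD exactly and
    enforcing between-block independence.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    rng = _rng(seed)
    founders = panel.genotypes
    n_founders = founders.shape[0]
    out = np.empty((n, panel.n_snps), dtype=np.uint8)
    picks = rng.integers(0, n_founders, size=(n, len(panel.block_bounds)))
    for b, (lo, hi) in enumerate(panel.block_bounds):
        out[:, lo:hi] = founders[picks[:, b], lo:hi]
    return out


# ---------------------------------------------------------------------------
# stage 1: expression and weights


def draw_true_weights(panel: FounderPanel, config: SimulationConfig, seed
                      ) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Sample causal cis-SNPs and true weights W_g ~ N(0, h2_gene / k)."""
    rng = _rng(seed)
    w = np.zeros((panel.n_snps, len(panel.gene_ids)))
    causal: dict[str, list[str]] = {}
    for g, gid in enumerate(panel.gene_ids):
        window = panel.cis_windows[gid]
        if config.k_causal_snps == "all":
            idx = window
        else:
            idx = rng.choice(window, size=int(config.k_causal_snps), replace=False)
        w[idx, g] = rng.normal(0.0, np.sqrt(config.h2_gene / len(idx)), size=len(idx))
        causal[gid] = [panel.snp_ids[i] for i in np.sort(idx)]
    return w, causal


def _genetic_values(geno_std: np.ndarray, true_weights: np.ndarray,
                    gene_idx: np.ndarray | None = None) -> np.ndarray:
    """X W restricted to the rows where W is nonzero (W is cis-sparse)."""
    w = true_weights if gene_idx is None else true_weights[:, gene_idx]
    rows = np.flatnonzero(np.any(w != 0, axis=1))
    return geno_std[:, rows] @ w[rows, :]


def simulate_expression(
    genotypes_std: np.ndarray,
    true_weights: np.ndarray,
    h2_gene: float,
    seed,
    gene_ids: list[str],
    sample_prefix: str = "ind",
) -> ExpressionDataset:
    """Expression A_g = X W_g + eps with noise matched to the heritability.

    Per gene, sigma2_eps = (1/N) ||X W_g||^2 * (1/h2 - 1), so the genetic
    value explains ``h2_gene`` of expression variance in expectation; at
    h2_gene = 1 the expression equals the genetic value exactly.
    """
    rng = _rng(seed)
    if not np.any(true_weights):
        raise ValidationError("true weights are all zero")
    g_val = _genetic_values(genotypes_std, true_weights)
    n = genotypes_std.shape[0]
    sigma2_eps = (g_val**2).mean(axis=0) * (1.0 / h2_gene - 1.0)
    a = g_val + rng.normal(0.0, 1.0, size=g_val.shape) * np.sqrt(sigma2_eps)
    return ExpressionDataset(
        gene_ids=list(gene_ids),
        sample_ids=[f"{sample_prefix}{i:05d}" for i in range(n)],
        values=a.T,
    )


def estimate_weights_lasso(
    expression_ref: ExpressionDataset,
    genotypes_ref_std: np.ndarray,
    cis_windows: dict[str, np.ndarray],
    snp_ids: list[str],
    seed=0,
    cv_folds: int = 5,
    n_alphas: int = 20,
) -> EqtlWeightSet:
    """Per-gene L1-penalized regression of expression on cis genotypes.

    The penalty is chosen by ``cv_folds``-fold cross-validation on a
    geometric path of ``n_alphas`` candidates (deterministic, unshuffled
    folds).  Genes whose fitted weights are all zero are dropped with a
    warning, as are genes with an empty cis window.
    """
    rng = _rng(seed)
    weights = np.zeros((len(snp_ids), expression_ref.n_genes))
    kept: list[int] = []
    for g, gid in enumerate(expression_ref.gene_ids):
        window = cis_windows.get(gid)
        if window is None or len(window) == 0:
            logger.warning("gene %s: empty cis window; dropped", gid)
            continue
        x = genotypes_ref_std[:, window]
        y = standardize_columns(expression_ref.values[g], names=[gid])
        model = LassoCV(
            cv=cv_folds,
            alphas=n_alphas,
            random_state=int(rng.integers(0, 2**31 - 1)),
            max_iter=3000,
            tol=1e-3,
        ).fit(x, y)
        if not np.any(model.coef_):
            logger.warning("gene %s: all-zero LASSO weights; dropped", gid)
            continue
        weights[window, g] = model.coef_
        kept.append(g)
    if not kept:
        raise ValidationError("LASSO produced no nonzero weight vectors")
    return EqtlWeightSet(
        snp_ids=list(snp_ids),
        gene_ids=[expression_ref.gene_ids[g] for g in kept],
        weights=weights[:, kept],
    )


# ---------------------------------------------------------------------------
# stage 2: pathways and phenotype


def build_pathways(
    universe: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    causal_set_size: int | None,
    allow_overlap: bool,
    min_set_size: int,
    seed,
) -> tuple[GeneSetCollection, str]:
    """Random gene sets with one designated causal pathway.

    When ``allow_overlap`` is false, causal genes are removed from every
    non-causal set, and non-causal sets falling below ``min_set_size`` are
    dropped.
    """
    rng = _rng(seed)
    lo, hi = set_size_range
    if hi > len(universe):
        raise UsageError("set_size_range upper bound exceeds the gene universe")
    if causal_set_size is not None and not (1 <= causal_set_size <= len(universe)):
        raise UsageError("infeasible causal_set_size")
    universe = list(universe)
    causal_idx = int(rng.integers(0, n_sets))
    set_ids, members = [], {}
    causal_id = ""
    causal_genes: set[str] = set()
    for i in range(n_sets):
        sid = f"set{i:04d}"
        if i == causal_idx:
            size = causal_set_size or int(rng.integers(lo, hi + 1))
            genes = list(rng.choice(universe, size=size, replace=False))
            causal_id, causal_genes = sid, set(genes)
        else:
            size = int(rng.integers(lo, hi + 1))
            genes = list(rng.choice(universe, size=size, replace=False))
        set_ids.append(sid)
        members[sid] = genes
    if not allow_overlap:
        pruned_ids = []
        for sid in set_ids:
            if sid == causal_id:
                pruned_ids.append(sid)
                continue
            kept = [g for g in members[sid] if g not in causal_genes]
            if len(kept) < min_set_size:
                continue
            members[sid] = kept
            pruned_ids.append(sid)
        members = {sid: members[sid] for sid in pruned_ids}
        set_ids = pruned_ids
    collection = GeneSetCollection(
        set_ids=set_ids,
        members=members,
        descriptions={sid: ("causal" if sid == causal_id else "non-causal") for sid in set_ids},
    )
    return collection, causal_id


def simulate_phenotype(
    expression_gwas: ExpressionDataset,
    causal_genes: list[str],
    sigma2_alpha: float,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Trait y = A_c alpha + eps with noise matched to sigma2_alpha.

    ``alpha ~ N(0, sigma2_alpha / G_c)`` on the causal genes only;
    sigma2_eps = (1/N) ||A_c alpha||^2 (1/sigma2_alpha - 1), so the causal
    expression explains ``sigma2_alpha`` of trait variance in expectation.
    With sigma2_alpha = 0 the trait is pure noise (null model).

    Returns (phenotype, alpha over causal genes, in their list order).
    """
    rng = _rng(seed)
    n = expression_gwas.n_samples
    if sigma2_alpha == 0.0:
        return rng.normal(0.0, 1.0, size=n), np.zeros(len(causal_genes))
    if not causal_genes:
        raise ValidationError("causal gene set is empty")
    pos = {g: i for i, g in enumerate(expression_gwas.gene_ids)}
    idx = [pos[g] for g in causal_genes]
    a_c = standardize_columns(expression_gwas.values[idx].T, names=causal_genes)
    alpha = rng.normal(0.0, np.sqrt(sigma2_alpha / len(idx)), size=len(idx))
    signal = a_c @ alpha
    sigma2_eps = (signal**2).mean() * (1.0 / sigma2_alpha - 1.0)
    y = signal + rng.normal(0.0, np.sqrt(sigma2_eps), size=n)
    return y, alpha


def compute_sumstats(
    genotypes: np.ndarray, phenotype: np.ndarray, snp_ids: list[str],
    standardize: bool = True,
) -> GwasSummary:
    """Marginal per-SNP effects beta = (1/N) X'y on standardized data."""
    x = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if standardize:
        x = standardize_columns(x, names=snp_ids)
        y = standardize_columns(y, names=["phenotype"])
    n = x.shape[0]
    return GwasSummary(snp_ids=list(snp_ids), beta=x.T @ y / n, n_gwas=n)


# ---------------------------------------------------------------------------
# full studies


def simulate_study(
    config: SimulationConfig,
    seed,
    panel: FounderPanel | None = None,
    mode: str = "sumstats",
    index: int = 0,
) -> Replicate:
    """Generate one complete replicate.

    ``mode`` selects the outputs: ``"sumstats"`` (GWAS summary statistics,
    LASSO weights, LD panel), ``"expression"`` (observed expression +
    phenotype for ``n_expression_cohort`` individuals), or ``"both"``.
    """
    if mode not in ("sumstats", "expression", "both"):
        raise UsageError(f"unknown mode {mode!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(8)
    logger.debug("replicate %d: seed entropy %s", index, ss.entropy)
    if panel is None:
        panel = make_founders(config, _rng(streams[0]))

    true_w, causal_snps = draw_true_weights(panel, config, _rng(streams[1]))
    sets, causal_set_id = build_pathways(
        panel.gene_ids,
        config.n_sets,
        config.set_size_range,
        config.causal_set_size,
        config.allow_overlap,
        config.min_set_size,
        _rng(streams[2]),
    )
    causal_genes = sets.members[causal_set_id]
    alpha_full = np.zeros(len(panel.gene_ids))
    gene_pos = {g: i for i, g in enumerate(panel.gene_ids)}

    rep = Replicate(index=index, sets=sets, truth=None)  # truth filled below

    if mode in ("sumstats", "both"):
        rng_ref = _rng(streams[3])
        x_ref = resample_genotypes(panel, config.n_ref, rng_ref)
        x_ref_std = standardize_columns(x_ref, names=panel.snp_ids)
        expr_ref = simulate_expression(
            x_ref_std, true_w, config.h2_gene, rng_ref, panel.gene_ids, "ref"
        )
        rep.weights = estimate_weights_lasso(
            expr_ref, x_ref_std, panel.cis_windows, panel.snp_ids, seed=rng_ref
        )
        rep.ld = ld_from_genotypes(x_ref_std, panel.snp_ids)

        rng_gwas = _rng(streams[4])
        x_gwas = resample_genotypes(panel, config.n_gwas, rng_gwas)
        x_gwas_std = standardize_columns(x_gwas, names=panel.snp_ids)
        del x_gwas
        causal_idx = np.array([gene_pos[g] for g in causal_genes])
        expr_causal = simulate_expression(
            x_gwas_std, true_w[:, causal_idx], config.h2_gene, rng_gwas,
            causal_genes, "gwas",
        ) if config.sigma2_alpha > 0 else ExpressionDataset(
            gene_ids=list(causal_genes),
            sample_ids=[f"gwas{i:05d}" for i in range(config.n_gwas)],
            values=np.zeros((len(causal_genes), config.n_gwas)),
        )
        y, alpha = simulate_phenotype(
            expr_causal, causal_genes, config.sigma2_alpha, rng_gwas
        )
        rep.gwas = compute_sumstats(x_gwas_std, y, panel.snp_ids)
        alpha_full[causal_idx] = alpha

    if mode in ("expression", "both"):
        rng_expr = _rng(streams[5])
        x_e = resample_genotypes(panel, config.n_expression_cohort, rng_expr)
        x_e_std = standardize_columns(x_e, names=panel.snp_ids)
        expr = simulate_expression(
            x_e_std, true_w, config.h2_gene, rng_expr, panel.gene_ids, "expr"
        )
        y_e, alpha_e = simulate_phenotype(
            expr, causal_genes, config.sigma2_alpha, rng_expr
        )
        expr.phenotype = np.asarray(y_e, dtype=float)
        rep.expression = expr
        if mode == "expression":
            alpha_full[[gene_pos[g] for g in causal_genes]] = alpha_e

    rep.truth = SimulationTruth(
        true_weights=true_w,
        causal_snps=causal_snps,
        alpha=alpha_full,
        causal_set_id=causal_set_id,
        sets=sets,
        gene_ids=list(panel.gene_ids),
    )
    return rep


def run_replicates(
    config: SimulationConfig,
    n_replicates: int,
    seed,
    mode: str = "sumstats",
    panel: FounderPanel | None = None,
) -> Iterator[Replicate]:
    """Yield independently seeded replicates sharing one founder panel.

    The founder panel plays the role of a fixed external reference cohort and
    is generated once from the master seed; every replicate then redraws
    genotype resampling, eQTL architecture, pathways and phenotype.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    panel_seed, *rep_seeds = ss.spawn(n_replicates + 1)
    if panel is None:
        panel = make_founders(config, _rng(panel_seed))
    for i, child in enumerate(rep_seeds):
        yield simulate_study(config, child, panel=panel, mode=mode, index=i)
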