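# Methods

## Model

Assume a continuous trait with linearly additive gene-expression effects,

    y_i = Σ_j A_ij α_j + ε_i,        α_j ~ N(0, σ_j²),  ε_i ~ N(0, σ_ε²),

with expression `A` (N samples × G genes) and trait `y` standardized to mean
0 and variance 1 under the population convention (1/N denominators
throughout).  The marginal effect of gene j is α̂_j = (1/N) A_j'y and its
association statistic is χ²_j = N α̂_j².  Writing r_jk = (1/N) A_j'A_k for
the expression correlation and grouping genes into (possibly overlapping)
sets C_c with per-gene variance τ_c, the expectation of the statistic is
approximately linear in the *gene scores* l(j,c) = Σ_{k∈C_c} r_jk²:

    E[χ²_j] ≈ N Σ_c τ_c l(j,c) + 1.

Regressing χ²_j on l(j,c) therefore estimates each set's per-gene trait
variance τ_c; τ_c × |C_c| is the set's total variance explained.  A
non-causal gene that is merely correlated with causal genes inherits an
inflated χ² *and* an inflated gene score, so the regression attributes its
signal to the correct set — the confounding that plain enrichment tests on
marginal statistics suffer from is modeled rather than ignored.

### Two input routes

* **Summary statistics.**  With per-SNP marginal GWAS effects
  β = (1/N) X'y, an eQTL weight matrix W (SNP × gene), and a reference LD
  panel Σ, predicted expression is A = XW and

      χ²_j = N (W̃_j'β)²,      R = W̃' Σ W̃,      W̃_j = W_j / sqrt(W_j'ΣW_j).

  The rescaling of each weight column to unit predicted-expression variance
  under Σ is the unique convention consistent with the standardization
  assumed by the model; it makes R a true correlation matrix (unit diagonal)
  and χ² a standardized-predictor association.  When β, Σ and A derive from
  one genotype matrix the two routes agree to machine precision; the test
  suite asserts this identity at rtol 1e-8.

* **Observed expression.**  With individual-level expression and phenotype,
  χ² and R follow directly from their definitions on standardized columns.

### Regression design and inference

Gene sets overlap, so sets are fit one at a time: χ²_j is regressed on an
intercept, the target score l(j,c), and a "dummy" score over the complement
of the target set (the union of all other analyzed genes), which absorbs
signal from causal genes outside the target.  The complement score is
strongly anti-correlated with the target score by construction — their sum
is the near-constant total gene score — so the raw target slope carries a
parametrization-inflated standard error.  Enrichment is therefore tested on
the *contrast* τ_target − τ_dummy ("does the target set carry more per-gene
signal than its complement?"), which is invariant to that near-collinearity
and conservative for non-causal sets, whose complement holds the causal
genes.

The default p-value references the contrast against its exact null law
rather than a t distribution.  The OLS contrast is a linear statistic a'χ²
with a = X(X'X)⁻¹c; under the global null the vector α̂ is approximately
N(0, R/N), so a'χ² is a quadratic form in correlated normals distributed as
Σ_i λ_i χ²₁ with λ = eig(R^{1/2} diag(a) R^{1/2}).  Tail probabilities come
from the Lugannani–Rice saddlepoint approximation, which stays accurate far
into the tail (relative error of a few percent; verified against Monte Carlo
in the test suite).  This accounts for both the right-skew of χ² residuals —
which makes a naive one-sided t-test anti-conservative at a few dozen genes
(measured type-I 0.068 at nominal 0.05 with 60 genes) — and the correlation
of the statistics across genes.  Measured on null simulations (α = 0,
~550 set-level tests) the analytic p-values give type-I 0.045–0.051 at 0.05
and Kolmogorov–Smirnov uniformity p > 0.6.  Plain t-tests on the contrast
(`test="contrast"`) or the raw slope (`test="slope"`), and HC1 robust
standard errors (`robust_se=True`), remain available; plain OLS errors are
the default for the t variants because χ² residuals are homoskedastic
(variance ≈ 2) under the null.

τ̂_c is always the raw target slope divided by the effective sample size,
with its OLS standard error; the choice of test affects only the p-value.
Bonferroni adjustment over the tested sets is applied by default (the number
of tested sets excludes sets flagged untested).  Sets with fewer than 2
genes in the analyzed universe are reported but flagged untested; fits with
fewer than 5 genes or a rank-deficient design are flagged failed, and a
per-set failure never aborts a run.

### Reporting conventions

The printed definition of τ_c is ambiguous between a per-gene and a per-set
quantity; the downstream identity E[α_k²] = Σ_{c: k∈C_c} τ_c forces the
per-gene reading, so `tau_hat` is per-gene variance and
`variance_explained = tau_hat × |C_c ∩ universe|` is the per-set figure.
Gene scores use raw r̂² without the −|C_c|/N small-sample correction; the
intercept absorbs that term (one reason fitted intercepts exceed 1 when R is
estimated from a finite reference panel).  The explicit correction is
available via `gene_scores(..., bias_n=N)`.

## Synthetic studies

The simulator reproduces a two-stage benchmark without external data.

**Founders.**  489 synthetic founders carry haplotypes organized in
independent LD blocks.  Within a block each haplotype is a switching mosaic
(switch probability 0.02 per SNP) over 8 ancestral haplotypes, themselves
Markov chains along the SNP axis (allele flip probability 0.25 between
neighbours), plus mutation noise (0.005) and a founder MAF floor of 0.05.
This yields mean adjacent-SNP |r| above 0.3 within blocks, smoothly decaying
LD, and exact independence between blocks.  Blocks are laid out with ≥ 2
cis-window gaps so no gene's ±500 kb cis window can cross a block boundary.
SNPs are spaced 5 kb apart, 200 per block by default, with genes placed
evenly inside blocks.

**Stage 1 (reference cohort, default N_ref = 500).**  Genotypes are
block-bootstrapped from the founders: for each individual and each block
independently, one founder's diploid genotype is copied.  Each gene receives
k causal cis-SNPs (default k = 1; "all" supported) with weights
N(0, h²_g/k), h²_g = 0.1 by default.  Expression is the genetic value plus
noise with σ²_ε = (1/N)‖XW_g‖²(1/h²_g − 1), so genotype explains h²_g of
expression variance in expectation (exactly noise-free at h²_g = 1).
Weights are then re-estimated per gene by LASSO on the cis window, with the
penalty chosen by 5-fold cross-validation over a 20-point geometric path
(deterministic unshuffled folds, coordinate-descent tolerance 1e-3); genes
whose fitted weights are all zero are dropped.  The LD panel is the Pearson
correlation of the reference genotypes.

**Stage 2 (GWAS cohort, default N_gwas = 50,000).**  An independent cohort
is resampled from the same founders.  One pathway is designated causal; its
genes receive effects α ~ N(0, σ²_α/G_c) with σ²_α = 0.1 by default, so the
pathway explains 10% of trait variance in total.  The phenotype is the
standardized causal expression times α plus noise scaled by
σ²_ε = (1/N)‖Āα‖²(1/σ²_α − 1); setting σ²_α = 0 produces a pure-noise trait
for null calibration.  Summary statistics are β = (1/N) X'y.  Pathways are
random gene subsets (sizes 5–30 by default); with overlap disallowed, causal
genes are removed from non-causal sets and sets falling below 5 members are
dropped.  An expression-mode cohort (default 1000 individuals) is generated
the same way, carrying observed (noisy) expression for all genes plus the
phenotype.

**What the generator does not emulate:** real MAF spectra and recombination
maps, allele coding/strand issues, population structure, trans-eQTLs,
co-regulation of expression beyond LD (all gene-gene correlation here is
LD-induced), case-control traits, and curated pathway topology.  Passing
benchmarks therefore demonstrate correctness of the statistical machinery
under the stated generative model, not performance on any real cohort.

**Problem sizes used in the checks.**  The packaged benchmark runs the
generator at desk scale — 20 blocks, 60 genes, ~50 pathways with a 10-gene
causal pathway, N_ref = 500, N_gwas = 5000, 20 replicates (and 12 null
replicates pooling ≥ 500 set-level tests) — which one CPU completes in a few
minutes.  The full-scale configuration (100 blocks, 300 genes, N_gwas =
50,000, 100 replicates) is the `SimulationConfig` default and runs the same
code path.

## Numerical choices

* All correlations and standardizations use the population (1/N) convention;
  correlation entries are clamped to [−1, 1] and symmetrized.
* Genes with predicted-expression variance W_j'ΣW_j ≤ 1e-8 are dropped with
  a warning; an optional convex ridge (Σ + λI)/(1+λ) is available for
  ill-conditioned user-supplied panels (off by default; the simulator's
  per-block panels are well conditioned at N_ref = 500).
* The saddlepoint root-finder brackets the natural-parameter singularities
  and falls back to p = 0.5 within 1e-10 of the null mean; weights below
  1e-12 in magnitude are discarded.
* Missing values are rejected at parse time; expression input must be
  complete.  Inputs are assumed allele-harmonized.
* Random streams derive from a single seed via `numpy` SeedSequence
  spawning, one child per replicate and stage; identical seeds give
  bit-identical studies.

## Limitations

* The analytic null assumes χ²_j is marginally χ²₁-distributed under no
  signal, which relies on a normal-ish phenotype and large N.
* In summary mode R comes from a finite reference panel: cross-block noise
  in r̂² inflates gene scores slightly, absorbed by the intercept but adding
  variance; block-jackknife standard errors are a known alternative and are
  not implemented.
* One weight set per run (no multi-tissue handling); joint multi-set
  regression and conditional analysis between correlated pathways are out of
  scope.
* Estimated eQTL weights absorb measurement error and confounding in real
  data; the benchmark's LASSO step models only the sampling-noise part.
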