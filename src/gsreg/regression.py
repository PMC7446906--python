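"""Gene score regression: per-set variance coefficients and enrichment tests.

For each gene set C_c the model E[chi2_j] = N * tau_c * l(j,c) + ... is fit by
ordinary least squares of the per-gene chi-square statistic on the target
set's gene score, a 'dummy' score over the complement of the target set, and
an intercept.  The dummy feature absorbs signal from causal genes outside the
target set; the intercept absorbs the "+1" null expectation and residual
biases.  The target slope divided by the effective sample size estimates
tau_c, the per-gene trait variance contributed by the set.

Enrichment is tested one-sidedly on the contrast tau_target - tau_dummy (is
the per-gene signal inside the set larger than in its complement?): the
complement score is strongly anti-correlated with the target score by
construction (their sum is the near-constant total gene score), so the raw
target slope has a parametrization-inflated standard error, while the
contrast is invariant to that near-collinearity and conservative for
non-causal sets whose complement holds the causal genes.

The default p-value references the contrast against its exact null law
rather than a t distribution: the OLS contrast is a linear statistic a'chi2,
and under the no-signal null alpha_hat ~ N(0, R/N), making a'chi2 a quadratic
form in correlated normals whose distribution is a weighted sum of 1-df
chi-squares with weights eig(R^{1/2} diag(a) R^{1/2}).  Tail probabilities
come from the Lugannani-Rice saddlepoint approximation, which stays accurate
far into the tail.  This accounts for both the skewness of chi-square
residuals (which makes a naive t-test anti-conservative at a few dozen
genes) and the gene-gene correlation of the statistics.  ``test="contrast"``
and ``test="slope"`` select plain t-tests on the contrast or the raw slope;
standard errors are plain OLS by default with HC1 behind ``robust_se=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import (
    ENRICHMENT_COLUMNS,
    ChiSquareStats,
    GeneCorrelationMatrix,
    GeneScoreTable,
    GeneSetCollection,
)
from .errors import UsageError, ValidationError
from .scores import gene_scores

logger = logging.getLogger(__name__)

#: fewest genes for which a regression is attempted
MIN_GENES_FIT = 5
#: sets with fewer genes in the universe are reported but flagged untested
MIN_SET_SIZE_TESTED = 2


@dataclass
class RegressionFit:
    """Result of one gene-set regression."""

    set_id: str
    tau_hat: float
    tau_dummy: float
    intercept: float
    se_tau: float
    t_stat: float
    p_value: float
    n_genes_used: int
    status: str = "ok"  # ok | failed:<reason> | untested:<reason>

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _saddlepoint_sf(lambdas: np.ndarray, s: float) -> float:
    """P(sum_i lambda_i Z_i^2 >= s) by the Lugannani-Rice saddlepoint formula.

    ``lambdas`` may have mixed signs.  Accurate far into the tail, unlike
    moment-matched approximations.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[np.abs(lam) > 1e-12]
    if lam.size == 0:
        return 0.5
    # centre/scale guard: near the mean the saddlepoint degenerates to 0.5
    sd = np.sqrt(2.0 * np.sum(lam**2))
    if abs(s) < 1e-10 * max(sd, 1.0):
        return 0.5
    lo = 0.5 / lam.min() if np.any(lam < 0) else -np.inf
    hi = 0.5 / lam.max() if np.any(lam > 0) else np.inf

    def kprime(t):
        return np.sum(lam / (1.0 - 2.0 * t * lam))

    eps = 1e-12
    a = max(lo * (1 - 1e-9), lo + eps) if np.isfinite(lo) else -1e6
    b = min(hi * (1 - 1e-9), hi - eps) if np.isfinite(hi) else 1e6
    # shrink towards the singularities until K'(a) < s < K'(b)
    while kprime(b) < s:
        b = b + 0.9 * (hi - b) if np.isfinite(hi) else b * 2
    while kprime(a) > s:
        a = a + 0.9 * (lo - a) if np.isfinite(lo) else a * 2
    from scipy.optimize import brentq

    t_hat = brentq(lambda t: kprime(t) - s, a, b, xtol=1e-14)
    arg = 1.0 - 2.0 * t_hat * lam
    cgf = -0.5 * np.sum(np.log(arg))
    k2 = 2.0 * np.sum(lam**2 / arg**2)
    w = np.sign(t_hat) * np.sqrt(max(2.0 * (t_hat * s - cgf), 0.0))
    u = t_hat * np.sqrt(k2)
    if abs(w) < 1e-8 or abs(u) < 1e-8:
        return 0.5
    p = stats.norm.sf(w) - stats.norm.pdf(w) * (1.0 / w - 1.0 / u)
    return float(min(max(p, 0.0), 1.0))


def _failed(set_id: str, reason: str, n: int, kind: str = "failed") -> RegressionFit:
    return RegressionFit(
        set_id=set_id,
        tau_hat=np.nan,
        tau_dummy=np.nan,
        intercept=np.nan,
        se_tau=np.nan,
        t_stat=np.nan,
        p_value=np.nan,
        n_genes_used=n,
        status=f"{kind}:{reason}",
    )


def fit_gene_set(
    chi2: ChiSquareStats,
    scores: GeneScoreTable,
    target: str,
    dummy_scores: np.ndarray | None = None,
    robust_se: bool = False,
    test: str = "analytic",
    null_cov_sqrt: np.ndarray | None = None,
) -> RegressionFit:
    """OLS of chi2_j on [intercept, l(j,target), l(j,dummy)].

    The dummy column is dropped when absent, identically zero, or collinear
    with the other columns.  ``tau_hat`` is the target slope divided by the
    effective sample size.  The one-sided p-value tests the enrichment
    contrast (target slope minus dummy slope; without a dummy column, the raw
    slope) against the weighted-chi-square analytic null by default
    (``null_cov_sqrt`` must then carry a symmetric square root of the
    gene-gene correlation matrix), or by plain t-tests with
    ``test="contrast"`` / ``test="slope"``.
    """
    if chi2.gene_ids != scores.gene_ids:
        raise ValidationError("chi2 and scores are not gene-aligned")
    if target not in scores.set_ids:
        raise UsageError(f"unknown gene set {target!r}")
    if test not in ("analytic", "contrast", "slope"):
        raise UsageError(f"unknown test {test!r}")
    if test == "analytic" and null_cov_sqrt is None:
        raise UsageError("test='analytic' requires null_cov_sqrt")
    y = chi2.chi2
    n = len(y)
    x_t = scores.scores[:, scores.set_ids.index(target)]
    columns = [np.ones(n), x_t]
    has_dummy = dummy_scores is not None and np.any(np.asarray(dummy_scores) != 0)
    if has_dummy:
        columns.append(np.asarray(dummy_scores, dtype=float))
    design = np.column_stack(columns)
    if n < max(MIN_GENES_FIT, design.shape[1] + 3):
        logger.warning("set %s: only %d genes; skipping fit", target, n)
        return _failed(target, "too-few-genes", n)
    # drop a collinear dummy before declaring the fit unusable
    if has_dummy and np.linalg.matrix_rank(design) < design.shape[1]:
        design = design[:, :2]
        has_dummy = False
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return _failed(target, "rank-deficient-design", n)
    model = sm.OLS(y, design)
    res = model.fit(cov_type="HC1", use_t=True) if robust_se else model.fit()
    slope = res.params[1]
    if test == "slope" or not has_dummy:
        contrast = np.zeros(design.shape[1])
        contrast[1] = 1.0
    else:
        contrast = np.array([0.0, 1.0, -1.0])
    estimate = float(contrast @ res.params)
    if test == "analytic":
        # contrast is the linear statistic a'chi2; under the global null its
        # law is sum_i lambda_i chi2_1 with lambda = eig(R^1/2 diag(a) R^1/2)
        a_vec = design @ np.linalg.solve(design.T @ design, contrast)
        b_mat = (null_cov_sqrt * a_vec) @ null_cov_sqrt
        lambdas = np.linalg.eigvalsh((b_mat + b_mat.T) / 2.0)
        p_value = _saddlepoint_sf(lambdas, estimate)
        var0 = 2.0 * np.sum(lambdas**2)
        t_stat = estimate / np.sqrt(var0) if var0 > 0 else 0.0
    else:
        se = float(np.sqrt(contrast @ res.cov_params() @ contrast))
        scale = max(1.0, float(np.mean(y)))
        if not np.isfinite(se) or se <= 0:
            # degenerate (e.g. exactly fit or constant) response
            if abs(estimate) <= 1e-10 * scale:
                t_stat, p_value = 0.0, 0.5
            else:
                t_stat = np.inf if estimate > 0 else -np.inf
                p_value = 0.0 if estimate > 0 else 1.0
        else:
            t_stat = estimate / se
            p_value = float(stats.t.sf(t_stat, res.df_resid))
    return RegressionFit(
        set_id=target,
        tau_hat=slope / chi2.n_effective,
        tau_dummy=(res.params[2] / chi2.n_effective) if has_dummy else 0.0,
        intercept=res.params[0],
        se_tau=float(res.bse[1]) / chi2.n_effective,
        t_stat=t_stat,
        p_value=p_value,
        n_genes_used=n,
    )


def adjust_pvalues(p_values, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment; NaNs (untested sets) pass through."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method != "bonferroni":
        raise UsageError(f"unsupported adjustment method {method!r}")
    m = int(finite.sum())
    out = p.copy()
    out[finite] = np.minimum(1.0, p[finite] * m)
    return out


def run_gsr(
    chi2: ChiSquareStats,
    corr: GeneCorrelationMatrix,
    sets: GeneSetCollection,
    robust_se: bool = False,
    test: str = "analytic",
    adjust_method: str = "bonferroni",
    min_set_size_tested: int = MIN_SET_SIZE_TESTED,
) -> pd.DataFrame:
    """Fit every gene set (one at a time, with its dummy complement).

    Returns an enrichment table (one row per set, in input set order) with
    per-gene ``tau_hat``, per-set ``variance_explained = tau_hat * set size``,
    standard errors, one-sided enrichment p-values and Bonferroni-adjusted
    p-values.  Per-set failures become flagged rows; the run never aborts.
    """
    if chi2.gene_ids != corr.gene_ids:
        raise ValidationError("chi2 and correlation matrix are not gene-aligned")
    table = gene_scores(corr, sets)
    universe = set(corr.gene_ids)
    # l(j, dummy) = total row sum - l(j, target): the complement of the target
    total = (corr.r**2).sum(axis=1)
    null_cov_sqrt = None
    if test == "analytic":
        evals, evecs = np.linalg.eigh(corr.r)
        null_cov_sqrt = (evecs * np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    rows: list[RegressionFit] = []
    sizes: dict[str, int] = {}
    for sid in sets.set_ids:
        n_in = sum(1 for g in sets.members[sid] if g in universe)
        sizes[sid] = n_in
        if sid not in table.set_ids:
            rows.append(_failed(sid, "no-genes-in-universe", 0, kind="untested"))
            continue
        if n_in < min_set_size_tested:
            rows.append(
                _failed(sid, f"fewer-than-{min_set_size_tested}-genes", n_in, kind="untested")
            )
            continue
        l_target = table.scores[:, table.set_ids.index(sid)]
        l_dummy = np.maximum(total - l_target, 0.0)
        rows.append(
            fit_gene_set(
                chi2,
                table,
                sid,
                dummy_scores=l_dummy,
                robust_se=robust_se,
                test=test,
                null_cov_sqrt=null_cov_sqrt,
            )
        )
    p_adj = adjust_pvalues([f.p_value for f in rows], method=adjust_method)
    out = pd.DataFrame(
        {
            "set_id": [f.set_id for f in rows],
            "n_genes_in_set": [sizes[f.set_id] for f in rows],
            "tau_hat": [f.tau_hat for f in rows],
            "variance_explained": [f.tau_hat * sizes[f.set_id] for f in rows],
            "se_tau": [f.se_tau for f in rows],
            "t_stat": [f.t_stat for f in rows],
            "p_value": [f.p_value for f in rows],
            "p_adjusted": p_adj,
            "intercept": [f.intercept for f in rows],
            "tau_dummy": [f.tau_dummy for f in rows],
            "status": [f.status for f in rows],
        },
        columns=ENRICHMENT_COLUMNS,
    )
    return out
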