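"""End-to-end analysis pipelines shared by the CLI, the test suite and the
reproduction script."""

from __future__ import annotations

import pandas as pd

from .datatypes import (
    EqtlWeightSet,
    ExpressionDataset,
    GeneSetCollection,
    GwasSummary,
    LdPanel,
)
from .io import align_summary_inputs
from .regression import run_gsr
from .scores import (
    chi2_from_expression,
    chi2_from_sumstats,
    correlation_from_expression,
    correlation_from_weights,
)


def enrichment_from_summary(
    weights: EqtlWeightSet,
    gwas: GwasSummary,
    ld: LdPanel,
    sets: GeneSetCollection,
    ridge: float = 0.0,
    robust_se: bool = False,
    test: str = "analytic",
) -> pd.DataFrame:
    """Summary-statistics mode: align SNPs, build chi2 and R, regress."""
    w, g, l = align_summary_inputs(weights, gwas, ld)
    chi2 = chi2_from_sumstats(w, g, l, ridge=ridge)
    corr = correlation_from_weights(w, l, ridge=ridge)
    return run_gsr(chi2, corr, sets, robust_se=robust_se, test=test)


def enrichment_from_expression(
    data: ExpressionDataset,
    sets: GeneSetCollection,
    robust_se: bool = False,
    test: str = "analytic",
) -> pd.DataFrame:
    """Observed-expression mode: in-sample chi2 and R, then regress."""
    chi2 = chi2_from_expression(data)
    corr = correlation_from_expression(data)
    if chi2.gene_ids != corr.gene_ids:
        keep = [g for g in chi2.gene_ids if g in set(corr.gene_ids)]
        idx = [chi2.gene_ids.index(g) for g in keep]
        from .datatypes import ChiSquareStats

        chi2 = ChiSquareStats(
            gene_ids=keep, chi2=chi2.chi2[idx], n_effective=chi2.n_effective
        )
    return run_gsr(chi2, corr, sets, robust_se=robust_se, test=test)
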