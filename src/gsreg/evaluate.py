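"""Scoring enrichment output against simulation truth.

Pathway p-values from many replicates are pooled into a single ranking by
-log10(p) with causal pathways as positives; precision-recall and its area
(average precision) summarize discrimination.  Top-1 recovery counts
replicates where the causal pathway is strictly the most significant, and
power/type-I rates are reported at fixed p-value thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve

from .errors import UsageError, ValidationError

__all__ = [
    "EvaluationSummary",
    "precision_recall",
    "top1_recovery",
    "power_at",
    "evaluate_replicates",
]


@dataclass
class EvaluationSummary:
    auprc: float
    top1_count: int
    n_replicates: int
    power_at_threshold: pd.DataFrame

    def __post_init__(self) -> None:
        if not (0.0 <= self.auprc <= 1.0):
            raise ValidationError("auprc must lie in [0, 1]")
        if not (0 <= self.top1_count <= self.n_replicates):
            raise ValidationError("top1_count must lie in [0, n_replicates]")


def precision_recall(labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled precision-recall curve and average-precision AUPRC.

    ``labels`` are binary (1 = causal pathway) and ``scores`` rank pathways
    (higher = more significant, e.g. -log10 p).  Ties in score enter the
    curve together.  Returns (precision, recall, auprc).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValidationError("labels and scores must be matching vectors")
    if not np.any(y == 1):
        raise UsageError("no positive labels; cannot compute precision-recall")
    precision, recall, _ = precision_recall_curve(y, s)
    # average precision can exceed 1 by float round-off on perfect rankings
    auprc = float(np.clip(average_precision_score(y, s), 0.0, 1.0))
    return precision, recall, auprc


def top1_recovery(
    results: list[pd.DataFrame], causal_set_ids: list[str]
) -> int:
    """Count replicates whose causal pathway has strictly the smallest p-value.

    Exact ties with any non-causal pathway count as a failure (conservative).
    """
    if len(results) != len(causal_set_ids):
        raise UsageError("one causal set id is required per replicate")
    count = 0
    for table, causal in zip(results, causal_set_ids):
        tested = table.dropna(subset=["p_value"])
        if causal not in set(tested["set_id"]):
            raise UsageError(f"causal set {causal!r} missing from results")
        p_causal = float(tested.loc[tested["set_id"] == causal, "p_value"].iloc[0])
        others = tested.loc[tested["set_id"] != causal, "p_value"].to_numpy(float)
        if others.size == 0 or p_causal < others.min():
            count += 1
    return count


def power_at(
    results: list[pd.DataFrame],
    causal_set_ids: list[str],
    thresholds=(0.001, 0.1),
) -> pd.DataFrame:
    """Per threshold: fraction of causal (power) and non-causal (type-I)
    pathway p-values below it, pooled over replicates."""
    causal_p, null_p = [], []
    for table, causal in zip(results, causal_set_ids):
        tested = table.dropna(subset=["p_value"])
        is_causal = tested["set_id"] == causal
        causal_p.extend(tested.loc[is_causal, "p_value"].tolist())
        null_p.extend(tested.loc[~is_causal, "p_value"].tolist())
    causal_p = np.asarray(causal_p)
    null_p = np.asarray(null_p)
    rows = []
    for thr in thresholds:
        rows.append(
            {
                "threshold": thr,
                "power": float(np.mean(causal_p < thr)) if causal_p.size else np.nan,
                "type_i": float(np.mean(null_p < thr)) if null_p.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def evaluate_replicates(
    results: list[pd.DataFrame],
    causal_set_ids: list[str],
    thresholds=(0.001, 0.1),
) -> EvaluationSummary:
    """Pool per-replicate enrichment tables into one evaluation summary."""
    labels, scores = [], []
    for table, causal in zip(results, causal_set_ids):
        tested = table.dropna(subset=["p_value"])
        labels.extend((tested["set_id"] == causal).astype(int).tolist())
        with np.errstate(divide="ignore"):
            scores.extend((-np.log10(tested["p_value"].to_numpy(float))).tolist())
    _, _, auprc = precision_recall(labels, scores)
    return EvaluationSummary(
        auprc=auprc,
        top1_count=top1_recovery(results, causal_set_ids),
        n_replicates=len(results),
        power_at_threshold=power_at(results, causal_set_ids, thresholds),
    )
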