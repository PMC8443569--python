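"""Evaluation metrics for both tasks: AUC, AUPR, MCC, per-pair residue AUC."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import matthews_corrcoef, precision_recall_curve, roc_auc_score

from .exceptions import UndefinedMetricError
from .objectives import classify_residue


@dataclass
class MetricsReport:
    """Metrics for a prediction set.

    Residue AUCs are computed per pair, only over pairs whose unmasked
    positions contain both a binding and a non-binding residue.
    """

    pair_auc: float | None = None
    pair_aupr: float | None = None
    mcc: float | None = None
    residue_auc_per_pair: list[float] = field(default_factory=list)
    mean_residue_auc: float | None = None
    n_pairs_scored: int = 0
    n_pairs_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "pair_auc": self.pair_auc,
            "pair_aupr": self.pair_aupr,
            "mcc": self.mcc,
            "mean_residue_auc": self.mean_residue_auc,
            "n_pairs_scored": self.n_pairs_scored,
            "n_pairs_skipped": self.n_pairs_skipped,
        }

    def summary(self) -> str:
        rows = [(k, v) for k, v in self.to_dict().items() if v is not None]
        width = max(len(k) for k, _ in rows)
        lines = ["Metrics", "=" * (width + 10)]
        for k, v in rows:
            val = f"{v:.4f}" if isinstance(v, float) else str(v)
            lines.append(f"{k:<{width}}  {val}")
        return "\n".join(lines)


def _check_two_classes(labels: np.ndarray, what: str) -> None:
    if labels.min() == labels.max():
        raise UndefinedMetricError(f"{what} requires both classes present")


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based ROC AUC with ties averaged."""
    labels = np.asarray(labels)
    _check_two_classes(labels, "ROC AUC")
    return float(roc_auc_score(labels, scores))


def pr_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration."""
    labels = np.asarray(labels)
    _check_two_classes(labels, "AUPR")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # curve is returned from high threshold to low; integrate stepwise in recall
    return float(-np.sum(np.diff(recall) * precision[:-1]))


def mcc(labels: np.ndarray, preds: np.ndarray) -> float:
    """Matthews correlation coefficient; 0 by convention on degenerate tables."""
    labels = np.asarray(labels, dtype=np.int64)
    preds = np.asarray(preds, dtype=np.int64)
    if labels.shape != preds.shape:
        raise UndefinedMetricError("labels and predictions differ in length")
    return float(matthews_corrcoef(labels, preds))


def per_pair_residue_auc(
    res_labels: np.ndarray,
    res_probs: np.ndarray,
    res_masks: np.ndarray,
) -> tuple[list[float], float, int]:
    """Residue AUC per pair over unmasked positions.

    Pairs whose unmasked labels are single-class are skipped; returns
    (per-pair AUCs, their mean, number skipped).
    """
    aucs: list[float] = []
    skipped = 0
    for lab, prob, m in zip(np.atleast_2d(res_labels), np.atleast_2d(res_probs), np.atleast_2d(res_masks)):
        sel = m == 1
        if sel.sum() == 0:
            skipped += 1
            continue
        sub = lab[sel]
        if sub.min() == sub.max():
            skipped += 1
            continue
        aucs.append(float(roc_auc_score(sub, prob[sel])))
    if not aucs:
        raise UndefinedMetricError("no pair has both binding and non-binding residues")
    return aucs, float(np.mean(aucs)), skipped


def evaluate(
    pair_labels: np.ndarray,
    pair_probs: np.ndarray,
    res_labels: np.ndarray | None = None,
    res_probs: np.ndarray | None = None,
    res_masks: np.ndarray | None = None,
    mcc_per_pair: bool = False,
) -> MetricsReport:
    """Full metrics report for a prediction set.

    MCC is computed on residue calls at the 0.5 threshold, pooled over all
    unmasked residues of all pairs by default; ``mcc_per_pair`` averages a
    per-pair MCC over eligible pairs instead.
    """
    report = MetricsReport()
    pair_labels = np.asarray(pair_labels)
    report.pair_auc = roc_auc(pair_labels, pair_probs)
    report.pair_aupr = pr_auc(pair_labels, pair_probs)
    report.n_pairs_scored = len(pair_labels)
    if res_labels is not None and res_probs is not None and res_masks is not None:
        aucs, mean_auc, skipped = per_pair_residue_auc(res_labels, res_probs, res_masks)
        report.residue_auc_per_pair = aucs
        report.mean_residue_auc = mean_auc
        report.n_pairs_skipped = skipped
        sel = np.asarray(res_masks) == 1
        if mcc_per_pair:
            vals = []
            for lab, prob, m in zip(res_labels, res_probs, res_masks):
                s = np.asarray(m) == 1
                if s.sum() and lab[s].min() != lab[s].max():
                    vals.append(mcc(lab[s], classify_residue(prob[s])))
            report.mcc = float(np.mean(vals)) if vals else 0.0
        else:
            pooled_labels = np.asarray(res_labels)[sel]
            pooled_preds = classify_residue(np.asarray(res_probs)[sel])
            report.mcc = mcc(pooled_labels, pooled_preds)
    return report
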