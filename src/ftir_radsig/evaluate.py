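"""Evaluation metrics and dose/day-stratified reports.

Sample-level ROC curves use the majority-vote positive fraction as the
continuous score. Dose strata share the control samples (each dose stratum
is that dose's exposed samples plus all controls); day strata hold the
samples measured on that day. Permutation significance permutes labels at
the sample level, respecting within-sample pixel correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, roc_curve

__all__ = [
    "EvalReport",
    "balanced_accuracy",
    "roc_and_auc",
    "specificity_at_sensitivity",
    "stratified_report",
    "permutation_pvalue",
    "evaluate_predictions",
]


def _check_two_class(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class; metric undefined")


def balanced_accuracy(labels, predictions) -> float:
    """Mean of sensitivity and specificity."""
    labels = np.asarray(labels)
    _check_two_class(labels)
    return float(balanced_accuracy_score(labels, np.asarray(predictions)))


def roc_and_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC over score thresholds plus trapezoidal AUC.

    Returns a (fpr, tpr, threshold) table; tied scores are grouped into one
    threshold point by construction of the empirical curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    _check_two_class(labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, float(np.trapezoid(tpr, fpr))


def specificity_at_sensitivity(scores, labels, sens_threshold: float = 0.9
                               ) -> float:
    """Specificity at the largest cutoff achieving the target sensitivity.

    Predicting positive for score >= cutoff, the largest cutoff with
    sensitivity >= ``sens_threshold`` is chosen (fewest false positives
    among qualifying cutoffs) and its specificity returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    if not pos.any():
        raise ValueError("no positive samples; sensitivity unreachable")
    # candidate cutoffs: each observed score (predict positive at >= cutoff)
    for cut in np.sort(np.unique(scores))[::-1]:
        pred = scores >= cut
        sens = pred[pos].mean()
        if sens >= sens_threshold:
            neg = ~pos
            return float((~pred[neg]).mean()) if neg.any() else 0.0
    # all scores equal / threshold below the minimum: predict all positive
    return 0.0


def permutation_pvalue(metric_fn, labels, predictions_or_scores,
                       n_perm: int = 1000, seed: int = 0) -> float:
    """Add-one permutation p-value, permuting labels at the sample level.

    ``p = (1 + #{permuted metric >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels)
    preds = np.asarray(predictions_or_scores)
    observed = metric_fn(labels, preds)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        try:
            if metric_fn(perm, preds) >= observed:
                count += 1
        except ValueError:  # degenerate permutation (single class)
            continue
    return (1 + count) / (1 + n_perm)


@dataclass
class EvalReport:
    """Pooled and stratified metrics for one model's predictions."""

    pixel_accuracy: float | None
    sample_accuracy: float
    balanced_accuracy: float
    auc: float
    roc_points: pd.DataFrame
    spec_at_sens: dict
    strata: dict = field(default_factory=dict)
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "pixel_accuracy": self.pixel_accuracy,
            "sample_accuracy": self.sample_accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
            "spec_at_sens": self.spec_at_sens,
            "strata": self.strata,
            "permutation_p": self.permutation_p,
        }


def _metric_block(labels, preds, scores,
                  sens_thresholds=(0.9,)) -> dict:
    block = {
        "n": int(len(labels)),
        "n_positive": int(np.sum(labels == 1)),
        "accuracy": float(np.mean(labels == preds)),
        "balanced_accuracy": balanced_accuracy(labels, preds),
    }
    _, block["auc"] = roc_and_auc(scores, labels)
    block["spec_at_sens"] = {
        s: specificity_at_sensitivity(scores, labels, s)
        for s in sens_thresholds
    }
    return block


def stratified_report(votes: pd.DataFrame, strata_keys=("dose_gy", "day"),
                      sens_thresholds=(0.9,)) -> dict:
    """Per-stratum metrics from a sample vote table.

    ``votes`` needs columns true_label, label, vote_fraction plus the strata
    keys. Dose strata pool that dose's exposed samples with all controls;
    day strata take all samples of the day. Strata lacking either class are
    skipped (reported as None).
    """
    out: dict = {}
    labels = votes["true_label"].to_numpy()
    preds = votes["label"].to_numpy()
    scores = votes["vote_fraction"].to_numpy()
    for key in strata_keys:
        if key not in votes.columns:
            continue
        per: dict = {}
        for value in sorted(votes[key].unique()):
            value = value.item() if hasattr(value, "item") else value
            if key == "dose_gy":
                if value == 0:
                    continue
                sel = (votes[key] == value) | (votes["true_label"] == 0)
            else:
                sel = votes[key] == value
            sel = sel.to_numpy()
            try:
                per[value] = _metric_block(
                    labels[sel], preds[sel], scores[sel], sens_thresholds
                )
            except ValueError:
                per[value] = None  # stratum lacking controls or exposed
        out[key] = per
    return out


def evaluate_predictions(votes: pd.DataFrame,
                         pixel_labels: np.ndarray | None = None,
                         pixel_truth: np.ndarray | None = None,
                         strata_keys=("dose_gy", "day"),
                         sens_thresholds=(0.9,),
                         n_perm: int | None = None,
                         seed: int = 0) -> EvalReport:
    """Full report: pooled metrics, strata, optional permutation p-value."""
    labels = votes["true_label"].to_numpy()
    preds = votes["label"].to_numpy()
    scores = votes["vote_fraction"].to_numpy()
    roc_points, auc = roc_and_auc(scores, labels)
    report = EvalReport(
        pixel_accuracy=(
            float(np.mean(pixel_labels == pixel_truth))
            if pixel_labels is not None and pixel_truth is not None else None
        ),
        sample_accuracy=float(np.mean(labels == preds)),
        balanced_accuracy=balanced_accuracy(labels, preds),
        auc=auc,
        roc_points=roc_points,
        spec_at_sens={
            s: specificity_at_sensitivity(scores, labels, s)
            for s in sens_thresholds
        },
        strata=stratified_report(votes, strata_keys, sens_thresholds),
    )
    if n_perm:
        report.permutation_p = permutation_pvalue(
            balanced_accuracy, labels, preds, n_perm=n_perm, seed=seed
        )
    return report
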