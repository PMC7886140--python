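"""ROC / threshold analysis and prescriptive-accuracy scoring.

AUROC is computed in its Mann–Whitney form — the probability that a random
case outscores a random control, counting ties half — which equals the
trapezoidal area under the tie-aware ROC curve.  The operating cutoff is
chosen by maximising Youden's J = sensitivity + specificity - 1, breaking
ties toward the lower threshold (the more sensitive choice, appropriate for
a screening tool).  Category accuracy follows the top-2 rule: a patient is
correctly triaged when the true IUIS category is among the two highest-
scoring predictions; patients with degenerate (equal-score) rankings are
unscorable and excluded from the denominator.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .categories import IUISCategory
from .estimator import BayesRiskScreen
from .inference import iuis_ranking
from .network import NetworkSpec, PatientEvidence

__all__ = [
    "ThresholdMetrics",
    "EvaluationReport",
    "auroc",
    "roc_points",
    "threshold_metrics",
    "best_cutoff",
    "category_top2_accuracy",
    "evaluate_cohort",
]


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = (y == "case")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise ValueError("need both case and control labels")
    return y


def auroc(labels, scores) -> float:
    """Tie-aware AUROC: P(case score > control score) + 0.5 P(tie)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("labels and scores must have equal length")
    ranks = rankdata(s)  # average ranks handle ties exactly
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(labels, scores) -> list[tuple[float, float, float]]:
    """(fpr, tpr, threshold) triples for the inclusive >= decision rule,
    swept over the distinct observed scores from high to low (plus the
    all-negative operating point above the maximum)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    points = [(0.0, 0.0, math.inf)]
    for t in sorted(np.unique(s))[::-1]:
        pred = s >= t
        tpr = float((pred & y).sum() / n_pos)
        fpr = float((pred & ~y).sum() / n_neg)
        points.append((fpr, tpr, float(t)))
    return points


@dataclasses.dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    sensitivity: float
    specificity: float
    precision: float  # NaN when no positive predictions
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int


def threshold_metrics(labels, scores, threshold: float) -> ThresholdMetrics:
    """Confusion-matrix metrics for the inclusive >= rule at *threshold*."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision undefined", stacklevel=2)
        precision = math.nan
    else:
        precision = tp / (tp + fp)
    recall = sensitivity
    if math.isnan(precision) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ThresholdMetrics(
        threshold=threshold, sensitivity=sensitivity, specificity=specificity,
        precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, tn=tn, fn=fn,
    )


def best_cutoff(labels, scores) -> float:
    """Cutoff maximising Youden's J among observed-score midpoints.

    Candidates are the midpoints between adjacent distinct scores; ties in J
    break toward the lower threshold.  With all scores tied there is no
    informative cutoff: the single observed value is returned with a warning.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    distinct = np.unique(s)
    if distinct.size == 1:
        warnings.warn("all scores tied; Youden's J is 0 everywhere", stacklevel=2)
        return float(distinct[0])
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_t, best_j = None, -math.inf
    for t in candidates:  # ascending, so strict > keeps the lowest on ties
        m = threshold_metrics(y, s, float(t))
        j = m.sensitivity + m.specificity - 1.0
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def category_top2_accuracy(
    predictions: Mapping[str, tuple[Sequence[IUISCategory], bool]],
    truth: Mapping[str, IUISCategory],
) -> tuple[float, int]:
    """Fraction of scorable patients whose true category is in the top 2.

    ``predictions`` maps patient id -> (top categories, degenerate flag);
    degenerate patients are unscorable and only counted in ``n_unscorable``.
    Returns (accuracy, n_unscorable); accuracy is NaN when no patient is
    scorable.
    """
    if set(predictions) != set(truth):
        raise ValueError("predictions and truth cover different patient ids")
    n_correct = n_scored = n_unscorable = 0
    for pid, (top, degenerate) in predictions.items():
        if degenerate:
            n_unscorable += 1
            continue
        n_scored += 1
        if truth[pid] in tuple(top)[:2]:
            n_correct += 1
    accuracy = n_correct / n_scored if n_scored else math.nan
    return accuracy, n_unscorable


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    """Full discrimination + prescriptive-accuracy report for one cohort."""

    auroc: float
    roc_points: list[tuple[float, float, float]]
    threshold: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    best_cutoff: float
    n_case: int
    n_control: int
    category_top2_accuracy: float | None = None
    n_unscorable: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roc_points"] = [list(p) for p in self.roc_points]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_cohort(
    presence: pd.DataFrame,
    labels,
    spec: NetworkSpec,
    threshold: float | None = None,
    truth_categories: Mapping[str, IUISCategory] | None = None,
) -> EvaluationReport:
    """Score a labelled presence matrix with *spec* and report performance."""
    est = BayesRiskScreen.from_network_spec(spec)
    scores = est.posterior_risk(presence)
    y = _as_binary(labels)
    threshold = spec.risk_threshold if threshold is None else threshold
    m = threshold_metrics(y, scores, threshold)
    top2_acc = n_unscorable = None
    if truth_categories is not None:
        cols = np.asarray(presence.columns, dtype=object)
        predictions = {}
        for pid in truth_categories:
            row = presence.loc[pid].to_numpy(dtype=bool)
            ev = PatientEvidence(frozenset(cols[row]), patient_id=pid)
            _, top2, degenerate = iuis_ranking(ev, spec)
            predictions[pid] = (top2, degenerate)
        top2_acc, n_unscorable = category_top2_accuracy(predictions, truth_categories)
    return EvaluationReport(
        auroc=auroc(y, scores),
        roc_points=roc_points(y, scores),
        threshold=threshold,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        precision=m.precision,
        recall=m.recall,
        f1=m.f1,
        best_cutoff=best_cutoff(y, scores),
        n_case=int(y.sum()),
        n_control=int((~y).sum()),
        category_top2_accuracy=top2_acc,
        n_unscorable=n_unscorable,
    )
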