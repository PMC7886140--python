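"""Evidence-set inference: posterior risk, threshold class, IUIS ranking.

These are thin wrappers that evaluate a :class:`~piprob.network.NetworkSpec`
for a single patient's evidence set; the numerical core is
:class:`~piprob.estimator.BayesRiskScreen`.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .categories import IUISCategory
from .estimator import BayesRiskScreen
from .network import (
    NetworkSpec,
    PatientEvidence,
    RiskResult,
    resolve_evidence,
    sort_categories_by_score,
)

__all__ = ["posterior_risk", "classify", "iuis_ranking", "score_patient"]


def _evidence_row(evidence: PatientEvidence, spec: NetworkSpec) -> pd.DataFrame:
    names = spec.feature_names
    unknown = evidence.present_features - set(names)
    if unknown:
        raise KeyError(f"unknown feature name(s): {sorted(unknown)}")
    row = np.array([[name in evidence.present_features for name in names]])
    return pd.DataFrame(row, columns=list(names))


def posterior_risk(
    evidence: PatientEvidence,
    spec: NetworkSpec,
    evidence_mode: str = "present_only",
) -> float:
    """P(case | present features) under conditional independence.

    Empty evidence returns exactly the population prior: with nothing
    instantiated, the joint probability defaults to the general-population
    risk.
    """
    if not evidence.present_features:
        # short-circuit keeps the empty-evidence contract bit-exact
        if evidence_mode == "present_only":
            return spec.prior_case
    est = BayesRiskScreen.from_network_spec(spec, evidence_mode=evidence_mode)
    return float(est.posterior_risk(_evidence_row(evidence, spec))[0])


def classify(risk: float, spec: NetworkSpec) -> str:
    """Threshold rule: ``med_high_risk`` iff risk >= spec.risk_threshold."""
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk must be in [0,1], got {risk}")
    return "med_high_risk" if risk >= spec.risk_threshold else "low_risk"


def iuis_ranking(
    evidence: PatientEvidence, spec: NetworkSpec
) -> tuple[dict[IUISCategory, float], tuple[IUISCategory, IUISCategory], bool]:
    """Score each IUIS category by summing case-conditional probabilities.

    A category's score is the sum of ``p_given_case`` over present features
    whose arc set contains it.  If no present feature carries an arc (or the
    evidence is empty) the prediction is degenerate: all seven categories
    receive an equal score and the flag is set.  Top-2 selection breaks ties
    by the canonical category order.
    """
    unknown = evidence.present_features - set(spec.feature_names)
    if unknown:
        raise KeyError(f"unknown feature name(s): {sorted(unknown)}")
    scores = {c: 0.0 for c in IUISCategory}
    for feature in spec.features:
        if feature.name in evidence.present_features:
            for cat in feature.categories:
                scores[cat] += feature.p_given_case
    degenerate = all(s == 0.0 for s in scores.values())
    if degenerate:
        scores = {c: 1.0 / len(IUISCategory) for c in IUISCategory}
    ranked = sort_categories_by_score(scores)
    return scores, (ranked[0], ranked[1]), degenerate


def score_patient(
    codes: Iterable[str],
    spec: NetworkSpec,
    patient_id: str | None = None,
    evidence_mode: str = "present_only",
) -> RiskResult:
    """End-to-end scoring: ICD-10 codes -> risk, class, category ranking."""
    evidence, unmatched = resolve_evidence(codes, spec, patient_id=patient_id)
    risk = posterior_risk(evidence, spec, evidence_mode=evidence_mode)
    scores, top2, degenerate = iuis_ranking(evidence, spec)
    total = sum(scores.values())
    normalized = {c: s / total for c, s in scores.items()}
    return RiskResult(
        posterior_risk=risk,
        classification=classify(risk, spec),
        category_scores=scores,
        category_scores_normalized=normalized,
        top_categories=top2,
        degenerate=degenerate,
        patient_id=patient_id,
        unmatched_codes=unmatched,
    )
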