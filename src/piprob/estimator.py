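"""Scikit-learn-style estimator for the two-layer Bayesian screening model.

The model is a binary risk node A (case vs. control) with prior P(A), and a
bank of Bernoulli feature nodes that are conditionally independent given A.
Fitting estimates each feature's class-conditional prevalence as the carrier
fraction in the corresponding cohort (with a small positive floor replacing
zero counts).  Scoring instantiates only the features a patient *has*:

    P(A | B_1..B_n) = P(A) prod_i P(B_i|A) / sum_a P(a) prod_i P(B_i|a)

over the present features only — an absent feature is unobserved and
contributes no (1-p) term.  A strict two-state naive-Bayes mode (absence
counts as evidence) is available via ``evidence_mode="two_state"`` for
comparison.  Likelihood products are accumulated in log space.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

from .network import (
    DEFAULT_PRIOR_CASE,
    DEFAULT_RISK_THRESHOLD,
    ZERO_COUNT_FLOOR,
    NetworkSpec,
)

__all__ = ["BayesRiskScreen"]


def _coerce_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    """Return (boolean ndarray, column names if X is a DataFrame)."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=bool), [str(c) for c in X.columns]
    arr = np.asarray(X)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D feature matrix, got shape {arr.shape}")
    return arr.astype(bool), None


def _binary_labels(y, positive_label=None) -> tuple[np.ndarray, np.ndarray]:
    """Return (boolean case mask, classes_ array [negative, positive])."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = "case" if "case" in classes.tolist() else classes[1]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in {classes.tolist()}")
    negative_label = classes[classes != positive_label][0]
    return y == positive_label, np.array([negative_label, positive_label])


class BayesRiskScreen(BaseEstimator, ClassifierMixin):
    """Naive-Bayes risk screen with present-only evidence instantiation.

    Parameters
    ----------
    prior_case : float, default 0.01
        Population prior P(A) for the positive (case) class; the default is
        the 1% general-population prevalence of features of PI risk.
    risk_threshold : float, default 0.055
        Posterior risk at or above which a patient is classified
        ``med_high_risk`` (inclusive).  The 6% clinical-guidance figure is
        the documented alternative setting.
    floor : float, default 1e-6
        Probability substituted for a zero-count cohort cell (0.0001% as a
        fraction) so no likelihood term is exactly zero.
    evidence_mode : {"present_only", "two_state"}, default "present_only"
        "present_only" treats an absent feature as unobserved; "two_state"
        is strict Bernoulli naive Bayes where absence contributes (1-p).
    positive_label : optional
        Which label in ``y`` is the case class; defaults to ``"case"`` when
        present, else the larger label.

    Attributes
    ----------
    classes_ : ndarray of shape (2,), [negative, positive].
    feature_names_in_ : ndarray of str, when fitted on a DataFrame.
    p_case_, p_control_ : ndarray, class-conditional feature prevalences.
    count_case_, count_control_ : ndarray of carrier counts.
    weight_ : ndarray, ratio p_case_ / p_control_ (unrounded).
    n_case_, n_control_ : cohort sizes.
    """

    def __init__(
        self,
        prior_case: float = DEFAULT_PRIOR_CASE,
        risk_threshold: float = DEFAULT_RISK_THRESHOLD,
        floor: float = ZERO_COUNT_FLOOR,
        evidence_mode: str = "present_only",
        positive_label=None,
    ):
        self.prior_case = prior_case
        self.risk_threshold = risk_threshold
        self.floor = floor
        self.evidence_mode = evidence_mode
        self.positive_label = positive_label

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y) -> "BayesRiskScreen":
        """Estimate class-conditional prevalences from a labelled cohort.

        X is a binary patient x feature presence matrix (DataFrame keeps
        feature names); y holds the two cohort labels.
        """
        self._validate_params()
        Xb, names = _coerce_matrix(X)
        case_mask, self.classes_ = _binary_labels(y, self.positive_label)
        if Xb.shape[0] != case_mask.shape[0]:
            raise ValueError("X and y have different numbers of patients")
        self.n_features_in_ = Xb.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_case_ = int(case_mask.sum())
        self.n_control_ = int((~case_mask).sum())
        self.count_case_ = Xb[case_mask].sum(axis=0).astype(int)
        self.count_control_ = Xb[~case_mask].sum(axis=0).astype(int)
        self.p_case_ = self._floored(self.count_case_, self.n_case_)
        self.p_control_ = self._floored(self.count_control_, self.n_control_)
        self.weight_ = self.p_case_ / self.p_control_
        return self

    def _validate_params(self) -> None:
        if not 0.0 < self.prior_case < 1.0:
            raise ValueError(f"prior_case must be in (0,1), got {self.prior_case}")
        if not 0.0 < self.floor < 1.0:
            raise ValueError(f"floor must be in (0,1), got {self.floor}")
        if self.evidence_mode not in ("present_only", "two_state"):
            raise ValueError(f"unknown evidence_mode {self.evidence_mode!r}")

    def _floored(self, counts: np.ndarray, n: int) -> np.ndarray:
        if n <= 0:
            raise ValueError("each cohort must contain at least one patient")
        p = counts / n
        if np.any(counts == n):
            warnings.warn(
                "feature present in every patient of a cohort; conditional "
                "probability saturates at 1",
                stacklevel=3,
            )
        return np.where(counts == 0, self.floor, p)

    @classmethod
    def from_network_spec(cls, spec: NetworkSpec, **overrides) -> "BayesRiskScreen":
        """Build an already-fitted screen from a network definition."""
        est = cls(
            prior_case=overrides.pop("prior_case", spec.prior_case),
            risk_threshold=overrides.pop("risk_threshold", spec.risk_threshold),
            **overrides,
        )
        est._validate_params()
        est.classes_ = np.array(["control", "case"])
        est.feature_names_in_ = np.asarray(spec.feature_names, dtype=object)
        est.n_features_in_ = len(spec.features)
        est.p_case_ = np.array([f.p_given_case for f in spec.features])
        est.p_control_ = np.array([f.p_given_control for f in spec.features])
        est.count_case_ = np.array([-1 if f.count_case is None else f.count_case for f in spec.features])
        est.count_control_ = np.array([-1 if f.count_control is None else f.count_control for f in spec.features])
        est.weight_ = est.p_case_ / est.p_control_
        est.n_case_ = spec.n_case or 0
        est.n_control_ = spec.n_control or 0
        return est

    def to_network_spec(self, skeleton: NetworkSpec) -> NetworkSpec:
        """Write fitted probabilities into a skeleton spec (matched by name)."""
        self._check_fitted()
        if not hasattr(self, "feature_names_in_"):
            raise ValueError("fit on a DataFrame to carry feature names")
        probs = {
            name: (pc, pk)
            for name, pc, pk in zip(self.feature_names_in_, self.p_case_, self.p_control_)
        }
        spec = skeleton.with_probabilities(probs)
        return spec.model_copy(
            update={
                "prior_case": self.prior_case,
                "risk_threshold": self.risk_threshold,
                "n_case": self.n_case_ or None,
                "n_control": self.n_control_ or None,
            }
        )

    # -- scoring ------------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "p_case_"):
            raise ValueError("this BayesRiskScreen instance is not fitted yet")

    def _align(self, X) -> np.ndarray:
        Xb, names = _coerce_matrix(X)
        if names is not None and hasattr(self, "feature_names_in_"):
            missing = set(names) - set(self.feature_names_in_)
            if missing:
                raise KeyError(f"unknown feature name(s): {sorted(missing)}")
            frame = pd.DataFrame(Xb, columns=names)
            aligned = np.zeros((Xb.shape[0], self.n_features_in_), dtype=bool)
            for j, fname in enumerate(self.feature_names_in_):
                if fname in frame.columns:
                    aligned[:, j] = frame[fname].to_numpy()
            return aligned
        if Xb.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xb.shape[1]} features, expected {self.n_features_in_}"
            )
        return Xb

    def posterior_risk(self, X) -> np.ndarray:
        """Posterior P(case | present features) for each row of X, in log space."""
        self._check_fitted()
        Xb = self._align(X)
        log_pc, log_pk = np.log(self.p_case_), np.log(self.p_control_)
        if self.evidence_mode == "two_state":
            log_case = Xb @ log_pc + (~Xb) @ np.log1p(-self.p_case_)
            log_ctrl = Xb @ log_pk + (~Xb) @ np.log1p(-self.p_control_)
        else:
            log_case = Xb @ log_pc
            log_ctrl = Xb @ log_pk
        log_case = log_case + np.log(self.prior_case)
        log_ctrl = log_ctrl + np.log1p(-self.prior_case)
        both = np.stack([log_ctrl, log_case], axis=1)
        return np.exp(log_case - logsumexp(both, axis=1))

    def predict_proba(self, X) -> np.ndarray:
        """Column-stacked [P(control), P(case)] in ``classes_`` order."""
        risk = self.posterior_risk(X)
        return np.column_stack([1.0 - risk, risk])

    def predict(self, X) -> np.ndarray:
        """Threshold the posterior at ``risk_threshold`` (inclusive >=)."""
        risk = self.posterior_risk(X)
        return np.where(risk >= self.risk_threshold, self.classes_[1], self.classes_[0])
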