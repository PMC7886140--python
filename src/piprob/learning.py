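"""Cohort construction and conditional-probability-table learning.

Starting point is a *cohort extract*: one row per (patient_id, cohort label,
ICD-10 code, date).  The pipeline selects the case cohort by the two-codes/
two-dates inclusion rule, reduces the extract to a patient x feature presence
matrix (a patient counts at most once per feature), and estimates each
feature's class-conditional prevalence as the carrier fraction in its cohort
— zero counts are replaced by a small positive floor so no likelihood term
is ever exactly zero.  The ranking statistic ("weight") is the ratio of the
case to the control conditional probability.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .estimator import BayesRiskScreen
from .network import (
    ZERO_COUNT_FLOOR,
    NetworkSpec,
    code_matches,
)

__all__ = [
    "FeatureEstimate",
    "read_cohort_extract",
    "write_cohort_extract",
    "select_case_cohort",
    "estimate_conditional_probability",
    "compute_weight",
    "presence_matrix",
    "build_feature_table",
    "feature_table_report",
    "learn_spec",
    "DEFAULT_SCID_CODES",
    "DEFAULT_SECONDARY_CODES",
]

EXTRACT_COLUMNS = ("patient_id", "cohort", "icd_code", "date")

#: Default exclusion code sets for case-cohort selection (configurable):
#: severe combined immunodeficiency (detected by newborn screening) and
#: secondary immunodeficiency.
DEFAULT_SCID_CODES: tuple[str, ...] = ("D81.0", "D81.1", "D81.2")
DEFAULT_SECONDARY_CODES: tuple[str, ...] = ("B20", "D84.81")


@dataclasses.dataclass(frozen=True)
class FeatureEstimate:
    """Learned CPT entry for one feature, with its ranking weight."""

    feature_name: str
    count_case: int
    count_control: int
    p_case: float
    p_control: float
    weight: float


def read_cohort_extract(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort extract CSV/TSV.

    Expects columns ``patient_id,cohort,icd_code,date`` with ISO-8601 dates
    and cohort labels in {case, control}; no patient may appear under both.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    extract = pd.read_csv(path, sep=sep, dtype=str)
    return validate_cohort_extract(extract)


def validate_cohort_extract(extract: pd.DataFrame) -> pd.DataFrame:
    missing = set(EXTRACT_COLUMNS) - set(extract.columns)
    if missing:
        raise ValueError(f"cohort extract is missing column(s): {sorted(missing)}")
    bad = set(extract["cohort"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"cohort labels must be 'case' or 'control', got {sorted(bad)}")
    labels = extract.groupby("patient_id")["cohort"].nunique()
    both = labels[labels > 1]
    if not both.empty:
        raise ValueError(
            f"patient(s) appear under both cohort labels: {sorted(both.index[:5])}"
        )
    extract = extract.copy()
    extract["date"] = pd.to_datetime(extract["date"], format="ISO8601").dt.date
    return extract


def write_cohort_extract(extract: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    extract.to_csv(path, sep=sep, index=False, columns=list(EXTRACT_COLUMNS))


def _matches_any(codes: pd.Series, patterns: Sequence[str]) -> pd.Series:
    return codes.map(lambda c: any(code_matches(c, p) for p in patterns))


def select_case_cohort(
    extract: pd.DataFrame,
    pi_codes: Iterable[str],
    scid_codes: Sequence[str] = DEFAULT_SCID_CODES,
    secondary_codes: Sequence[str] = DEFAULT_SECONDARY_CODES,
) -> set[str]:
    """Patients qualifying for the case cohort.

    Inclusion: at least two records whose codes match ``pi_codes``, entered
    on at least two distinct calendar dates.  Exclusion (applied to the case
    side only): any SCID or secondary-immunodeficiency code.
    """
    pi_codes = tuple(pi_codes)
    if not pi_codes:
        raise ValueError("pi_codes must be a non-empty set of ICD-10 patterns")
    if extract.empty:
        raise ValueError("cohort extract is empty")
    hits = extract[_matches_any(extract["icd_code"], pi_codes)]
    by_patient = hits.groupby("patient_id").agg(
        n_records=("icd_code", "size"), n_dates=("date", "nunique")
    )
    qualified = set(by_patient[(by_patient.n_records >= 2) & (by_patient.n_dates >= 2)].index)
    excl_patterns = tuple(scid_codes) + tuple(secondary_codes)
    if excl_patterns:
        excluded = set(extract.loc[_matches_any(extract["icd_code"], excl_patterns), "patient_id"])
        qualified -= excluded
    return qualified


def estimate_conditional_probability(
    count: int, n: int, floor: float = ZERO_COUNT_FLOOR
) -> float:
    """Carrier fraction count/n with the zero-count floor.

    Returns ``floor`` (default 1e-6, i.e. 0.0001%) when count is zero; a
    saturated count (count == n) returns 1.0 with a warning since a
    certainty of 100% does not reflect real-world uncertainty.
    """
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    if not 0 <= count <= n:
        raise ValueError(f"count must be in [0, {n}], got {count}")
    if count == 0:
        return floor
    if count == n:
        warnings.warn(
            "feature present in every cohort member; probability saturates at 1",
            stacklevel=2,
        )
    return count / n


def compute_weight(
    p_case: float, p_control: float, convention: str = "unrounded"
) -> float:
    """Ratio of case to control conditional probability.

    ``unrounded`` (canonical) divides the raw fractions.  ``rounded_percent``
    divides the percentages after rounding each to one decimal — the
    convention that reproduces the published zero-count rows, where e.g. a
    2.2% prevalence over the 0.0001% floor gives a weight of 22000.
    """
    if p_case <= 0 or p_control <= 0:
        raise ValueError("both probabilities must be strictly positive")
    if convention == "unrounded":
        return p_case / p_control
    if convention == "rounded_percent":
        return _display_percent(p_case) / _display_percent(p_control)
    raise ValueError(f"unknown weight convention {convention!r}")


def _display_percent(p: float) -> float:
    """Percent rounded to one decimal; sub-resolution values (e.g. the
    0.0001% floor) are kept unrounded, as printed tables do."""
    rounded = round(p * 100.0, 1)
    return rounded if rounded > 0.0 else p * 100.0


def presence_matrix(
    extract: pd.DataFrame, spec: NetworkSpec
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse an extract to (patient x feature bool matrix, cohort labels).

    A patient is a carrier of a feature iff any of their codes matches any of
    the feature's patterns, regardless of how often the code repeats.
    """
    extract = validate_cohort_extract(extract)
    patients = extract["patient_id"].unique()
    labels = extract.drop_duplicates("patient_id").set_index("patient_id")["cohort"]
    labels = labels.loc[patients]
    X = pd.DataFrame(False, index=pd.Index(patients, name="patient_id"),
                     columns=list(spec.feature_names))
    for feature in spec.features:
        if not feature.icd_codes:
            raise ValueError(f"feature {feature.name!r} has an empty ICD code set")
        mask = _matches_any(extract["icd_code"], feature.icd_codes)
        carriers = extract.loc[mask, "patient_id"].unique()
        X.loc[carriers, feature.name] = True
    return X, labels


def build_feature_table(
    extract: pd.DataFrame,
    spec_skeleton: NetworkSpec,
    floor: float = ZERO_COUNT_FLOOR,
) -> list[FeatureEstimate]:
    """Estimate all feature CPT entries, sorted by weight descending.

    Ties are broken by the feature order of the skeleton spec (canonical
    feature order).  Delegates the count -> probability -> weight arithmetic
    to the fitted :class:`BayesRiskScreen`.
    """
    if extract.empty:
        raise ValueError("cohort extract is empty")
    X, labels = presence_matrix(extract, spec_skeleton)
    est = BayesRiskScreen(floor=floor, positive_label="case").fit(X, labels)
    order = {name: i for i, name in enumerate(spec_skeleton.feature_names)}
    rows = [
        FeatureEstimate(
            feature_name=name,
            count_case=int(cc),
            count_control=int(ck),
            p_case=float(pc),
            p_control=float(pk),
            weight=float(w),
        )
        for name, cc, ck, pc, pk, w in zip(
            est.feature_names_in_, est.count_case_, est.count_control_,
            est.p_case_, est.p_control_, est.weight_,
        )
    ]
    return sorted(rows, key=lambda r: (-r.weight, order[r.feature_name]))


def feature_table_report(
    estimates: Sequence[FeatureEstimate], spec: NetworkSpec | None = None
) -> pd.DataFrame:
    """Render estimates in the published table layout.

    Columns: rank, description, ICD codes, carrier counts, percentages to
    one decimal, and the integer-rounded weight.
    """
    rows = []
    for rank, e in enumerate(estimates, start=1):
        desc, codes = e.feature_name, ""
        if spec is not None:
            node = spec.feature(e.feature_name)
            desc = node.description or e.feature_name
            codes = ", ".join(node.icd_codes)
        rows.append(
            {
                "rank": rank,
                "description": desc,
                "icd_codes": codes,
                "count_case": e.count_case,
                "p_case_percent": _display_percent(e.p_case),
                "count_control": e.count_control,
                "p_control_percent": _display_percent(e.p_control),
                "weight": round(e.weight),
            }
        )
    return pd.DataFrame(rows)


def learn_spec(
    extract: pd.DataFrame,
    spec_skeleton: NetworkSpec,
    floor: float = ZERO_COUNT_FLOOR,
) -> NetworkSpec:
    """Return the skeleton spec with probabilities learned from the extract.

    Literature-sourced nodes keep their configured probabilities; cohort
    sizes are recorded as metadata.
    """
    estimates = {e.feature_name: e for e in build_feature_table(extract, spec_skeleton, floor)}
    updates = {}
    counts = {}
    for f in spec_skeleton.features:
        if f.source == "literature":
            continue
        e = estimates[f.name]
        updates[f.name] = (e.p_case, e.p_control)
        counts[f.name] = (e.count_case, e.count_control)
    spec = spec_skeleton.with_probabilities(updates)
    features = []
    for f in spec.features:
        if f.name in counts:
            cc, ck = counts[f.name]
            f = f.model_copy(update={"count_case": cc, "count_control": ck})
        features.append(f)
    labels = extract.drop_duplicates("patient_id")["cohort"]
    return spec.model_copy(
        update={
            "features": tuple(features),
            "n_case": int((labels == "case").sum()),
            "n_control": int((labels == "control").sum()),
        }
    )
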