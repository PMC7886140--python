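"""Domain types for the screening network and its on-disk definition format.

A network is a two-layer Bayesian model: a binary risk node (does this
patient have a primary immunodeficiency?) with a population prior, and one
feature node per clinical concept, each holding the class-conditional
probability of observing that concept in the case and control populations.
Feature nodes additionally carry arcs to IUIS diagnostic categories used for
the prescriptive (top-2 category) output.

Probabilities are stored internally as fractions in (0, 1]; the YAML/JSON
file dialect stores them as percentages, matching how clinical prevalence
tables are conventionally printed.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .categories import CANONICAL_RANK, IUISCategory

__all__ = [
    "FeatureNode",
    "NetworkSpec",
    "PatientEvidence",
    "RiskResult",
    "load_network_spec",
    "write_network_spec",
    "load_builtin_spec",
    "builtin_spec_names",
    "normalize_code",
    "normalize_pattern",
    "code_matches",
    "resolve_evidence",
]

#: Default population prior for primary immunodeficiency risk (1%).
DEFAULT_PRIOR_CASE = 0.01
#: Default risk threshold for the med-high classification (5.5%); the 6%
#: clinical-guidance figure is the documented alternative configuration.
DEFAULT_RISK_THRESHOLD = 0.055
#: Probability substituted for a zero-count cohort cell (0.0001% as fraction).
ZERO_COUNT_FLOOR = 1e-6


class FeatureNode(BaseModel):
    """One clinical concept node with its ICD-10 code set and CPT entries.

    ``p_given_case`` / ``p_given_control`` are the class-conditional
    prevalences P(feature | PI) and P(feature | not PI), as fractions.
    ``source`` records whether the probabilities were learned from cohort
    counts or taken from literature (the meningococcal-disease node).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    description: str = ""
    icd_codes: tuple[str, ...] = ()
    p_given_case: float = Field(gt=0.0, le=1.0)
    p_given_control: float = Field(gt=0.0, le=1.0)
    source: Literal["cohort_learned", "literature"] = "cohort_learned"
    categories: tuple[IUISCategory, ...] = ()
    count_case: int | None = None
    count_control: int | None = None

    @model_validator(mode="after")
    def _codes_required_when_learned(self) -> "FeatureNode":
        if self.source == "cohort_learned" and not self.icd_codes:
            raise ValueError(
                f"feature {self.name!r}: cohort_learned nodes need a non-empty icd_codes set"
            )
        return self

    @property
    def weight(self) -> float:
        """Ratio of case to control conditional probability."""
        return self.p_given_case / self.p_given_control


class NetworkSpec(BaseModel):
    """The full screening model: features, risk prior, threshold, arcs."""

    model_config = ConfigDict(frozen=True)

    features: tuple[FeatureNode, ...]
    prior_case: float = Field(default=DEFAULT_PRIOR_CASE, gt=0.0, lt=1.0)
    risk_threshold: float = Field(default=DEFAULT_RISK_THRESHOLD, gt=0.0, lt=1.0)
    n_case: int | None = None
    n_control: int | None = None

    @field_validator("features")
    @classmethod
    def _unique_names(cls, features: tuple[FeatureNode, ...]) -> tuple[FeatureNode, ...]:
        names = [f.name for f in features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        return features

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def category_arcs(self) -> dict[str, frozenset[IUISCategory]]:
        """Mapping feature name -> categories that feature arcs into."""
        return {f.name: frozenset(f.categories) for f in self.features}

    def feature(self, name: str) -> FeatureNode:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"unknown feature: {name!r}")

    def with_probabilities(
        self, probabilities: Mapping[str, tuple[float, float]]
    ) -> "NetworkSpec":
        """Return a copy with (p_given_case, p_given_control) replaced by name."""
        new_features = []
        for f in self.features:
            if f.name in probabilities:
                pc, pk = probabilities[f.name]
                f = f.model_copy(update={"p_given_case": pc, "p_given_control": pk})
            new_features.append(f)
        return self.model_copy(update={"features": tuple(new_features)})


@dataclasses.dataclass(frozen=True)
class PatientEvidence:
    """The set of features instantiated "present" for one patient.

    A feature absent from ``present_features`` is *unobserved*, not
    observed-absent: it contributes nothing to the posterior.
    """

    present_features: frozenset[str]
    patient_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "present_features", frozenset(self.present_features))


@dataclasses.dataclass(frozen=True)
class RiskResult:
    """Full output for one patient: posterior risk, class, category ranking."""

    posterior_risk: float
    classification: Literal["med_high_risk", "low_risk"]
    category_scores: dict[IUISCategory, float]
    category_scores_normalized: dict[IUISCategory, float]
    top_categories: tuple[IUISCategory, IUISCategory]
    degenerate: bool
    patient_id: str | None = None
    unmatched_codes: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        """JSON-friendly rendering (percent scale for the risk)."""
        return {
            "patient_id": self.patient_id,
            "posterior_risk_percent": self.posterior_risk * 100.0,
            "classification": self.classification,
            "category_scores": {c.value: s for c, s in self.category_scores.items()},
            "category_scores_normalized": {
                c.value: s for c, s in self.category_scores_normalized.items()
            },
            "top_categories": [c.value for c in self.top_categories],
            "degenerate": self.degenerate,
            "unmatched_codes": sorted(self.unmatched_codes),
        }


# ---------------------------------------------------------------------------
# ICD-10 code matching
# ---------------------------------------------------------------------------

def normalize_code(code: str) -> str:
    """Canonical form of an ICD-10 code: upper-case, dot removed."""
    return code.strip().upper().replace(".", "")

def normalize_pattern(pattern: str) -> str:
    """Canonical form of a code pattern.

    Trailing lower-case ``x`` characters are wildcard markers ("A39.xx" is
    the A39 family) and are stripped; an upper-case ``X`` is a literal ICD-10
    placeholder character (as in T45.1X5A) and is kept.
    """
    p = pattern.strip().rstrip("x")
    return normalize_code(p)

def code_matches(code: str, pattern: str) -> bool:
    """True if the code is the pattern or a child of the pattern's family."""
    return normalize_code(code).startswith(normalize_pattern(pattern))


def resolve_evidence(
    codes: Iterable[str],
    spec: NetworkSpec,
    patient_id: str | None = None,
) -> tuple[PatientEvidence, frozenset[str]]:
    """Map raw ICD-10 codes to present features under *spec*.

    A feature is present iff any code matches any of its patterns (dot-
    insensitive prefix matching).  Codes that match no feature are returned
    as the unmatched remainder, never raised.
    """
    codes = frozenset(codes)
    present: set[str] = set()
    matched: set[str] = set()
    for feature in spec.features:
        for code in codes:
            if any(code_matches(code, pat) for pat in feature.icd_codes):
                present.add(feature.name)
                matched.add(code)
    return PatientEvidence(frozenset(present), patient_id=patient_id), frozenset(codes - matched)


# ---------------------------------------------------------------------------
# File dialect (percent-scaled YAML/JSON)
# ---------------------------------------------------------------------------

def _feature_from_file(entry: dict, index: int) -> FeatureNode:
    try:
        name = entry["name"]
    except KeyError:
        raise ValueError(f"features[{index}]: missing required key 'name'") from None
    for key in ("p_case_percent", "p_control_percent"):
        if key not in entry:
            raise ValueError(f"feature {name!r}: missing required key {key!r}")
        value = float(entry[key])
        if not 0.0 < value <= 100.0:
            raise ValueError(
                f"feature {name!r}: {key} must be in (0, 100] percent, got {value}"
            )
    return FeatureNode(
        name=name,
        description=entry.get("description", ""),
        icd_codes=tuple(entry.get("icd_codes", ())),
        p_given_case=float(entry["p_case_percent"]) / 100.0,
        p_given_control=float(entry["p_control_percent"]) / 100.0,
        source=entry.get("source", "cohort_learned"),
        categories=tuple(IUISCategory(c) for c in entry.get("categories", ())),
        count_case=entry.get("count_case"),
        count_control=entry.get("count_control"),
    )


def spec_from_mapping(data: Mapping) -> NetworkSpec:
    """Build a validated NetworkSpec from the parsed file mapping."""
    if not isinstance(data, Mapping) or "features" not in data:
        raise ValueError("network definition must be a mapping with a 'features' list")
    features = tuple(
        _feature_from_file(entry, i) for i, entry in enumerate(data["features"])
    )
    kwargs: dict = {"features": features}
    if "prior_case_percent" in data:
        kwargs["prior_case"] = float(data["prior_case_percent"]) / 100.0
    if "risk_threshold_percent" in data:
        kwargs["risk_threshold"] = float(data["risk_threshold_percent"]) / 100.0
    for key in ("n_case", "n_control"):
        if data.get(key) is not None:
            kwargs[key] = int(data[key])
    return NetworkSpec(**kwargs)


def spec_to_mapping(spec: NetworkSpec) -> dict:
    """Render a NetworkSpec back to the percent-scaled file mapping."""
    features = []
    for f in spec.features:
        entry: dict = {
            "name": f.name,
            "description": f.description,
            "icd_codes": list(f.icd_codes),
            "p_case_percent": f.p_given_case * 100.0,
            "p_control_percent": f.p_given_control * 100.0,
            "source": f.source,
            "categories": [c.value for c in f.categories],
        }
        if f.count_case is not None:
            entry["count_case"] = f.count_case
        if f.count_control is not None:
            entry["count_control"] = f.count_control
        features.append(entry)
    out: dict = {
        "features": features,
        "prior_case_percent": spec.prior_case * 100.0,
        "risk_threshold_percent": spec.risk_threshold * 100.0,
    }
    if spec.n_case is not None:
        out["n_case"] = spec.n_case
    if spec.n_control is not None:
        out["n_control"] = spec.n_control
    return out


def load_network_spec(path: str | Path, format: str | None = None) -> NetworkSpec:
    """Load and validate a network definition from a YAML or JSON file."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "yaml"
    if format not in ("yaml", "json"):
        raise ValueError(f"format must be 'yaml' or 'json', got {format!r}")
    text = path.read_text()
    data = json.loads(text) if format == "json" else yaml.safe_load(text)
    return spec_from_mapping(data)


def write_network_spec(spec: NetworkSpec, path: str | Path, format: str | None = None) -> None:
    """Write a network definition in the percent-scaled file dialect."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "yaml"
    data = spec_to_mapping(spec)
    if format == "json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


_BUILTIN_FILES = {
    "table2": "table2.yaml",
    "example36": "example36_synthetic.yaml",
}

def builtin_spec_names() -> tuple[str, ...]:
    return tuple(_BUILTIN_FILES)

def load_builtin_spec(name: str) -> NetworkSpec:
    """Load a packaged network definition ("table2" or "example36")."""
    try:
        filename = _BUILTIN_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin spec {name!r}; available: {sorted(_BUILTIN_FILES)}"
        ) from None
    text = resources.files("piprob.data").joinpath(filename).read_text()
    return spec_from_mapping(yaml.safe_load(text))


def sort_categories_by_score(
    scores: Mapping[IUISCategory, float]
) -> list[IUISCategory]:
    """Categories in descending score order, ties by canonical order."""
    return sorted(scores, key=lambda c: (-scores[c], CANONICAL_RANK[c]))
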