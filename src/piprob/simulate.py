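"""Synthetic cohort simulator.

Generates labelled patients as independent Bernoulli feature vectors at the
network's own class-conditional prevalences — deliberately matching the
model's conditional-independence assumption, which is the correct null for
testing the engine (and is why simulated discrimination exceeds what the
same network achieves on real, correlated EHR data).  Optionally the
simulator emits a dated ICD-10 cohort extract: each present feature emits
one of its codes on a random in-window date, and case patients additionally
receive two cohort-qualifying marker codes on distinct dates so the case
selector re-identifies them.

Randomness comes from :func:`numpy.random.default_rng` (PCG64), a named
stable generator; the seed is a required config field.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd

from .network import NetworkSpec, PatientEvidence

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_patient", "simulate_cohort"]

#: ICD-10 codes stamped on simulated case patients so the two-codes/two-dates
#: inclusion rule re-identifies them (D84.9: immunodeficiency, unspecified).
DEFAULT_PI_MARKER_CODES: tuple[str, ...] = ("D84.9",)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Reproducible cohort-simulation settings.

    Defaults mirror the study cohorts: 1762 cases and 1698 controls.
    """

    n_case: int = 1762
    n_control: int = 1698
    seed: int = 0
    emit_codes: bool = False
    dates_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2015, 1, 1),
        datetime.date(2016, 12, 31),
    )
    pi_marker_codes: tuple[str, ...] = DEFAULT_PI_MARKER_CODES

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("n_case and n_control must be positive")
        if self.dates_window[0] >= self.dates_window[1]:
            raise ValueError("dates_window start must precede end")


@dataclasses.dataclass(frozen=True)
class SimulatedCohort:
    """Simulation output: presence matrix, labels, optional dated extract."""

    presence: pd.DataFrame          # patient x feature booleans
    labels: pd.Series               # patient -> {"case", "control"}
    extract: pd.DataFrame | None    # dated ICD-10 records when emit_codes

    def evidence(self) -> list[PatientEvidence]:
        cols = np.asarray(self.presence.columns, dtype=object)
        return [
            PatientEvidence(frozenset(cols[row.to_numpy(dtype=bool)]), patient_id=pid)
            for pid, row in self.presence.iterrows()
        ]


def simulate_patient(
    label: str, spec: NetworkSpec, rng: np.random.Generator
) -> PatientEvidence:
    """One patient: each feature present independently at its class prevalence."""
    if label not in ("case", "control"):
        raise ValueError(f"label must be 'case' or 'control', got {label!r}")
    p = np.array(
        [f.p_given_case if label == "case" else f.p_given_control for f in spec.features]
    )
    present = rng.random(p.size) < p
    names = np.asarray(spec.feature_names, dtype=object)
    return PatientEvidence(frozenset(names[present]))


def _random_dates(
    rng: np.random.Generator, window: tuple[datetime.date, datetime.date], size: int
) -> list[datetime.date]:
    span = (window[1] - window[0]).days + 1
    offsets = rng.integers(0, span, size=size)
    return [window[0] + datetime.timedelta(days=int(d)) for d in offsets]


def simulate_cohort(config: SimulationConfig, spec: NetworkSpec) -> SimulatedCohort:
    """Simulate the full labelled cohort described by *config*.

    Output contains exactly ``n_case`` cases followed by ``n_control``
    controls, with unique patient ids; identical configs give identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_case + config.n_control
    ids = [f"P{i:06d}" for i in range(n_total)]
    labels = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control,
        index=pd.Index(ids, name="patient_id"),
        name="cohort",
    )
    p_case = np.array([f.p_given_case for f in spec.features])
    p_control = np.array([f.p_given_control for f in spec.features])
    draws = rng.random((n_total, p_case.size))
    presence = np.where(
        (labels == "case").to_numpy()[:, None], draws < p_case, draws < p_control
    )
    X = pd.DataFrame(presence, index=labels.index, columns=list(spec.feature_names))

    extract = None
    if config.emit_codes:
        records: list[tuple[str, str, str, datetime.date]] = []
        code_choices = {f.name: list(f.icd_codes) for f in spec.features}
        for pid, row in X.iterrows():
            cohort = labels.loc[pid]
            present_names = [name for name, hit in row.items() if hit]
            dates = _random_dates(rng, config.dates_window, len(present_names))
            for name, date in zip(present_names, dates):
                codes = code_choices[name]
                code = codes[int(rng.integers(len(codes)))] if codes else name
                records.append((pid, cohort, code, date))
            if cohort == "case":
                # two qualifying codes on guaranteed-distinct dates
                d1 = _random_dates(rng, config.dates_window, 1)[0]
                d2 = d1 + datetime.timedelta(days=1)
                if d2 > config.dates_window[1]:
                    d2 = d1 - datetime.timedelta(days=1)
                for d in (d1, d2):
                    code = config.pi_marker_codes[
                        int(rng.integers(len(config.pi_marker_codes)))
                    ]
                    records.append((pid, cohort, code, d))
        extract = pd.DataFrame(
            records, columns=["patient_id", "cohort", "icd_code", "date"]
        )
    return SimulatedCohort(presence=X, labels=labels, extract=extract)
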