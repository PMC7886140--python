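"""Cohort selection and conditional-probability-table estimation."""

import numpy as np
import pandas as pd
import pytest

from piprob import (
    build_feature_table,
    compute_weight,
    estimate_conditional_probability,
    select_case_cohort,
)
from piprob.learning import (
    learn_spec,
    presence_matrix,
    read_cohort_extract,
    validate_cohort_extract,
)
from piprob.network import ZERO_COUNT_FLOOR


def extract_frame(rows):
    return validate_cohort_extract(
        pd.DataFrame(rows, columns=["patient_id", "cohort", "icd_code", "date"])
    )


# -- conditional probability ------------------------------------------------

@pytest.mark.parametrize(
    "count, n, expected",
    [
        (113, 1762, 113 / 1762),   # displays as 6.4%
        (246, 1762, 246 / 1762),   # displays as 14.0%
        (0, 1698, ZERO_COUNT_FLOOR),
        (1, 1, None),              # saturation, handled below
    ],
)
def test_estimate_conditional_probability(count, n, expected):
    if count == n:
        with pytest.warns(UserWarning, match="saturates"):
            assert estimate_conditional_probability(count, n) == 1.0
    else:
        assert estimate_conditional_probability(count, n) == pytest.approx(
            expected, abs=1e-15
        )


@pytest.mark.parametrize("count, n", [(5, 4), (-1, 10), (0, 0)])
def test_estimate_conditional_probability_domain_errors(count, n):
    with pytest.raises(ValueError):
        estimate_conditional_probability(count, n)


# -- weight -----------------------------------------------------------------

def test_weight_unrounded_fractions():
    w = compute_weight(113 / 1762, 3 / 1698)
    assert w == pytest.approx(36.30, abs=0.01)
    assert round(w) == 36


def test_weight_identity_and_errors():
    assert compute_weight(0.25, 0.25) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compute_weight(0.0, 0.1)
    with pytest.raises(ValueError):
        compute_weight(0.1, -0.1)
    with pytest.raises(ValueError):
        compute_weight(0.1, 0.1, convention="bogus")


def test_weight_rounded_percent_convention_reproduces_zero_count_row():
    # 39/1762 rounds to 2.2%; divided by the 0.0001% floor gives 22000
    w = compute_weight(39 / 1762, ZERO_COUNT_FLOOR, convention="rounded_percent")
    assert w == pytest.approx(22000.0)


# -- case-cohort selection --------------------------------------------------

PI = ["D80.0"]

def test_case_selection_requires_two_codes_on_distinct_dates():
    extract = extract_frame(
        [
            ("included", "case", "D80.0", "2015-01-02"),
            ("included", "case", "D80.0", "2016-03-04"),
            ("same_day", "case", "D80.0", "2015-01-02"),
            ("same_day", "case", "D80.0", "2015-01-02"),
            ("only_one", "case", "D80.0", "2015-01-02"),
            ("ctrl", "control", "J06.9", "2015-01-02"),
        ]
    )
    assert select_case_cohort(extract, PI) == {"included"}


def test_case_selection_applies_exclusion_codes():
    extract = extract_frame(
        [
            ("kept", "case", "D80.0", "2015-01-02"),
            ("kept", "case", "D80.0", "2016-03-04"),
            ("scid", "case", "D80.0", "2015-01-02"),
            ("scid", "case", "D80.0", "2016-03-04"),
            ("scid", "case", "D81.1", "2016-05-01"),
            ("secondary", "case", "D80.0", "2015-01-02"),
            ("secondary", "case", "D80.0", "2016-03-04"),
            ("secondary", "case", "B20", "2016-05-01"),
        ]
    )
    assert select_case_cohort(extract, PI) == {"kept"}
    # exclusions are configurable
    assert select_case_cohort(extract, PI, scid_codes=(), secondary_codes=()) == {
        "kept", "scid", "secondary",
    }


def test_case_selection_rejects_empty_pattern_set():
    extract = extract_frame([("p", "case", "D80.0", "2015-01-02")])
    with pytest.raises(ValueError, match="pi_codes"):
        select_case_cohort(extract, [])


def test_extract_validation_rejects_patients_in_both_cohorts():
    with pytest.raises(ValueError, match="both cohort"):
        extract_frame(
            [("p1", "case", "D80.0", "2015-01-02"), ("p1", "control", "J06", "2015-01-03")]
        )


# -- feature table ----------------------------------------------------------

def synthetic_extract(n_case, n_control, carriers_case, carriers_control, code):
    """Extract where the first k patients of each cohort carry `code`."""
    rows = []
    for i in range(n_case):
        rows.append((f"case{i:05d}", "case", "D80.0", "2015-01-01"))
        if i < carriers_case:
            rows.append((f"case{i:05d}", "case", code, "2015-06-01"))
    for i in range(n_control):
        rows.append((f"ctrl{i:05d}", "control", "J06.9", "2015-01-01"))
        if i < carriers_control:
            rows.append((f"ctrl{i:05d}", "control", code, "2015-06-01"))
    return extract_frame(rows)


def test_feature_table_reproduces_published_lymphopenia_row(table2_spec):
    extract = synthetic_extract(1762, 1698, 113, 3, "D72.810")
    table = build_feature_table(extract, table2_spec)
    row = next(e for e in table if e.feature_name == "lymphopenia")
    assert (row.count_case, row.count_control) == (113, 3)
    assert row.p_case == pytest.approx(
        estimate_conditional_probability(113, 1762), abs=1e-15
    )
    assert round(row.weight) == 36


def test_feature_table_zero_control_carriers_hit_the_floor(table2_spec):
    extract = synthetic_extract(50, 50, 5, 0, "D72.810")
    table = build_feature_table(extract, table2_spec)
    row = next(e for e in table if e.feature_name == "lymphopenia")
    assert row.p_control == ZERO_COUNT_FLOOR


def test_patient_level_deduplication(table2_spec):
    extract = synthetic_extract(40, 40, 7, 2, "D70")
    doubled = validate_cohort_extract(
        pd.concat([extract, extract], ignore_index=True)
    )
    assert build_feature_table(extract, table2_spec) == build_feature_table(
        doubled, table2_spec
    )


def test_feature_table_is_a_sorted_permutation(table2_spec):
    extract = synthetic_extract(60, 60, 10, 1, "D72.810")
    table = build_feature_table(extract, table2_spec)
    assert {e.feature_name for e in table} == set(table2_spec.feature_names)
    weights = [e.weight for e in table]
    assert weights == sorted(weights, reverse=True)


def test_empty_extract_is_an_error(table2_spec):
    with pytest.raises(ValueError, match="empty"):
        build_feature_table(pd.DataFrame(columns=["patient_id", "cohort", "icd_code", "date"]), table2_spec)


def test_presence_matrix_counts_each_patient_once(table2_spec):
    extract = extract_frame(
        [
            ("p1", "case", "D70", "2015-01-01"),
            ("p1", "case", "D70", "2015-02-01"),  # repeat code, same feature
            ("p2", "control", "J06.9", "2015-01-01"),
        ]
    )
    X, labels = presence_matrix(extract, table2_spec)
    assert X.loc["p1", "neutropenia"] == True  # noqa: E712
    assert X.loc["p1"].sum() == 1
    assert labels.to_dict() == {"p1": "case", "p2": "control"}


def test_learn_spec_updates_probabilities_but_keeps_literature_nodes(table2_spec):
    extract = synthetic_extract(100, 100, 20, 2, "D72.810")
    learned = learn_spec(extract, table2_spec)
    assert learned.feature("lymphopenia").p_given_case == pytest.approx(0.2)
    assert learned.feature("lymphopenia").p_given_control == pytest.approx(0.02)
    assert learned.n_case == 100 and learned.n_control == 100
    # no literature node in table2; check on the 36-node spec instead
    from piprob import load_builtin_spec

    spec36 = load_builtin_spec("example36")
    learned36 = learn_spec(extract_to_36(extract), spec36)
    men = spec36.feature("meningococcal_disease")
    assert learned36.feature("meningococcal_disease").p_given_case == men.p_given_case


def extract_to_36(extract):
    return extract


def test_roundtrip_csv(tmp_path, table2_spec):
    extract = synthetic_extract(10, 10, 3, 1, "D70")
    path = tmp_path / "extract.csv"
    from piprob.learning import write_cohort_extract

    write_cohort_extract(extract, path)
    back = read_cohort_extract(path)
    assert len(back) == len(extract)
    assert set(back["patient_id"]) == set(extract["patient_id"])
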