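# piprob

Bayesian-network screening for **primary immunodeficiency (PI)** — inherited
disorders of immune function that present with recurrent or unusual
infections and are routinely diagnosed 7–9 years late. `piprob` is aimed at
clinical informaticians and immunology researchers who want a transparent,
probability-based risk screen over routinely coded EHR data: it learns
feature conditional-probability tables (CPTs) from ICD-10-coded case/control
cohorts, computes each patient's posterior risk of PI, and ranks the most
likely IUIS diagnostic categories as a prescriptive starting point for the
work-up. A synthetic-cohort simulator and an evaluation harness make every
stage runnable and testable without patient data.

## The model

The network is a binary risk node *A* (PI vs. not-PI) with population prior
*P(A)* = 1%, connected to a bank of Bernoulli feature nodes *B₁…Bₙ*
(lymphopenia, sepsis, neutropenia, …), each defined by a set of ICD-10 codes
and two class-conditional prevalences learned as carrier fractions:

    P(Bᵢ | A)  = (carriers among cases) / n_cases
    P(Bᵢ | ¬A) = (carriers among controls) / n_controls

with zero counts replaced by a 0.0001 % floor so no likelihood is exactly 0.
Features a patient *has* are instantiated "present"; an absent feature is
**unobserved**, not evidence of absence. Under conditional independence,

    P(A | B₁,…,Bₙ) = P(A) ∏ᵢ P(Bᵢ|A) / [ P(A) ∏ᵢ P(Bᵢ|A) + P(¬A) ∏ᵢ P(Bᵢ|¬A) ]

over the present features only (products accumulated in log space). A risk
≥ 5.5 % classifies the patient *med-high risk*. Each feature also arcs into
one or more of the seven IUIS categories (T/CID, PAD, PIRD, PD, ID, AID,
CD); a category's score is the sum of *P(Bᵢ|A)* over present features arcing
into it, and the top-2 categories are the prescriptive output. Features are
ranked by **weight** = *P(Bᵢ|A) / P(Bᵢ|¬A)*.

The core lives in a scikit-learn-style estimator, `BayesRiskScreen`
(`fit(X, y)` on a binary presence matrix, `predict_proba` / `predict`), and
composes with sklearn tooling; the module-level functions
(`posterior_risk`, `score_patient`, `build_feature_table`, …) are thin
wrappers over it.

## Worked example

Score a patient carrying lymphopenia (D72.810) and neutropenia (D70) codes
against the packaged 20-feature network (`table2`, learned from a cohort of
1762 PI cases and 1698 controls):

```sh
$ piprob score --codes-inline "D72.810,D70,Z99.99"
posterior risk : 82.84%
classification : med_high_risk
IUIS category guidance:
  PD       68.5% ########################### <- top 2
  T/CID    31.5% ############# <- top 2
  PAD       0.0%
  ...
unmatched codes: Z99.99
```

Reading: the two haematological features multiply the 1 % prior up to an
82.84 % posterior — far above the 5.5 % screening threshold — and the
category guidance suggests starting the work-up with phagocyte disorders
(neutropenia) and T-cell/combined defects (lymphopenia). `Z99.99` matches no
feature node and is reported, not dropped. The same result is available in
JSON (`--json`) for EHR/API consumption, and from Python via
`piprob.score_patient({"D72.810", "D70"}, spec)`.

The full pipeline — simulate a labelled cohort, learn CPTs from the dated
ICD-10 extract, score a patient, evaluate ROC/threshold performance — runs
end-to-end with:

```sh
$ piprob demo --seed 7
demo: AUROC 0.560, best cutoff 1.14%, example patient risk 99.90% (med_high_risk)
wrote piprob_demo/
```

(Synthetic cohorts drawn from the sparse 20-feature network alone carry far
less evidence per patient than chart-reviewed validation data, hence the
modest AUROC at these settings; see `docs/methods.md`.)

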