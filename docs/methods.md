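# Methods

## Model and assumptions

`piprob` implements a two-layer Bayesian network for rare-disease screening:
a binary risk node (primary immunodeficiency, PI) and a bank of Bernoulli
feature nodes that are assumed conditionally independent given the risk
state. Scoring is naive-Bayes with **present-only instantiation**: the
posterior is the prior updated by the likelihood ratio of the *instantiated*
features only. A feature a patient does not carry is treated as unobserved
— it is marginalised away, which under conditional independence means its
terms cancel and it contributes nothing. This mirrors how a clinician
enters findings: the absence of a code in an EHR is weak evidence of the
absence of the finding. A strict two-state mode
(`evidence_mode="two_state"`), in which absence contributes a (1−p) term, is
available for comparison and is what classical Bernoulli naive Bayes does.

Likelihood products are accumulated in log space (`scipy.special.logsumexp`
for normalisation), so hundreds of weak features cannot underflow; empty
evidence short-circuits to return the prior bit-exactly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `prior_case` | 0.01 | population prior P(PI); ~1 % of a general paediatric population shows features of PI risk |
| `risk_threshold` | 0.055 | posterior at/above which a patient is `med_high_risk` (inclusive ≥); 0.06 is the documented clinical-guidance alternative |
| `floor` | 1e-6 | probability substituted for a zero-count cohort cell (0.0001 %), keeping every likelihood strictly positive |
| `evidence_mode` | `present_only` | see above |

Threshold inclusivity is genuinely ambiguous in screening practice ("> 5.5 %"
vs "≥ 6 %"); we adopt inclusive ≥ with the value configurable, which makes
the boundary case screen-positive — the sensitive choice for a screening
tool.

## CPT learning

Conditional probabilities are carrier fractions: a patient counts **once**
per feature regardless of how many matching codes they accumulate, because
the quantity modelled is a prevalence (fraction of individuals), not a code
rate. Case-cohort inclusion requires ≥ 2 qualifying codes on ≥ 2 distinct
calendar dates (one coded mention is too often rule-out or mis-entry);
SCID and secondary-immunodeficiency codes exclude a patient from the case
side only. The exclusion code sets default to D81.0–D81.2 and B20/D84.81
and are configurable, as the canonical lists are institution-specific.

ICD-10 matching is dot-insensitive, case-insensitive prefix matching: a
3-character family pattern ("A41") matches all its children ("A41.9"), an
exact code matches itself, and trailing lower-case `x` characters in a
pattern ("A39.xx") are wildcard markers (upper-case `X` is a literal ICD-10
placeholder, as in T45.1X5A). Prefix semantics were chosen because
published code lists freely mix exact codes and families.

The feature-ranking **weight** is the ratio of the unrounded carrier
fractions (canonical). A second convention, `rounded_percent`, divides the
percentages after rounding each to one decimal, keeping sub-resolution
values such as the floor unrounded; it exists because printed clinical
tables round before dividing, and it is the only convention under which
zero-count rows (e.g. a 2.2 % prevalence over the 0.0001 % floor → 22000)
reproduce. Four of the twenty packaged feature rows have printed weights
that reproduce under neither convention (off by one rounding step or by a
few counts); the engine always reports the unrounded ratio as canonical.

## Packaged networks

`table2` packages the 20 highest-weight feature nodes with probabilities
recomputed exactly from their published carrier counts. Two nodes print no
code list, so the standard ICD-10 families were assigned (SLE → M32,
superficial mycosis → B35/B36). The meningococcal-disease node is
literature-sourced: its case-side risk proxy is 0.0001 % with a control
value of 1e-7 % (reproducing its published weight of 1000); both are
ordinary spec-file fields and can be overridden. The feature→IUIS arc map
is not published in machine-readable form; the packaged arcs are this
package's own domain-plausible defaults (e.g. neutropenia → PD,
lymphopenia → T/CID, hypocalcemia → T/CID for the DiGeorge phenotype) and
should be replaced by locally validated arcs for any clinical use.
`example36` (`example36_synthetic.yaml`) pads the network to its full
36-node composition (10 history/physical, 5 laboratory, 5 general
infection, 16 informative infection/condition); apart from abscess, whose
3.7 % / 1.5 % prevalences are published, the 15 padding nodes carry
clearly-labelled synthetic placeholder probabilities.

## IUIS category ranking

A category's score is Σ P(feature | PI) over present features arcing into
it — a heuristic evidence tally, not a calibrated posterior, which is why
scores are reported both raw and normalised to sum to one and why the
magnitude of change from baseline matters more than the absolute figure.
Ranking uses the raw sums; all ties (and the top-2 selection) break by the
fixed canonical category order T/CID, PAD, PIRD, PD, ID, AID, CD. If no
present feature carries an arc the prediction is degenerate: all seven
categories score equally, the flag is set, and such patients are excluded
from top-2 accuracy denominators as unscorable.

## Synthetic cohorts

The simulator draws each patient's features as independent Bernoullis at
the network's own class-conditional prevalences — deliberately matching the
model's independence assumption. That is the correct null for verifying
the engine (parameter recovery, ranking arithmetic, threshold behaviour),
but it means passing tests say nothing about performance on real EHR data,
where features are correlated, coding is incomplete, and discrimination is
lower for the same network. Conversely, cohorts drawn from only the 20
sparse packaged nodes carry *less* evidence per patient than chart-reviewed
validation data (mean control feature burden ≈ 0.05), so simulated AUROC at
the demo settings is modest; the published validation AUROC of 0.945 was
measured on real chart-reviewed patients with the full 36-node network and
is not recomputable here. Randomness uses `numpy.random.default_rng`
(PCG64) with a mandatory seed; identical configs give byte-identical
outputs. When a dated extract is emitted, case patients receive two
marker codes (D84.9) on distinct dates so the cohort selector re-identifies
them exactly.

## Evaluation

AUROC is the Mann–Whitney statistic — P(case score > control score) + ½
P(tie) via average ranks — which equals the trapezoidal area under the
tie-aware ROC and is verified against an all-pairs oracle and
scikit-learn's `roc_auc_score` in the tests. The operating cutoff maximises
Youden's J over midpoints of adjacent distinct scores, breaking ties toward
the lower (more sensitive) threshold; with all scores tied there is no
informative cutoff and the single value is returned with a warning.
Degenerate inputs are surfaced, not silenced: no positive predictions →
precision is NaN with a warning; single-class label vectors are errors.

## Verification problem sizes

The test suite and acceptance script run at desk scale by design: the
posterior is cross-checked against full joint-table enumeration on ≥ 1000
random networks of up to 12 features; parameter recovery simulates 20
cohorts at the study sizes (1762 cases / 1698 controls) and requires ≥ 95 %
of feature cells inside exact binomial 99 % acceptance intervals; the
published feature-table arithmetic is reproduced row by row from the
printed counts. The full suite completes in a few seconds.

## Known limitations

- Arc structure is fixed, not learned; inter-feature dependence is not
  modelled.
- Category scores are uncalibrated tallies; top-2 accuracy on synthetic
  data depends on the packaged (unofficial) arc map.
- The simulator does not model age/sex/ethnicity structure, longitudinal
  code trajectories, or comorbidity correlation.
- Weight display conventions cannot reproduce every printed value of the
  source table (four rows are internally inconsistent); the unrounded ratio
  is canonical.
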