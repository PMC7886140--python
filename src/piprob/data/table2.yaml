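# Packaged "table2" network: the top-20 features of the published model,
# class-conditional prevalences recomputed exactly from the printed carrier
# counts (case n=1762, control n=1698); zero-count control cells use the
# 0.0001% floor.  The feature->IUIS category arcs are package defaults chosen
# by domain plausibility (the published arc map is not reproduced in the
# article text).  Probabilities are percentages in this dialect.
features:
- name: systemic_lupus_erythematosus
  description: Systemic lupus erythematosus
  icd_codes:
  - M32
  p_case_percent: 2.213393870601589
  p_control_percent: 0.0001
  source: cohort_learned
  categories:
  - PIRD
  - AID
  count_case: 39
  count_control: 0
- name: eosinophilia
  description: Eosinophilia
  icd_codes:
  - D72.1
  p_case_percent: 1.9863791146424516
  p_control_percent: 0.0001
  source: cohort_learned
  categories:
  - PIRD
  - T/CID
  count_case: 35
  count_control: 0
- name: autoimmune_hemolytic_anemia
  description: Auto-immune hemolytic anemia
  icd_codes:
  - D59.1
  p_case_percent: 1.8161180476730987
  p_control_percent: 0.0001
  source: cohort_learned
  categories:
  - PIRD
  - PAD
  count_case: 32
  count_control: 0
- name: meningococcal_disease
  description: Meningococcal disease (literature-derived risk; complement-inhibitor therapy as surrogate
    in cases)
  icd_codes:
  - A39.xx
  p_case_percent: 0.0001
  p_control_percent: 1.0e-07
  source: literature
  categories:
  - CD
- name: lymphopenia
  description: Lymphopenia
  icd_codes:
  - D72.810
  p_case_percent: 6.413166855845629
  p_control_percent: 0.17667844522968199
  source: cohort_learned
  categories:
  - T/CID
  count_case: 113
  count_control: 3
- name: hypocalcemia
  description: Hypocalcemia
  icd_codes:
  - E83.51
  p_case_percent: 2.7809307604994324
  p_control_percent: 0.17667844522968199
  source: cohort_learned
  categories:
  - T/CID
  count_case: 49
  count_control: 3
- name: superficial_mycosis
  description: Superficial mycosis
  icd_codes:
  - B35
  - B36
  p_case_percent: 0.9080590238365494
  p_control_percent: 0.058892815076560655
  source: cohort_learned
  categories:
  - T/CID
  - ID
  count_case: 16
  count_control: 1
- name: neutropenia
  description: Neutropenia
  icd_codes:
  - D70
  p_case_percent: 13.961407491486947
  p_control_percent: 1.0600706713780919
  source: cohort_learned
  categories:
  - PD
  count_case: 246
  count_control: 18
- name: opportunistic_infections
  description: Opportunistic infections
  icd_codes:
  - A02
  - A31
  - B39
  - B55
  - B40
  - B59
  p_case_percent: 1.4755959137343928
  p_control_percent: 0.11778563015312131
  source: cohort_learned
  categories:
  - T/CID
  - PD
  count_case: 26
  count_control: 2
- name: polyarthritis
  description: Polyarthritis
  icd_codes:
  - M00
  - M13
  p_case_percent: 0.7377979568671964
  p_control_percent: 0.058892815076560655
  source: cohort_learned
  categories:
  - PAD
  - AID
  count_case: 13
  count_control: 1
- name: sepsis
  description: Sepsis
  icd_codes:
  - A40
  - A41
  - O85
  - P36
  p_case_percent: 5.902383654937571
  p_control_percent: 0.5300353356890459
  source: cohort_learned
  categories:
  - PAD
  - ID
  count_case: 104
  count_control: 9
- name: lymphoma
  description: Lymphoma
  icd_codes:
  - C81
  - C82
  - C83
  - C84
  - C85
  - C86
  - C88
  p_case_percent: 1.3053348467650396
  p_control_percent: 0.11778563015312131
  source: cohort_learned
  categories:
  - PIRD
  - T/CID
  count_case: 23
  count_control: 2
- name: thrombocytopenia
  description: Thrombocytopenia
  icd_codes:
  - D69.59
  - T45.1X5A
  p_case_percent: 4.256526674233825
  p_control_percent: 0.4122497055359246
  source: cohort_learned
  categories:
  - PIRD
  - T/CID
  count_case: 75
  count_control: 7
- name: septic_shock
  description: Septic shock
  icd_codes:
  - A41.9
  - R65.21
  p_case_percent: 5.391600454029512
  p_control_percent: 0.5300353356890459
  source: cohort_learned
  categories:
  - ID
  - PAD
  count_case: 95
  count_control: 9
- name: recurrent_fever
  description: Recurrent fever
  icd_codes:
  - A68
  p_case_percent: 1.70261066969353
  p_control_percent: 0.17667844522968199
  source: cohort_learned
  categories:
  - AID
  count_case: 30
  count_control: 3
- name: herpes_infections
  description: Herpesvirus infections
  icd_codes:
  - A60
  - B00
  - B02
  - B10
  - B27
  p_case_percent: 5.675368898978434
  p_control_percent: 0.88339222614841
  source: cohort_learned
  categories:
  - T/CID
  - ID
  count_case: 100
  count_control: 15
- name: encephalitis
  description: Encephalitis
  icd_codes:
  - A83
  - A84
  - A85
  - A86
  - G04
  p_case_percent: 0.5675368898978433
  p_control_percent: 0.11778563015312131
  source: cohort_learned
  categories:
  - ID
  - T/CID
  count_case: 10
  count_control: 2
- name: fibrosis
  description: Hepatic fibrosis
  icd_codes:
  - K74
  p_case_percent: 0.340522133938706
  p_control_percent: 0.058892815076560655
  source: cohort_learned
  categories:
  - PD
  count_case: 6
  count_control: 1
- name: organomegaly
  description: Organomegaly (hepatosplenomegaly)
  icd_codes:
  - R16
  p_case_percent: 2.837684449489217
  p_control_percent: 0.47114252061248524
  source: cohort_learned
  categories:
  - PIRD
  - PD
  count_case: 50
  count_control: 8
- name: mycobacterial_disease
  description: Mycobacterial disease
  icd_codes:
  - A31.9
  p_case_percent: 0.5675368898978433
  p_control_percent: 0.11778563015312131
  source: cohort_learned
  categories:
  - PD
  - ID
  count_case: 10
  count_control: 2
prior_case_percent: 1.0
risk_threshold_percent: 5.5
n_case: 1762
n_control: 1698
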