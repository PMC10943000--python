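# hdpheno

Rule-based phenotyping of **hypertensive disorders of pregnancy (HDP)**
from longitudinal cohort records.

Large prospective pregnancy cohorts transcribe prenatal care into tabular
records — an interview at the first visit, repeated checkups with blood
pressure (BP) and urine-dipstick proteinuria (PU), short clinical notes,
and a delivery record — but rarely have linked EHR diagnoses. `hdpheno`
classifies each pregnancy into the HDP subtypes from those records alone,
with two configurable rule engines:

* **Algorithm 1** (American/ACOG concepts): hypertensive disease history,
  BP, PU, timing of onset, and PE-related clinical conditions
  (severe-feature labs plus note-mined new-onset headache, visual
  disturbance, pulmonary edema).
* **Algorithm 2** (Japanese/JSOG concepts): algorithm 1 plus upgrade paths
  for hypertensive subjects *without* proteinuria — maternal organ
  dysfunction (epigastralgia, HELLP syndrome, eclampsia, FGR, renal or
  hepatic dysfunction, mined from notes) or a light-for-date infant
  upgrades GH → PE and CH → SPE.

Labels form an 8-way partition: `GH_EO, GH_LO, SPE_EO, SPE_LO, PE_EO,
PE_LO, CH, NT` — gestational hypertension, superimposed preeclampsia and
preeclampsia split into early/late onset (onset < 34 weeks vs ≥ 34 weeks),
plus chronic hypertension and normotensive.

The core longitudinal predicates, with guideline-default cutoffs (all
configurable via `Thresholds`):

* hypertension onset: first visit with SBP ≥ 140 or DBP ≥ 90 mmHg;
  onset < 20 weeks (140 days) or a positive history ⇒ chronic hypertension
  status;
* proteinuria onset: first day with dipstick ≥ 2+ once, or ≥ 1+ at two
  visits; a pattern completing **before** 20 weeks flags early proteinuria
  (a chronic-kidney-disease-style confounder) and disables the PU channel;
* PE-related labs: platelets < 100×10³/µL, creatinine > 1.1 mg/dL,
  transaminases > 2× ULN — missing labs never fire;
* light-for-date: birth weight strictly below the 10th percentile for
  gestational week and sex (CSV reference table; a synthetic one ships
  with the package).

A validation module compares phenotyped labels to a reference-standard
(chart-review) label file and produces PPV / NPV / accuracy / sensitivity /
specificity per subgroup, with not-applicable handling for empty strata.
A synthetic-cohort generator produces realistic visit schedules, BP and
dipstick trajectories, bilingual note snippets and delivery outcomes with
ground-truth labels, so the whole pipeline is testable without any data
download.

## Worked example

```bash
hdpheno simulate --out demo --n 120 --seed 5
hdpheno phenotype --data demo --out demo_pheno --algorithm both
```

prints (algorithm 1):

```
       group  eo_count  eo_pct  lo_count  lo_pct  count    pct
          GH       4.0    3.33       4.0    3.33      8   6.67
         SPE       1.0    0.83       2.0    1.67      3   2.50
          PE       1.0    0.83       0.0    0.00      1   0.83
          CH       NaN     NaN       NaN     NaN      1   0.83
Normotensive       NaN     NaN       NaN     NaN    107  89.17
       Total       NaN     NaN       NaN     NaN    120 100.00
```

— 13 of 120 simulated pregnancies are hypertensive: 8 gestational
hypertension (4 early-onset), 1 preeclampsia, 3 superimposed preeclampsia,
1 chronic hypertension; percentages are of the included cohort, rounded
half-up to two decimals. `demo_pheno/` also contains per-subject labels
(`labels_algorithm*.csv`), the fired-rule evidence trail
(`evidence_algorithm*.json`), the algorithm-1 × algorithm-2 cross-table and
discordant-subject list, and a run manifest.

Validating the phenotyped labels against the generator's truth:

```bash
hdpheno validate --pred demo_pheno/labels_algorithm1.csv \
                 --truth demo/truth.csv --out demo_val
```

writes the 12-row metric table (HDP, GH, GH EO, GH LO, SPE, …, CH, NT);
strata with no positive subjects show `-` (not applicable).

As a library:

```python
from hdpheno import SimConfig, generate, phenotype_cohort, truth_label, label_recovery

bundles, truths = generate(SimConfig(n_subjects=2000, seed=0, emission_noise=0.0))
results = phenotype_cohort(bundles, algorithm=2)
truth = {t.subject_id: truth_label(t) for t in truths}
print(label_recovery(results, truth))   # 1.0 on a noise-free cohort
```

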