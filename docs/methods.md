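# Methods

## The phenotyping model

Each pregnancy is a `SubjectBundle`: an interview history flag, an ordered
series of prenatal visits (gestational age in days since the last
menstrual period, systolic/diastolic blood pressure, ordinal urine-protein
dipstick grade, optional labs), free-text clinical notes, and a delivery
record. Week *W* maps to days [7*W*, 7*W*+7); "before 20 weeks" means
< 140 days.

Two deterministic rule engines assign exactly one of eight labels
(`GH_EO, GH_LO, SPE_EO, SPE_LO, PE_EO, PE_LO, CH, NT`). Both share the
longitudinal predicates:

* **Hypertension onset** — the first visit with SBP ≥ `sbp_cut` (140) or
  DBP ≥ `dbp_cut` (90), cuts inclusive. A single qualifying visit suffices
  by default: visit spacing in cohort data rarely supports the
  re-measurement clause of clinic diagnosis, so requiring confirmation
  would systematically miss onsets; `htn_required_visits` makes the
  stricter behaviour available.
* **Chronic-hypertension status** — positive hypertensive-disease history
  (interview OR note-mined, OR-combined because history reaches the record
  by self-report as well as by note) or measured onset before
  `ch_boundary` (140 days).
* **Proteinuria onset** — first day with a single dipstick ≥
  `pu_single_grade` (2+) or with ≥ `pu_repeat_grade` (1+) at
  `pu_repeat_count` (2) distinct visits (the day of the last). A pattern
  completing before `ch_boundary` marks *early proteinuria* and disables
  the proteinuria channel for the whole pregnancy — early dipstick
  positivity is typically renal (CKD-spectrum) rather than placental, and
  counting it would overestimate preeclampsia. The subject remains
  eligible for GH/CH, and for PE/SPE via clinical conditions; only the PU
  criterion is suppressed.
* **PE-related conditions** — lab-based: platelets < `platelet_low` (100
  ×10³/µL, strict <), creatinine > `creatinine_high` (1.1 mg/dL, strict
  >), AST/ALT > `transaminase_uln_multiplier` (2) × ULN (30/30 U/L);
  note-based: new-onset headache, visual disturbance, pulmonary edema at
  the earliest non-negated dated mention. A missing lab never fires a
  condition. Boundary directions follow the guideline wording each cutoff
  comes from.

**Algorithm 1** (American concepts): never hypertensive and not chronic →
`NT`; chronic status with new proteinuria (onset ≥ `ch_boundary`) or a
PE-related condition at/after the boundary → `SPE`, otherwise `CH`;
new-onset hypertension with such a trigger → `PE`, otherwise `GH`.

**Algorithm 2** (Japanese concepts): identical, plus upgrade paths for
hypertensive subjects without proteinuria: ≥ 1 maternal organ-dysfunction
flag (epigastralgia, HELLP syndrome, eclampsia, FGR, renal or hepatic
dysfunction) dated at/after `ch_boundary`, or a light-for-date infant,
relabels `GH → PE` and `CH → SPE`. Undated flag mentions do not qualify
(the timing requirement cannot be checked), a deliberately conservative
choice.

**Onset for the EO/LO split** is the first day on which the last of the
label's defining criteria is met: GH uses the hypertension onset; PE uses
min over qualifying paths of max(hypertension onset, trigger day); SPE —
hypertension being chronic, hence antecedent — uses the earliest
qualifying trigger. Early onset means onset < `eo_lo_cut` (238 days, 34
weeks; 32-week variants are a config change). Light-for-date carries no
date of its own: an LFD-only upgrade keeps the hypertension onset, and for
a chronic subject with no measured onset it falls back to the delivery day
(assessment happens at delivery), defaulting to late-onset when even that
is absent. CH and NT carry no timing suffix.

Postpartum disease is out of reach by construction: the records end at
delivery, so onsets that would only manifest intra-/postpartum are
systematically missed. This is a documented data-coverage limitation of
cohort phenotyping, not something the rules attempt to patch.

## Note mining

Literal-term matching over NFKC-normalized, casefolded, whitespace-
collapsed text; ASCII-edged terms get word-boundary lookarounds (so
"eclampsia" cannot fire inside "preeclampsia"), CJK terms match as
substrings. Longest term wins on overlap. Negation is fixed-window cue
matching: pre-positional cues within 10 characters before a hit, and
post-positional cues (Japanese "なし", "認めず"; English "ruled out")
within 10 characters after. The shipped bilingual lexicon is a small
editable seed — the engine, not the lexicon, is the stable contract, and
real deployments are expected to supply their site's term lists as YAML.

## Light-for-date reference

`data/lfd_reference_synthetic.csv` is a **synthetic** percentile table
(weeks 22–42 × sex × p3/p10/p50/p90/p97 in grams) generated from a
piecewise-linear mean-growth curve with sex scaling and a normal spread
model. It is adequate for exercising the strict-below-cutoff lookup and
for simulation; population analyses must load their national standard via
`load_lfd_table`.

## Synthetic cohort generator

`SimConfig` defaults define the study conditions: 2000 subjects; class
prevalences NT 0.8967, CH 0.0241, GH 0.0396, PE 0.0261, SPE 0.0135
(matching the ~8% HDP burden large pregnancy cohorts report, with the
remainder normotensive); early-onset fractions GH 0.40, PE 0.24, SPE 0.68;
the standard Japanese prenatal cadence (4-weekly to week 23, 2-weekly to
week 35, weekly to delivery); BP drawn per visit around state-dependent
means (112/68 baseline, 152/96 after onset, sd 8/6 mmHg — no
autocorrelation, which is sufficient to exercise threshold predicates);
dipstick misreads (trace 5%, 1+ 1% per visit); 1% of normotensive subjects
with a CKD-style early-proteinuria pattern; PE triggered by proteinuria
(75%) or by a condition (creatinine or headache note); SPE analogous;
delivery at ~38–39 weeks (earlier for hypertensive classes) with birth
weight drawn from the same growth model as the LFD table, below or above
the 10th-percentile cutoff according to the drawn LFD status.

Truth classes are defined under the **union** of both guideline concepts:
organ-dysfunction flags and light-for-date are emitted only for PE/SPE
subjects, so both engines can recover the truth labels — with
`emission_noise=0` recovery is exactly 1.0 and is asserted ≥ 0.99. The
`SimConfig.cross_guideline()` condition additionally gives GH/CH subjects
organ flags and LFD; there the engines genuinely diverge and the structural
properties are checked instead: discordances lie only on GH→PE / CH→SPE
edges and the HDP-count gain of algorithm 2 equals the number of CH→SPE
moves. Decoy notes (negated mentions) are injected for NT/CH subjects to
exercise the negation handling inside the full pipeline.

What passing these tests shows — and does not show. They demonstrate that
the rule engines implement the stated logic exactly and degrade
monotonically under missingness; they do not certify performance on real
cohorts, whose BP autocorrelation, transcription errors, free-text
variety and visit irregularity the generator does not model.

`inject_missingness` blanks fields at per-field rates with a dedicated
seed, leaving truth untouched. Masks at increasing rates under the same
seed are nested, which makes "dipstick loss never raises PE sensitivity"
an exact property rather than an expectation-level one.

## Validation

One-vs-rest confusion counts per table label (HDP aggregate and the fine
labels) with PPV = TP/(TP+FP), NPV = TN/(TN+FN), accuracy = (TP+TN)/n,
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP). A metric is
not-applicable exactly when its denominator is zero (rendered `-`), the
standard treatment for strata with no diagnosed cases. Display rounding is
half-up at two decimals, the same convention as the count→percentage
reporting (chosen because banker's rounding visibly disagrees with
conventional cohort tables at values like 8.0750).

## Numerical and degenerate-input choices

* Percentages via exact `Decimal` arithmetic (50-digit context) before
  half-up quantization; a zero total raises rather than returning 0.
* Same-day duplicate visits: identical rows collapse; conflicting rows
  merge keeping the higher-systolic pair and the higher dipstick grade
  (conservative toward detection), with the conflict reported.
* An empty cohort after the inclusion filters summarizes with Total 0 and
  a warning; it is not an error.
* Unknown infant sex uses the male (higher) LFD cutoffs — conservative
  toward detection; a gestational week outside the table raises a coverage
  error rather than extrapolating.
* Run manifests are timestamp-free so identical runs produce identical
  artifacts.

## Problem sizes

The test suite and the acceptance script use cohorts of 120–3000 subjects
(2000 for the recovery and comparison experiments) — large enough for
binomial convergence checks at 4σ and for every subgroup to be populated,
and the full suite runs in well under a minute.

## Known limitations

* No severity grading, and eclampsia/HELLP are input flags, not output
  labels.
* Note mining is literal matching: misspellings, morphology and
  long-range negation are out of scope by design.
* The early-proteinuria rule suppresses only the PU criterion rather than
  excluding the subject from phenotyping altogether; sites wanting full
  exclusion can filter on the `early_proteinuria_channel_disabled`
  evidence marker.
* Antepartum data only; onsets first documented at or after delivery are
  invisible.
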