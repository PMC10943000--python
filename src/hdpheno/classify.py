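"""The two HDP phenotyping rule engines and their shared longitudinal predicates.

Hypertensive disorders of pregnancy (HDP) comprise gestational hypertension
(GH), preeclampsia (PE) and superimposed preeclampsia (SPE); chronic
hypertension (CH) and normotensive (NT) complete the partition.  GH/SPE/PE
are further split into early-onset (EO) and late-onset (LO) by gestational
age at disorder onset.

Two rule engines share the longitudinal predicates:

* ``classify_algorithm1`` follows the ACOG clinical concepts — hypertensive
  disease history, blood pressure, proteinuria, timing of onset and
  PE-related clinical conditions (severe-feature labs plus note-mined
  new-onset headache / visual disturbance / pulmonary edema).
* ``classify_algorithm2`` follows the JSOG concepts — identical except that
  hypertensive subjects *without* proteinuria are upgraded (GH -> PE,
  CH -> SPE) when a maternal organ-dysfunction flag fires at or after the
  chronic-hypertension boundary, or the infant is light-for-date.

All numeric cutoffs are configuration (:class:`Thresholds`); the defaults
are the guideline-standard values (140/90 mmHg, 20-week chronic boundary,
34-week EO/LO cut, dipstick 2+ once or 1+ twice, platelets < 100 x 10^3/uL,
creatinine > 1.1 mg/dL, transaminases > 2x the upper limit of normal, 10th
birth-weight percentile for light-for-date).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .cohort import Dipstick, SubjectBundle, Visit
from .notemining import (
    ORGAN_DYSFUNCTION_CATEGORIES,
    PE_CONDITION_NOTE_CATEGORIES,
    SubjectFlags,
)

LABELS = ("GH_EO", "GH_LO", "SPE_EO", "SPE_LO", "PE_EO", "PE_LO", "CH", "NT")
HDP_LABELS = ("GH_EO", "GH_LO", "SPE_EO", "SPE_LO", "PE_EO", "PE_LO")

#: Lab-based PE-related condition categories and the note-based ones.
LAB_CONDITION_CATEGORIES = ("low_platelets", "high_creatinine", "elevated_transaminases")
CONDITION_CATEGORIES = LAB_CONDITION_CATEGORIES + PE_CONDITION_NOTE_CATEGORIES


@dataclass
class Thresholds:
    """Every numeric cutoff of both rule engines, with guideline defaults."""

    sbp_cut: int = 140                     # mmHg, inclusive
    dbp_cut: int = 90                      # mmHg, inclusive
    ch_boundary: int = 140                 # days; hypertension before this is chronic (20 weeks)
    eo_lo_cut: int = 238                   # days; onset before this is early-onset (34 weeks)
    pu_single_grade: Dipstick = Dipstick.PLUS_2
    pu_repeat_grade: Dipstick = Dipstick.PLUS_1
    pu_repeat_count: int = 2
    platelet_low: float = 100.0            # 10^3/uL, strict <
    creatinine_high: float = 1.1           # mg/dL, strict >
    transaminase_uln_multiplier: float = 2.0
    uln_ast: float = 30.0                  # U/L
    uln_alt: float = 30.0                  # U/L
    lfd_percentile: int = 10
    htn_required_visits: int = 1           # qualifying visits needed for hypertension onset

    def __post_init__(self) -> None:
        self.pu_single_grade = Dipstick(self.pu_single_grade)
        self.pu_repeat_grade = Dipstick(self.pu_repeat_grade)
        for name in ("sbp_cut", "dbp_cut", "ch_boundary", "eo_lo_cut", "platelet_low",
                     "creatinine_high", "transaminase_uln_multiplier", "uln_ast", "uln_alt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pu_single_grade < self.pu_repeat_grade:
            raise ValueError("pu_single_grade must be >= pu_repeat_grade")
        if self.ch_boundary >= self.eo_lo_cut:
            raise ValueError("ch_boundary must be below eo_lo_cut")
        if self.pu_repeat_count < 1 or self.htn_required_visits < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class OnsetAssessment:
    htn_onset_ga: Optional[int] = None
    pu_onset_ga: Optional[int] = None
    early_pu: bool = False
    condition_onsets: dict = field(default_factory=dict)


@dataclass
class PhenotypeResult:
    """One label from the 8-way partition plus the onset day and the fired
    rules, in firing order, as an audit trail."""

    label: str
    onset_ga: Optional[int] = None
    evidence: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def is_hdp(self) -> bool:
        return self.label in HDP_LABELS


def detect_hypertension_onset(visits: Sequence[Visit], t: Thresholds) -> Optional[int]:
    """Gestational age of hypertension onset, or ``None``.

    Onset is the day of the ``htn_required_visits``-th visit (default: the
    first) with sbp >= ``sbp_cut`` or dbp >= ``dbp_cut``; cuts inclusive.
    """
    seen = 0
    for v in visits:
        if (v.sbp is not None and v.sbp >= t.sbp_cut) or (
            v.dbp is not None and v.dbp >= t.dbp_cut
        ):
            seen += 1
            if seen >= t.htn_required_visits:
                return v.gestational_age
    return None


def assess_proteinuria(visits: Sequence[Visit], t: Thresholds) -> tuple[Optional[int], bool]:
    """Dipstick positivity day and the early-proteinuria flag.

    The series turns positive on the first day at which either a single
    grade >= ``pu_single_grade`` occurs, or grades >= ``pu_repeat_grade``
    have occurred at ``pu_repeat_count`` distinct visits (the day of the
    last of them).  A positivity pattern that completes before
    ``ch_boundary`` marks early proteinuria — a chronic-kidney-disease
    style confounder — and disables the proteinuria channel entirely:
    the returned onset is ``None``.
    """
    repeat_seen = 0
    onset: Optional[int] = None
    for v in visits:
        if v.dipstick is None:
            continue
        if v.dipstick >= t.pu_repeat_grade:
            repeat_seen += 1
        if v.dipstick >= t.pu_single_grade or repeat_seen >= t.pu_repeat_count:
            onset = v.gestational_age
            break
    if onset is None:
        return None, False
    if onset < t.ch_boundary:
        return None, True
    return onset, False


def detect_pe_related_conditions(bundle: SubjectBundle, t: Thresholds) -> dict:
    """PE-related clinical conditions with their onset days.

    Lab-based categories fire at the first visit whose labs cross the cut
    (missing labs never fire); note-based categories fire at the earliest
    non-negated, dated mention.  Only fired categories appear in the map.
    """
    out: dict = {}

    def _fire(cat: str, day: int) -> None:
        if cat not in out or day < out[cat]:
            out[cat] = day

    for v in bundle.visits:
        labs = v.labs or {}
        plt = labs.get("platelet_count")
        if plt is not None and plt < t.platelet_low:
            _fire("low_platelets", v.gestational_age)
        cre = labs.get("serum_creatinine")
        if cre is not None and cre > t.creatinine_high:
            _fire("high_creatinine", v.gestational_age)
        ast, alt = labs.get("ast"), labs.get("alt")
        if (ast is not None and ast > t.transaminase_uln_multiplier * t.uln_ast) or (
            alt is not None and alt > t.transaminase_uln_multiplier * t.uln_alt
        ):
            _fire("elevated_transaminases", v.gestational_age)

    flags = bundle.flags
    if flags is not None:
        for cat in PE_CONDITION_NOTE_CATEGORIES:
            if flags.present(cat) and flags.earliest(cat) is not None:
                _fire(cat, flags.earliest(cat))
    return out


def _has_history(bundle: SubjectBundle) -> bool:
    # Self-reported interview and note-mined history are OR-combined.
    if bundle.interview_history_hypertension:
        return True
    return bundle.flags is not None and bundle.flags.present("history_of_hypertension")


def assess_onsets(bundle: SubjectBundle, t: Thresholds) -> OnsetAssessment:
    pu_onset, early_pu = assess_proteinuria(bundle.visits, t)
    return OnsetAssessment(
        htn_onset_ga=detect_hypertension_onset(bundle.visits, t),
        pu_onset_ga=pu_onset,
        early_pu=early_pu,
        condition_onsets=detect_pe_related_conditions(bundle, t),
    )


def _timing_suffix(onset: Optional[int], t: Thresholds) -> str:
    # Missing onset (possible only for the rare upgrade-by-LFD path with no
    # dated criterion at all) defaults to late-onset.
    return "EO" if onset is not None and onset < t.eo_lo_cut else "LO"


def classify_algorithm1(bundle: SubjectBundle, t: Optional[Thresholds] = None) -> PhenotypeResult:
    """ACOG-concept rule engine.

    Decision order: chronic-hypertension status (history or measured onset
    before ``ch_boundary``); normotensive if never hypertensive and not
    chronic; chronic subjects with new proteinuria or a PE-related
    condition at/after the boundary become SPE, otherwise CH; new-onset
    hypertensive subjects become PE with such a trigger, otherwise GH.
    Disorder onset for the EO/LO split is the first day on which the last
    of the label's defining criteria is met.
    """
    t = t or Thresholds()
    if not bundle.visits:
        raise ValueError(f"subject {bundle.subject_id}: no visits")
    ga_sorted = [v.gestational_age for v in bundle.visits]
    if ga_sorted != sorted(set(ga_sorted)):
        raise ValueError(f"subject {bundle.subject_id}: visits not strictly ascending")

    oa = assess_onsets(bundle, t)
    evidence: list[str] = []
    history = _has_history(bundle)
    if history:
        evidence.append("history_of_hypertension")
    if oa.early_pu:
        evidence.append("early_proteinuria_channel_disabled")

    ch_star = history or (oa.htn_onset_ga is not None and oa.htn_onset_ga < t.ch_boundary)
    if oa.htn_onset_ga is not None:
        evidence.append(f"hypertension_onset@{oa.htn_onset_ga}")
    if ch_star:
        evidence.append("chronic_hypertension_status")

    if oa.htn_onset_ga is None and not ch_star:
        evidence.append("never_hypertensive")
        return PhenotypeResult("NT", None, evidence)

    qualifying = {
        cat: d for cat, d in sorted(oa.condition_onsets.items()) if d >= t.ch_boundary
    }
    for cat, d in qualifying.items():
        evidence.append(f"pe_condition:{cat}@{d}")
    if oa.pu_onset_ga is not None:
        evidence.append(f"new_proteinuria@{oa.pu_onset_ga}")

    if ch_star:
        triggers = list(qualifying.values())
        if oa.pu_onset_ga is not None:
            triggers.append(oa.pu_onset_ga)
        if triggers:
            onset = min(triggers)
            evidence.append("superimposition_on_chronic_hypertension")
            return PhenotypeResult(f"SPE_{_timing_suffix(onset, t)}", onset, evidence)
        return PhenotypeResult("CH", oa.htn_onset_ga, evidence)

    # New-onset hypertension at/after the boundary.
    candidates = [max(oa.htn_onset_ga, d) for d in qualifying.values()]
    if oa.pu_onset_ga is not None:
        candidates.append(max(oa.htn_onset_ga, oa.pu_onset_ga))
    if candidates:
        onset = min(candidates)
        evidence.append("preeclampsia_criteria_met")
        return PhenotypeResult(f"PE_{_timing_suffix(onset, t)}", onset, evidence)
    evidence.append("gestational_hypertension_without_proteinuria")
    return PhenotypeResult(f"GH_{_timing_suffix(oa.htn_onset_ga, t)}", oa.htn_onset_ga, evidence)


def _organ_dysfunction_onsets(flags: Optional[SubjectFlags], t: Thresholds) -> list[tuple[str, int]]:
    if flags is None:
        return []
    out = []
    for cat in ORGAN_DYSFUNCTION_CATEGORIES:
        day = flags.earliest(cat)
        if flags.present(cat) and day is not None and day >= t.ch_boundary:
            out.append((cat, day))
    return out


def classify_algorithm2(
    bundle: SubjectBundle, t: Optional[Thresholds] = None, lfd: bool = False
) -> PhenotypeResult:
    """JSOG-concept rule engine: algorithm 1 plus the upgrade paths.

    A GH subject becomes PE, and a CH subject becomes SPE, when at least
    one maternal organ-dysfunction flag (epigastralgia, HELLP syndrome,
    eclampsia, FGR, renal or hepatic dysfunction) is present with onset
    at/after ``ch_boundary``, or the infant is light-for-date.  The EO/LO
    split is re-evaluated from the upgraded disorder's onset day;
    light-for-date carries no timing of its own.
    """
    t = t or Thresholds()
    res = classify_algorithm1(bundle, t)
    if res.label not in ("GH_EO", "GH_LO", "CH"):
        return res
    organ = _organ_dysfunction_onsets(bundle.flags, t)
    if not organ and not lfd:
        return res
    evidence = list(res.evidence)
    for cat, day in organ:
        evidence.append(f"organ_dysfunction:{cat}@{day}")
    if lfd:
        evidence.append("light_for_date")

    htn_onset = detect_hypertension_onset(bundle.visits, t)
    if res.label == "CH":
        candidates = [day for _, day in organ]
        if not candidates:  # LFD alone: no dated criterion
            fallback = htn_onset if htn_onset is not None else (
                bundle.delivery.delivery_ga if bundle.delivery is not None else None
            )
            candidates = [fallback] if fallback is not None else []
        onset = min(candidates) if candidates else None
        evidence.append("upgrade_ch_to_spe")
        return PhenotypeResult(f"SPE_{_timing_suffix(onset, t)}", onset, evidence)

    # GH -> PE; hypertension onset is always dated here.
    candidates = [max(htn_onset, day) for _, day in organ]
    if lfd:
        candidates.append(htn_onset)
    onset = min(candidates)
    evidence.append("upgrade_gh_to_pe")
    return PhenotypeResult(f"PE_{_timing_suffix(onset, t)}", onset, evidence)


#: Off-diagonal moves algorithm 2's upgrade paths can produce.
UPGRADE_EDGES = {
    ("GH_EO", "PE_EO"), ("GH_EO", "PE_LO"), ("GH_LO", "PE_EO"), ("GH_LO", "PE_LO"),
    ("CH", "SPE_EO"), ("CH", "SPE_LO"),
}


@dataclass
class Discordance:
    subject_id: str
    label1: str
    label2: str
    rule: str  # upgrade rule responsible, from the algorithm-2 evidence trail


def compare_algorithms(
    results1: Mapping[str, PhenotypeResult], results2: Mapping[str, PhenotypeResult]
) -> tuple[dict, list[Discordance]]:
    """Cross-tabulate algorithm 1 x algorithm 2 labels.

    Returns the contingency table as ``{(label1, label2): count}`` plus the
    list of discordant subjects with the responsible upgrade rule.
    """
    if set(results1) != set(results2):
        raise ValueError("subject sets differ between the two result sets")
    table: dict = {}
    discordant: list[Discordance] = []
    for sid in sorted(results1):
        l1, l2 = results1[sid].label, results2[sid].label
        table[(l1, l2)] = table.get((l1, l2), 0) + 1
        if l1 != l2:
            rules = [
                e for e in results2[sid].evidence
                if e.startswith(("upgrade_", "organ_dysfunction:", "light_for_date"))
            ]
            discordant.append(Discordance(sid, l1, l2, ";".join(rules)))
    return table, discordant
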