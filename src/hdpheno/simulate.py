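"""Synthetic pregnancy-cohort generator with ground-truth labels.

Emulates the statistical structure the phenotyping rules consume: a
prenatal visit schedule with repeated BP and dipstick measurements,
class-dependent hypertension/proteinuria onset, occasional labs, short
bilingual clinical-note strings seeded with dictionary terms (and negated
decoys), and delivery outcomes — so every module is testable without any
cohort download.

Generative classes are NT, CH, GH, PE and SPE, drawn at configured
prevalences (defaults follow the rates a large pregnancy cohort reports:
~90% normotensive, ~8% HDP).  Truth classes are defined under the union of
the American and Japanese guideline concepts — organ-dysfunction flags and
light-for-date are emitted only for PE/SPE subjects — so that both rule
engines can recover the truth exactly when emission noise is off.

Everything is driven by one ``numpy`` Generator seeded from
``SimConfig.seed``: identical config means identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import DeliveryRecord, Dipstick, SubjectBundle, Visit
from .classify import Thresholds
from .lfd import default_lfd_table, growth_model

CLASSES = ("NT", "CH", "GH", "PE", "SPE")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_prevalence() -> dict:
    # Mirrors the subgroup mix of a ~22k-pregnancy cohort: ~2.4% chronic
    # hypertension, ~4% GH, ~2.6% PE, ~1.4% SPE, remainder normotensive.
    return {"NT": 0.8967, "CH": 0.0241, "GH": 0.0396, "PE": 0.0261, "SPE": 0.0135}


def _default_eo_fraction() -> dict:
    return {"GH": 0.40, "PE": 0.24, "SPE": 0.68}


def _default_lfd_prob() -> dict:
    return {"NT": 0.08, "CH": 0.0, "GH": 0.0, "PE": 0.30, "SPE": 0.20}


def _default_organ_flag_prob() -> dict:
    return {"PE": 0.30, "SPE": 0.25}


def _default_delivery_mean() -> dict:
    return {"NT": 276.0, "CH": 274.0, "GH": 272.0, "PE": 268.0, "SPE": 268.0}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_subjects: int = 2000
    seed: int = 0
    prevalence: dict = field(default_factory=_default_prevalence)
    eo_fraction: dict = field(default_factory=_default_eo_fraction)
    #: standard Japanese prenatal cadence: 4-weekly to week 23, 2-weekly to
    #: week 35, weekly to delivery.
    visit_weeks: tuple = (12, 16, 20, 24, 26, 28, 30, 32, 34, 36, 37, 38, 39, 40)
    sbp_baseline: tuple = (112.0, 8.0)     # mmHg (mean, sd)
    dbp_baseline: tuple = (68.0, 6.0)
    sbp_hypertensive: tuple = (152.0, 8.0)
    dbp_hypertensive: tuple = (96.0, 6.0)
    #: multiplier on all emission noise (BP spread, dipstick misreads);
    #: 0.0 gives a fully deterministic, noise-free emission model.
    emission_noise: float = 1.0
    dipstick_trace_p: float = 0.05
    dipstick_false_pos_p: float = 0.01
    baseline_lab_p: float = 0.3
    pe_condition_fraction: float = 0.25    # PE via conditions rather than dipstick
    condition_headache_fraction: float = 0.5
    spe_condition_fraction: float = 0.30
    organ_flag_prob: dict = field(default_factory=_default_organ_flag_prob)
    lfd_prob: dict = field(default_factory=_default_lfd_prob)
    early_pu_rate: float = 0.01            # CKD-style early proteinuria, NT subjects
    history_interview_p: float = 0.75
    ch_hypertensive_from_start_p: float = 0.6
    note_decoy_rate: float = 0.15
    delivery_mean: dict = field(default_factory=_default_delivery_mean)
    delivery_sd: float = 8.0
    delivery_range: tuple = (252, 293)

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be non-negative")
        if set(self.prevalence) != set(CLASSES):
            raise ConfigError(f"prevalence must cover exactly {CLASSES}")
        vals = list(self.prevalence.values())
        if any(p < 0 for p in vals) or abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigError("prevalences must be non-negative and sum to 1")
        if list(self.visit_weeks) != sorted(set(self.visit_weeks)):
            raise ConfigError("visit_weeks must be strictly increasing")
        for pair in (self.sbp_baseline, self.dbp_baseline,
                     self.sbp_hypertensive, self.dbp_hypertensive):
            if pair[1] < 0:
                raise ConfigError("sd values must be >= 0")
        if self.emission_noise < 0:
            raise ConfigError("emission_noise must be >= 0")

    @classmethod
    def cross_guideline(cls, **overrides) -> "SimConfig":
        """Study condition for the algorithm-comparison experiment.

        By default the generator emits organ-dysfunction flags and
        light-for-date only for PE/SPE subjects, so the two rule engines
        agree everywhere.  Real cohorts also contain GH/CH pregnancies with
        organ dysfunction or a light-for-date infant — exactly the subjects
        the Japanese-concept engine upgrades and the American-concept one
        does not.  This configuration adds those subjects so the
        cross-algorithm discordance structure is exercised.
        """
        base = dict(
            organ_flag_prob={"PE": 0.30, "SPE": 0.25, "GH": 0.10, "CH": 0.10},
            lfd_prob={"NT": 0.08, "CH": 0.05, "GH": 0.08, "PE": 0.30, "SPE": 0.20},
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TruthRecord:
    subject_id: str
    generative_class: str
    onset_day: Optional[int] = None     # disorder onset, GH/PE/SPE only
    flags: dict = field(default_factory=dict)  # category -> day
    lfd: bool = False


# Bilingual note templates; {term} is replaced by a dictionary surface term.
_POSITIVE_TEMPLATES = ("{term} noted at this visit", "{term}あり、経過観察")
_HISTORY_TEMPLATES = (
    "history of hypertension since before pregnancy",
    "高血圧の既往について本人より聴取",
)
_HEADACHE_TEMPLATES = ("new-onset headache, persistent", "持続する頭痛を認める")
_DECOY_TEMPLATES = (
    "no epigastralgia, no visual disturbance",
    "頭痛なし、心窩部痛なし",
    "eclampsia ruled out",
)


def _bp_draw(rng, mean_sd: tuple, noise: float) -> int:
    mean, sd = mean_sd
    return int(round(rng.normal(mean, sd * noise)))


def generate(config: Optional[SimConfig] = None) -> tuple[list[SubjectBundle], list[TruthRecord]]:
    """Generate ``(bundles, truth_records)`` for one cohort."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    lfd_table = default_lfd_table()
    cutoff10 = {
        (int(r.week), r.sex): float(r.p10) for r in lfd_table.itertuples(index=False)
    }

    classes = list(CLASSES)
    probs = np.array([config.prevalence[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    assigned = rng.choice(len(classes), size=config.n_subjects, p=probs)

    noise = config.emission_noise
    bundles: list[SubjectBundle] = []
    truths: list[TruthRecord] = []
    lo_floor = 238  # EO/LO cut of the default thresholds; onset windows respect it

    for i in range(config.n_subjects):
        sid = f"S{i:05d}"
        klass = classes[int(assigned[i])]
        delivery_ga = int(
            np.clip(
                round(rng.normal(config.delivery_mean[klass], config.delivery_sd)),
                *config.delivery_range,
            )
        )
        days = [7 * w for w in config.visit_weeks if 7 * w < delivery_ga]

        interview_hist = False
        history_note = False
        htn_from: Optional[int] = None       # first hypertensive visit day
        pu_from: Optional[int] = None        # first dipstick-positive day
        creat_from: Optional[int] = None     # first elevated-creatinine day
        headache_day: Optional[int] = None
        early_pu = False
        truth_onset: Optional[int] = None
        organ_flags: dict = {}

        def _pick_trigger(eo: bool) -> int:
            if eo:
                pool = [d for d in days if 140 <= d < lo_floor]
            else:
                pool = [d for d in days if lo_floor <= d <= delivery_ga - 7]
            return int(rng.choice(pool))

        if klass in ("CH", "SPE"):
            interview_hist = rng.random() < config.history_interview_p
            if interview_hist and rng.random() < 0.3:
                history_note = True
            if not interview_hist or rng.random() < config.ch_hypertensive_from_start_p:
                htn_from = days[0]
        if klass in ("GH", "PE"):
            eo = rng.random() < config.eo_fraction[klass]
            htn_from = _pick_trigger(eo)
            truth_onset = htn_from
        if klass == "PE":
            idx = days.index(htn_from)
            trigger = days[min(idx + int(rng.integers(0, 2)), len(days) - 1)]
            if rng.random() < config.pe_condition_fraction:
                if rng.random() < config.condition_headache_fraction:
                    headache_day = trigger
                else:
                    creat_from = trigger
            else:
                pu_from = trigger
            truth_onset = max(htn_from, trigger)
        if klass == "SPE":
            eo = rng.random() < config.eo_fraction["SPE"]
            trigger = _pick_trigger(eo)
            if rng.random() < config.spe_condition_fraction:
                creat_from = trigger
            else:
                pu_from = trigger
            truth_onset = trigger
        if klass == "NT" and rng.random() < config.early_pu_rate:
            early_pu = True

        # Organ-dysfunction decoration (PE/SPE only; see module docstring).
        p_flag = config.organ_flag_prob.get(klass, 0.0)
        if p_flag and rng.random() < p_flag:
            cat = ("epigastralgia", "hellp_syndrome", "fgr")[int(rng.integers(0, 3))]
            if truth_onset is not None:
                organ_flags[cat] = truth_onset
            else:  # classes without a disorder onset: any mid-pregnancy visit
                organ_flags[cat] = int(rng.choice([d for d in days if d >= 140]))

        visits = []
        for k, day in enumerate(days):
            hyper = htn_from is not None and day >= htn_from
            sbp = _bp_draw(rng, config.sbp_hypertensive if hyper else config.sbp_baseline, noise)
            dbp = _bp_draw(rng, config.dbp_hypertensive if hyper else config.dbp_baseline, noise)
            sbp = max(sbp, 60)
            dbp = max(min(dbp, sbp - 10), 30)

            if pu_from is not None and day >= pu_from:
                dip = Dipstick.PLUS_3 if rng.random() < 0.25 else Dipstick.PLUS_2
            elif early_pu and k < 2:
                dip = Dipstick.PLUS_1
            else:
                dip = Dipstick.NEGATIVE
                r = rng.random()
                if r < config.dipstick_false_pos_p * noise:
                    dip = Dipstick.PLUS_1
                elif r < (config.dipstick_false_pos_p + config.dipstick_trace_p) * noise:
                    dip = Dipstick.TRACE

            labs = {}
            if creat_from is not None and day >= creat_from:
                labs["serum_creatinine"] = round(1.4 + rng.normal(0.0, 0.1 * noise), 2)
            elif rng.random() < config.baseline_lab_p:
                labs["serum_creatinine"] = round(0.60 + rng.normal(0.0, 0.05 * noise), 2)
                labs["platelet_count"] = round(250.0 + rng.normal(0.0, 30.0 * noise), 1)
            visits.append(Visit(day, sbp, dbp, dip, labs))

        notes = []
        if history_note:
            notes.append((days[0], _HISTORY_TEMPLATES[int(rng.integers(0, 2))]))
        if headache_day is not None:
            notes.append((headache_day, _HEADACHE_TEMPLATES[int(rng.integers(0, 2))]))
        for cat, day in organ_flags.items():
            term = {"epigastralgia": "epigastralgia", "hellp_syndrome": "hellp syndrome",
                    "fgr": "fetal growth restriction"}[cat]
            tpl = _POSITIVE_TEMPLATES[int(rng.integers(0, 2))]
            notes.append((day, tpl.format(term=term)))
        if klass in ("NT", "CH") and rng.random() < config.note_decoy_rate:
            notes.append((days[-1], _DECOY_TEMPLATES[int(rng.integers(0, 3))]))

        sex = "male" if rng.random() < 0.5 else "female"
        week = delivery_ga // 7
        mean, sd = growth_model(week, sex)
        cut = cutoff10[(week, sex)]
        lfd = rng.random() < config.lfd_prob.get(klass, 0.0)
        if lfd:
            weight = int(cut * rng.uniform(0.80, 0.97))
        else:
            weight = int(rng.uniform(cut * 1.03, mean + 1.5 * sd))
        delivery = DeliveryRecord(
            delivery_ga=delivery_ga,
            birth_weight=weight,
            infant_sex=sex,
            live_birth=True,
            parity=int(rng.integers(0, 3)),
        )

        bundles.append(
            SubjectBundle(
                subject_id=sid,
                interview_history_hypertension=interview_hist,
                visits=visits,
                delivery=delivery,
                notes=notes,
            )
        )
        if headache_day is not None:
            organ_flags = dict(organ_flags)
            organ_flags["new_onset_headache"] = headache_day
        truths.append(TruthRecord(sid, klass, truth_onset, organ_flags, lfd))

    return bundles, truths


def truth_label(record: TruthRecord, t: Optional[Thresholds] = None) -> str:
    """The 8-way label a perfect classifier should assign to a truth record."""
    t = t or Thresholds()
    k = record.generative_class
    if k in ("NT", "CH"):
        return k
    suffix = "EO" if record.onset_day is not None and record.onset_day < t.eo_lo_cut else "LO"
    return f"{k}_{suffix}"


MISSINGNESS_FIELDS = (
    "bp", "dipstick", "platelet_count", "serum_creatinine", "ast", "alt", "birth_weight",
)


def inject_missingness(
    bundles: Sequence[SubjectBundle],
    truth: Sequence[TruthRecord],
    rates: Mapping[str, float],
    seed: int,
) -> list[SubjectBundle]:
    """Blank fields at the stated per-field rates; truth is untouched.

    ``rates`` keys are a subset of :data:`MISSINGNESS_FIELDS`; ``bp`` blanks
    the systolic/diastolic pair together.  Deterministic given ``seed``.
    """
    bad = set(rates).difference(MISSINGNESS_FIELDS)
    if bad:
        raise ValueError(f"unknown missingness fields {sorted(bad)}")
    if any(not 0.0 <= r <= 1.0 for r in rates.values()):
        raise ValueError("missingness rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(list(bundles))
    for b in out:
        for v in b.visits:
            if rates.get("bp", 0.0) and rng.random() < rates["bp"]:
                v.sbp = None
                v.dbp = None
            if rates.get("dipstick", 0.0) and rng.random() < rates["dipstick"]:
                v.dipstick = None
            for lab in ("platelet_count", "serum_creatinine", "ast", "alt"):
                if lab in v.labs and rates.get(lab, 0.0) and rng.random() < rates[lab]:
                    del v.labs[lab]
        if (
            b.delivery is not None
            and b.delivery.birth_weight is not None
            and rates.get("birth_weight", 0.0)
            and rng.random() < rates["birth_weight"]
        ):
            b.delivery.birth_weight = None
    return out
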