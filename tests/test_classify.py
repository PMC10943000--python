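"""Longitudinal predicates, the two rule engines and their comparison."""

import pandas as pd
import pytest

from hdpheno.classify import (
    HDP_LABELS,
    LABELS,
    PhenotypeResult,
    Thresholds,
    UPGRADE_EDGES,
    assess_proteinuria,
    classify_algorithm1,
    classify_algorithm2,
    compare_algorithms,
    detect_hypertension_onset,
    detect_pe_related_conditions,
)
from hdpheno.cohort import DeliveryRecord, Dipstick, SubjectBundle, Visit
from hdpheno.lfd import (
    LfdCoverageError,
    build_synthetic_lfd_table,
    default_lfd_table,
    is_light_for_date,
)
from hdpheno.notemining import aggregate_flags, default_dictionary
from hdpheno.pipeline import phenotype_cohort
from hdpheno.simulate import SimConfig, generate

T = Thresholds()


def _v(ga, sbp=112, dbp=68, dip="negative", labs=None):
    grades = {"negative": Dipstick.NEGATIVE, "trace": Dipstick.TRACE, "1+": Dipstick.PLUS_1,
              "2+": Dipstick.PLUS_2, "3+": Dipstick.PLUS_3}
    return Visit(ga, sbp, dbp, grades[dip], labs or {})


def _bundle(visits, history=False, notes=(), delivery=True):
    b = SubjectBundle(
        "x", history, list(visits),
        DeliveryRecord(270, 3000, "male") if delivery else None, list(notes),
    )
    b.flags = aggregate_flags(b.notes, default_dictionary())
    return b


@pytest.mark.parametrize(
    "visits,expected",
    [
        ([(84, 112, 68), (168, 118, 72)], None),
        ([(210, 142, 88)], 210),          # 142 >= 140, inclusive cut
        ([(130, 150, 95), (200, 152, 96)], 130),
        ([(130, 139, 89)], None),         # just below both cuts
        ([(130, 120, 90)], 130),          # diastolic alone qualifies
    ],
)
def test_detect_hypertension_onset(visits, expected):
    vs = [_v(ga, s, d) for ga, s, d in visits]
    assert detect_hypertension_onset(vs, T) == expected


@pytest.mark.parametrize(
    "series,expected",
    [
        ([(100, "1+"), (120, "1+")], (None, True)),   # repeat completes at 120 < 140
        ([(220, "2+")], (220, False)),                # single-grade criterion
        ([(220, "trace")], (None, False)),
        ([(100, "1+"), (150, "1+")], (150, False)),   # repeat completes after boundary
        ([(100, "2+")], (None, True)),                # single grade in early pregnancy
        ([(150, "1+"), (200, "negative"), (230, "1+")], (230, False)),
    ],
)
def test_assess_proteinuria(series, expected):
    vs = [_v(ga, dip=g) for ga, g in series]
    assert assess_proteinuria(vs, T) == expected


def test_lab_conditions_fire_at_first_crossing():
    b = _bundle([
        _v(200, labs={"serum_creatinine": 0.8}),
        _v(230, labs={"serum_creatinine": 1.3}),
        _v(245, labs={"serum_creatinine": 1.4}),
    ])
    assert detect_pe_related_conditions(b, T) == {"high_creatinine": 230}


def test_conditions_empty_when_no_labs_or_flags():
    assert detect_pe_related_conditions(_bundle([_v(200)]), T) == {}


def test_lab_boundary_conventions():
    # platelets exactly at the cut do not fire (strict <); transaminases
    # must exceed the ULN multiple (strict >)
    b = _bundle([_v(230, labs={"platelet_count": 100.0, "ast": 60.0})])
    assert detect_pe_related_conditions(b, T) == {}
    b2 = _bundle([_v(230, labs={"platelet_count": 99.9, "alt": 61.0})])
    assert detect_pe_related_conditions(b2, T) == {
        "low_platelets": 230, "elevated_transaminases": 230,
    }


def test_note_conditions_fire_at_earliest_mention():
    b = _bundle([_v(200)], notes=[(240, "new-onset headache, persistent")])
    assert detect_pe_related_conditions(b, T) == {"new_onset_headache": 240}


# --- algorithm 1 -----------------------------------------------------------

def test_algorithm1_pe_late_onset():
    """New-onset hypertension at 240 with proteinuria from 245: PE, onset
    the day the last defining criterion is met."""
    b = _bundle([_v(84), _v(240, 150, 95), _v(245, 152, 96, "2+")])
    res = classify_algorithm1(b, T)
    assert (res.label, res.onset_ga) == ("PE_LO", 245)


def test_algorithm1_history_without_triggers_is_ch():
    b = _bundle([_v(84), _v(200)], history=True)
    assert classify_algorithm1(b, T).label == "CH"


def test_algorithm1_never_hypertensive_is_nt():
    b = _bundle([_v(84), _v(200), _v(250)])
    assert classify_algorithm1(b, T).label == "NT"


def test_algorithm1_early_pu_disables_proteinuria_channel():
    # early dipstick positivity (CKD-style) must not create PE on its own
    b = _bundle([_v(100, dip="1+"), _v(120, dip="1+"), _v(250, 150, 95, "2+")])
    res = classify_algorithm1(b, T)
    assert res.label == "GH_LO"
    assert "early_proteinuria_channel_disabled" in res.evidence


def test_algorithm1_empty_visits_raises():
    with pytest.raises(ValueError, match="no visits"):
        classify_algorithm1(SubjectBundle("x", visits=[]), T)


# --- algorithm 2 -----------------------------------------------------------

def test_algorithm2_lfd_upgrades_gh_to_pe():
    b = _bundle([_v(84), _v(230, 150, 95)])
    res = classify_algorithm2(b, T, lfd=True)
    assert (res.label, res.onset_ga) == ("PE_EO", 230)


def test_algorithm2_flag_upgrades_ch_to_spe():
    b = _bundle([_v(84), _v(200)], history=True, notes=[(250, "epigastralgia noted")])
    res = classify_algorithm2(b, T, lfd=False)
    assert (res.label, res.onset_ga) == ("SPE_LO", 250)


def test_algorithm2_without_upgrade_equals_algorithm1():
    b = _bundle([_v(84), _v(240, 150, 95), _v(245, 152, 96, "2+")])
    assert classify_algorithm2(b, T, lfd=False) == classify_algorithm1(b, T)


def test_algorithm2_flag_before_boundary_does_not_upgrade():
    b = _bundle([_v(84), _v(230, 150, 95)], notes=[(100, "epigastralgia noted")])
    assert classify_algorithm2(b, T, lfd=False).label == "GH_EO"


# --- light-for-date --------------------------------------------------------

def test_lfd_above_median_is_false():
    table = default_lfd_table()
    p50 = float(table[(table.week == 38) & (table.sex == "male")].iloc[0]["p50"])
    assert not is_light_for_date(p50 + 1, 266, "male", table)


def test_lfd_exactly_at_cutoff_is_false():
    table = default_lfd_table()
    p10 = float(table[(table.week == 38) & (table.sex == "male")].iloc[0]["p10"])
    assert not is_light_for_date(p10, 266, "male", table)
    assert is_light_for_date(p10 - 1, 266, "male", table)


def test_lfd_shipped_table_lookup():
    # value fixed by the shipped synthetic table row (38 weeks, male)
    assert is_light_for_date(2000, 266, "male")
    # shipped CSV agrees with the generating growth model, row by row
    pd.testing.assert_frame_equal(
        default_lfd_table(), build_synthetic_lfd_table(), check_dtype=False
    )


def test_lfd_outside_table_coverage():
    with pytest.raises(LfdCoverageError):
        is_light_for_date(500, 7 * 18, "male")


# --- algorithm comparison and cohort-level properties ----------------------

def test_compare_identical_results():
    r = {"a": PhenotypeResult("GH_LO"), "b": PhenotypeResult("NT")}
    table, disc = compare_algorithms(r, r)
    assert disc == []
    assert table == {("GH_LO", "GH_LO"): 1, ("NT", "NT"): 1}


def test_compare_single_upgrade():
    r1 = {"a": PhenotypeResult("GH_LO"), "b": PhenotypeResult("NT")}
    r2 = {"a": PhenotypeResult("PE_LO", evidence=["light_for_date", "upgrade_gh_to_pe"]),
          "b": PhenotypeResult("NT")}
    table, disc = compare_algorithms(r1, r2)
    off_diag = {k: v for k, v in table.items() if k[0] != k[1]}
    assert off_diag == {("GH_LO", "PE_LO"): 1}
    assert len(disc) == 1 and "upgrade_gh_to_pe" in disc[0].rule


def test_compare_subject_mismatch_raises():
    with pytest.raises(ValueError):
        compare_algorithms({"a": PhenotypeResult("NT")}, {"b": PhenotypeResult("NT")})


@pytest.fixture(scope="module")
def noisy_cohort():
    bundles, _ = generate(SimConfig.cross_guideline(n_subjects=600, seed=13))
    return bundles


def test_every_subject_gets_exactly_one_label(noisy_cohort):
    for algorithm in (1, 2):
        results = phenotype_cohort(noisy_cohort, algorithm=algorithm)
        assert len(results) == len(noisy_cohort)
        assert all(r.label in LABELS for r in results.values())


def test_eo_lo_consistency(noisy_cohort):
    """EO labels iff onset before the 34-week cut; CH/NT carry no timing."""
    for algorithm in (1, 2):
        for r in phenotype_cohort(noisy_cohort, algorithm=algorithm).values():
            if r.label in HDP_LABELS:
                if r.label.endswith("EO"):
                    assert r.onset_ga is not None and r.onset_ga < T.eo_lo_cut
                else:
                    assert r.onset_ga is None or r.onset_ga >= T.eo_lo_cut
            else:
                assert not r.label.endswith(("EO", "LO"))


def test_raising_bp_cuts_never_adds_hypertensive_labels(noisy_cohort):
    counts = []
    for sbp, dbp in ((140, 90), (150, 95), (160, 100)):
        t = Thresholds(sbp_cut=sbp, dbp_cut=dbp)
        results = phenotype_cohort(noisy_cohort, thresholds=t, algorithm=1)
        counts.append(sum(1 for r in results.values() if r.label != "NT"))
    assert counts[0] >= counts[1] >= counts[2]


def test_hdp_containment_and_upgrade_edges(noisy_cohort):
    r1 = phenotype_cohort(noisy_cohort, algorithm=1)
    r2 = phenotype_cohort(noisy_cohort, algorithm=2)
    hdp1 = {s for s, r in r1.items() if r.is_hdp}
    hdp2 = {s for s, r in r2.items() if r.is_hdp}
    assert hdp1 <= hdp2
    _, disc = compare_algorithms(r1, r2)
    assert {(d.label1, d.label2) for d in disc} <= UPGRADE_EDGES
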