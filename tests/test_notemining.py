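"""Dictionary matching, negation and per-subject flag aggregation."""

import re

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hdpheno.notemining import (
    FLAG_CATEGORIES,
    FlagDictionary,
    aggregate_flags,
    default_dictionary,
    dump_dictionary,
    load_dictionary,
    mine_note,
    normalize_text,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("HELLP  Syndrome", "hellp syndrome"),
        ("ＨＥＬＬＰ", "hellp"),   # full-width Latin folds onto ASCII
        ("", ""),
        ("  a\tb \n c ", "a b c"),
    ],
)
def test_normalize_text(raw, expected):
    assert normalize_text(raw) == expected


def _dict(**kw):
    base = dict(
        terms={"history_of_hypertension": ["history of hypertension", "hypertension"]},
        negation_cues=["no"],
        post_negation_cues=["ruled out"],
        negation_window=10,
    )
    base.update(kw)
    return FlagDictionary(**base)


def test_simple_hit_not_negated():
    hits = mine_note("history of hypertension since 2010", _dict())
    assert len(hits) == 1
    assert hits[0].category == "history_of_hypertension"
    assert not hits[0].negated


def test_pre_window_negation():
    (hit,) = mine_note("no history of hypertension", _dict())
    assert hit.negated


def test_post_positive_cue_negates_only_its_term():
    hits = mine_note("eclampsia ruled out; epigastralgia present", default_dictionary())
    by_cat = {h.category: h for h in hits}
    assert by_cat["eclampsia"].negated
    assert not by_cat["epigastralgia"].negated


def test_longest_term_wins_on_overlap():
    hits = mine_note("hellp syndrome suspected", default_dictionary())
    assert [h.text for h in hits if h.category == "hellp_syndrome"] == ["hellp syndrome"]


def test_term_does_not_fire_inside_longer_word():
    assert all(
        h.category != "eclampsia" for h in mine_note("preeclampsia workup", default_dictionary())
    )


def test_fullwidth_japanese_note_matches():
    hits = mine_note("ＨＥＬＬＰ症候群を認める", default_dictionary())
    assert any(h.category == "hellp_syndrome" for h in hits)


def test_aggregate_empty_notes():
    flags = aggregate_flags([], default_dictionary())
    assert all(not flags.present(c) for c in FLAG_CATEGORIES)


def test_aggregate_earliest_dated_mention():
    notes = [(210, "epigastralgia"), (180, "epigastralgia"), (None, "epigastralgia")]
    flags = aggregate_flags(notes, default_dictionary())
    assert flags.present("epigastralgia")
    assert flags.earliest("epigastralgia") == 180


def test_only_negated_mentions_leave_flag_absent():
    flags = aggregate_flags([(200, "no epigastralgia")], default_dictionary())
    assert not flags.present("epigastralgia")
    assert flags["epigastralgia"].evidence == []


def test_undated_mentions_only_give_missing_timing():
    flags = aggregate_flags([(None, "epigastralgia")], default_dictionary())
    assert flags.present("epigastralgia")
    assert flags.earliest("epigastralgia") is None


_NOTE_POOL = [
    "epigastralgia noted",
    "no epigastralgia",
    "hellp syndrome",
    "頭痛なし",
    "持続する頭痛を認める",
    "eclampsia ruled out",
    "visual disturbance reported",
    "routine visit, nothing abnormal",
]


@given(st.lists(st.sampled_from(_NOTE_POOL), max_size=5), st.sampled_from(_NOTE_POOL))
def test_adding_a_note_never_clears_a_flag(notes, extra):
    d = default_dictionary()
    dated = [(100 + 7 * i, t) for i, t in enumerate(notes)]
    before = aggregate_flags(dated, d)
    after = aggregate_flags(dated + [(250, extra)], d)
    for cat in FLAG_CATEGORIES:
        if before.present(cat):
            assert after.present(cat)


def _naive_presence(text, dictionary):
    """Brute-force scanner: every term occurrence, no overlap optimization."""
    norm = normalize_text(text)
    present = set()
    for cat, terms in dictionary.terms.items():
        for term in terms:
            for i in range(len(norm) - len(term) + 1):
                if norm[i: i + len(term)] != term:
                    continue
                if term[0].isascii() and term[0].isalnum() and i > 0 and re.match(
                    r"[0-9a-z]", norm[i - 1]
                ):
                    continue
                j = i + len(term)
                if term[-1].isascii() and term[-1].isalnum() and j < len(norm) and re.match(
                    r"[0-9a-z]", norm[j]
                ):
                    continue
                w = dictionary.negation_window
                before, after = norm[max(0, i - w): i], norm[j: j + w]
                negated = any(
                    re.search(rf"(?<![0-9a-z]){re.escape(c)}(?![0-9a-z])", before)
                    for c in dictionary.negation_cues
                ) or any(c in after for c in dictionary.post_negation_cues)
                if not negated:
                    present.add(cat)
    return present


@given(st.lists(st.sampled_from(_NOTE_POOL), min_size=1, max_size=4))
def test_matcher_agrees_with_brute_force_scanner(notes):
    d = default_dictionary()
    # separator longer than the negation window, so notes cannot bleed
    # negation cues into each other
    text = " ; routine visit, stable ; ".join(notes)
    mined = {m.category for m in mine_note(text, d) if not m.negated}
    assert mined == _naive_presence(text, d)


def test_mining_is_deterministic():
    d = default_dictionary()
    text = "epigastralgia; no hellp syndrome; 頭痛なし; visual disturbance"
    assert mine_note(text, d) == mine_note(text, d)


def test_dictionary_requires_terms():
    with pytest.raises(ValueError):
        FlagDictionary(terms={"epigastralgia": ["", "  "]})


def test_dictionary_yaml_roundtrip(tmp_path):
    d = default_dictionary()
    dump_dictionary(d, tmp_path / "dict.yaml")
    back = load_dictionary(tmp_path / "dict.yaml")
    assert back.terms == d.terms
    assert back.negation_cues == d.negation_cues
    assert back.negation_window == d.negation_window
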