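"""Dictionary-driven pattern matching over free-text clinical notes.

Clinical notes in cohort transcriptions are short strings ("no history of
hypertension", "epigastralgia reported", Japanese equivalents).  The engine
here is deliberately simple and auditable: normalized literal-term matching
with longest-match overlap resolution and fixed-window negation cues.  The
lexicon is configuration, not code — ``default_dictionary`` ships bilingual
seed terms per flag category, and any category's list can be replaced.

No statistical NLP, no morphology: the matcher is exactly reproducible and
its behaviour is fully determined by the dictionary.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

#: Flag categories the downstream classifiers consume.
FLAG_CATEGORIES = (
    "history_of_hypertension",
    "epigastralgia",
    "hellp_syndrome",
    "eclampsia",
    "fgr",
    "renal_dysfunction",
    "hepatic_dysfunction",
    "new_onset_headache",
    "visual_disturbance",
    "pulmonary_edema",
)

#: Maternal organ-dysfunction categories used by the JSOG-style upgrade
#: paths (algorithm 2).
ORGAN_DYSFUNCTION_CATEGORIES = (
    "epigastralgia",
    "hellp_syndrome",
    "eclampsia",
    "fgr",
    "renal_dysfunction",
    "hepatic_dysfunction",
)

#: Note-based PE-related conditions recognised by the ACOG-style rules
#: (algorithm 1), alongside the lab-based ones.
PE_CONDITION_NOTE_CATEGORIES = (
    "new_onset_headache",
    "visual_disturbance",
    "pulmonary_edema",
)


def normalize_text(text: str) -> str:
    """Unicode-compatibility normalize, casefold, collapse whitespace.

    NFKC folds full-width Latin (e.g. full-width "HELLP") onto ASCII, so a
    single dictionary entry covers both scripts' typography.
    """
    return " ".join(unicodedata.normalize("NFKC", text).casefold().split())


def _term_pattern(term: str) -> re.Pattern:
    # Literal match; ASCII-alnum edges get boundary lookarounds so that
    # "eclampsia" does not fire inside "preeclampsia".  CJK terms match as
    # plain substrings (no word boundaries exist in Japanese).
    pat = re.escape(term)
    if term and term[0].isascii() and term[0].isalnum():
        pat = r"(?<![0-9a-z])" + pat
    if term and term[-1].isascii() and term[-1].isalnum():
        pat = pat + r"(?![0-9a-z])"
    return re.compile(pat)


@dataclass
class FlagDictionary:
    """Per-category surface-term lists plus global negation configuration.

    ``negation_cues`` are matched in a ``negation_window``-character window
    immediately before a term hit; ``post_negation_cues`` in the same-sized
    window after it (Japanese negation is post-positional: "頭痛なし").
    """

    terms: dict = field(default_factory=dict)  # category -> list of terms
    negation_cues: list = field(default_factory=list)
    post_negation_cues: list = field(default_factory=list)
    negation_window: int = 10

    def __post_init__(self) -> None:
        self.terms = {
            cat: [normalize_text(t) for t in ts] for cat, ts in self.terms.items()
        }
        for cat, ts in self.terms.items():
            cleaned = [t for t in ts if t]
            if not cleaned:
                raise ValueError(f"category {cat!r} has no non-empty terms")
            self.terms[cat] = cleaned
        self.negation_cues = [normalize_text(c) for c in self.negation_cues if normalize_text(c)]
        self.post_negation_cues = [
            normalize_text(c) for c in self.post_negation_cues if normalize_text(c)
        ]
        self._term_patterns = [
            (cat, t, _term_pattern(t)) for cat, ts in self.terms.items() for t in ts
        ]
        self._pre_cues = [_term_pattern(c) for c in self.negation_cues]
        self._post_cues = [_term_pattern(c) for c in self.post_negation_cues]


@dataclass(frozen=True)
class Match:
    category: str
    start: int
    end: int
    text: str
    negated: bool


def mine_note(text: str, dictionary: FlagDictionary) -> list[Match]:
    """All dictionary hits in one note, longest term winning on overlap.

    A hit is negated iff a negation cue occurs within the configured window
    before it (or a post-positional cue within the window after it).
    Offsets refer to the normalized text.
    """
    norm = normalize_text(text)
    raw: list[tuple[str, int, int]] = []
    for cat, _term, pat in dictionary._term_patterns:
        for m in pat.finditer(norm):
            raw.append((cat, m.start(), m.end()))
    # Longest-wins overlap resolution: prefer longer spans, then earlier.
    raw.sort(key=lambda r: (-(r[2] - r[1]), r[1], r[0]))
    kept: list[tuple[str, int, int]] = []
    for cat, s, e in raw:
        if all(e <= ks or s >= ke for _, ks, ke in kept):
            kept.append((cat, s, e))
    w = dictionary.negation_window
    out = []
    for cat, s, e in sorted(kept, key=lambda r: (r[1], r[0])):
        before = norm[max(0, s - w): s]
        after = norm[e: e + w]
        negated = any(p.search(before) for p in dictionary._pre_cues) or any(
            p.search(after) for p in dictionary._post_cues
        )
        out.append(Match(cat, s, e, norm[s:e], negated))
    return out


@dataclass
class FlagState:
    present: bool = False
    earliest_mention_ga: Optional[int] = None
    evidence: list = field(default_factory=list)  # (note index, matched span text)


@dataclass
class SubjectFlags:
    """Note-mined booleans with earliest-mention timing, one per category."""

    states: dict = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "SubjectFlags":
        return cls({cat: FlagState() for cat in FLAG_CATEGORIES})

    def __getitem__(self, category: str) -> FlagState:
        return self.states[category]

    def present(self, category: str) -> bool:
        st = self.states.get(category)
        return bool(st and st.present)

    def earliest(self, category: str) -> Optional[int]:
        st = self.states.get(category)
        return st.earliest_mention_ga if st else None


def aggregate_flags(
    notes: Sequence[tuple[Optional[int], str]], dictionary: FlagDictionary
) -> SubjectFlags:
    """Fold per-note hits into per-subject flags.

    A category is present iff it has at least one non-negated hit anywhere;
    ``earliest_mention_ga`` is the minimum gestational age over dated
    non-negated hits (missing if every such hit is undated).
    """
    flags = SubjectFlags.empty()
    for idx, (ga, text) in enumerate(notes):
        for m in mine_note(text, dictionary):
            if m.negated or m.category not in flags.states:
                continue
            st = flags.states[m.category]
            st.present = True
            st.evidence.append((idx, m.text))
            if ga is not None and (st.earliest_mention_ga is None or ga < st.earliest_mention_ga):
                st.earliest_mention_ga = ga
    return flags


_DEFAULT_TERMS = {
    "history_of_hypertension": [
        "history of hypertension",
        "chronic hypertension",
        "essential hypertension",
        "hypertension prior to pregnancy",
        "高血圧の既往",
        "慢性高血圧",
        "本態性高血圧",
    ],
    "epigastralgia": ["epigastralgia", "epigastric pain", "心窩部痛"],
    "hellp_syndrome": ["hellp syndrome", "hellp", "hellp症候群"],
    "eclampsia": ["eclampsia", "eclamptic seizure", "子癇"],
    "fgr": ["fetal growth restriction", "fgr", "iugr", "胎児発育不全", "子宮内胎児発育遅延"],
    "renal_dysfunction": [
        "renal dysfunction",
        "renal insufficiency",
        "renal impairment",
        "腎機能障害",
    ],
    "hepatic_dysfunction": [
        "hepatic dysfunction",
        "liver dysfunction",
        "elevated transaminases",
        "肝機能障害",
    ],
    "new_onset_headache": [
        "new-onset headache",
        "new onset headache",
        "severe headache",
        "頭痛",
    ],
    "visual_disturbance": ["visual disturbance", "blurred vision", "視覚障害", "眼華閃発"],
    "pulmonary_edema": ["pulmonary edema", "pulmonary oedema", "肺水腫"],
}

_DEFAULT_NEGATION = ["no", "not", "without", "denies", "negative for", "ない"]
_DEFAULT_POST_NEGATION = ["ruled out", "not present", "なし", "認めず", "(-)"]


def default_dictionary() -> FlagDictionary:
    """Bilingual (English/Japanese) seed lexicon.

    The seed lists are intentionally small and editable; the matcher engine,
    not the lexicon, is the stable contract.
    """
    return FlagDictionary(
        terms={k: list(v) for k, v in _DEFAULT_TERMS.items()},
        negation_cues=list(_DEFAULT_NEGATION),
        post_negation_cues=list(_DEFAULT_POST_NEGATION),
        negation_window=10,
    )


def load_dictionary(path) -> FlagDictionary:
    """Load a dictionary from a YAML file.

    Expected keys: ``terms`` (category -> list), ``negation_cues``,
    ``post_negation_cues``, ``negation_window``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return FlagDictionary(
        terms=raw.get("terms", {}),
        negation_cues=raw.get("negation_cues", []),
        post_negation_cues=raw.get("post_negation_cues", []),
        negation_window=int(raw.get("negation_window", 10)),
    )


def dump_dictionary(dictionary: FlagDictionary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "terms": dictionary.terms,
                "negation_cues": dictionary.negation_cues,
                "post_negation_cues": dictionary.post_negation_cues,
                "negation_window": dictionary.negation_window,
            },
            fh,
            allow_unicode=True,
        )
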