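"""Domain types and I/O for longitudinal pregnancy-cohort records.

The cohort layout mirrors how prenatal care data are transcribed in
population cohorts: a per-subject interview record (disease history), a
series of prenatal-checkup visits (gestational age, blood pressure, urine
dipstick, optional labs), a delivery record, and short free-text clinical
notes.  Four delimited files keyed by ``subject_id`` carry these tables;
``SchemaConfig`` maps source column names and dipstick token aliases onto
the canonical schema.

Gestational age is stored as integer days since the last menstrual period;
week W covers days [7W, 7W+7).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal, localcontext
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .notemining import SubjectFlags

logger = logging.getLogger(__name__)

#: Upper bound on plausible gestational age, in days (45 weeks).
MAX_GA_DAYS = 315

LAB_FIELDS = ("platelet_count", "serum_creatinine", "ast", "alt")


class SchemaError(ValueError):
    """A mandatory column is missing or the schema config is inconsistent."""


class UndefinedDenominatorError(ZeroDivisionError):
    """Percentage requested with a zero total."""


class Dipstick(enum.IntEnum):
    """Ordinal urine-protein dipstick grade."""

    NEGATIVE = 0
    TRACE = 1
    PLUS_1 = 2
    PLUS_2 = 3
    PLUS_3 = 4
    PLUS_4 = 5

    def __str__(self) -> str:  # canonical token
        return _CANONICAL_TOKENS[self]


_CANONICAL_TOKENS = {
    Dipstick.NEGATIVE: "negative",
    Dipstick.TRACE: "trace",
    Dipstick.PLUS_1: "1+",
    Dipstick.PLUS_2: "2+",
    Dipstick.PLUS_3: "3+",
    Dipstick.PLUS_4: "4+",
}

_TOKEN_TO_GRADE = {v: k for k, v in _CANONICAL_TOKENS.items()}

#: Widespread shorthand seen in transcribed records; extend via
#: ``SchemaConfig.dipstick_aliases``.
DEFAULT_DIPSTICK_ALIASES = {
    "-": "negative",
    "(-)": "negative",
    "neg": "negative",
    "+-": "trace",
    "±": "trace",
    "+/-": "trace",
    "+": "1+",
    "++": "2+",
    "+++": "3+",
    "++++": "4+",
}


def parse_dipstick(token: str, aliases: Optional[Mapping[str, str]] = None) -> Optional[Dipstick]:
    """Parse a dipstick token into a grade; empty/NA tokens give ``None``.

    Raises ``ValueError`` for a token not covered by the canonical names,
    the default aliases, or the caller-supplied alias map.
    """
    tok = token.strip().lower()
    if tok in ("", "na", "nan", "none"):
        return None
    table = dict(DEFAULT_DIPSTICK_ALIASES)
    if aliases:
        table.update({k.strip().lower(): v for k, v in aliases.items()})
    tok = table.get(tok, tok)
    if tok not in _TOKEN_TO_GRADE:
        raise ValueError(f"unparseable dipstick token {token!r}")
    return _TOKEN_TO_GRADE[tok]


@dataclass
class Visit:
    """One prenatal checkup: BP pair, dipstick grade and optional labs.

    ``labs`` may hold ``platelet_count`` (10^3/uL), ``serum_creatinine``
    (mg/dL), ``ast`` and ``alt`` (U/L).
    """

    gestational_age: int
    sbp: Optional[int] = None
    dbp: Optional[int] = None
    dipstick: Optional[Dipstick] = None
    labs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.gestational_age <= MAX_GA_DAYS:
            raise ValueError(
                f"gestational_age {self.gestational_age} outside (0, {MAX_GA_DAYS}]"
            )
        for name in ("sbp", "dbp"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.sbp is not None and self.dbp is not None and self.dbp >= self.sbp:
            raise ValueError(f"dbp {self.dbp} >= sbp {self.sbp}")

    @property
    def has_bp(self) -> bool:
        return self.sbp is not None and self.dbp is not None


@dataclass
class DeliveryRecord:
    delivery_ga: int
    birth_weight: Optional[int] = None
    infant_sex: str = "unknown"
    live_birth: bool = True
    parity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.live_birth and not 140 <= self.delivery_ga <= MAX_GA_DAYS:
            raise ValueError(
                f"delivery_ga {self.delivery_ga} outside [140, {MAX_GA_DAYS}] for a live birth"
            )
        if self.birth_weight is not None and self.birth_weight <= 0:
            raise ValueError(f"birth_weight must be positive, got {self.birth_weight}")
        if self.infant_sex not in ("male", "female", "unknown"):
            raise ValueError(f"infant_sex {self.infant_sex!r} not in male/female/unknown")
        if self.parity is not None and self.parity < 0:
            raise ValueError("parity must be non-negative")


@dataclass
class SubjectBundle:
    """All per-pregnancy inputs the phenotyping rules consume."""

    subject_id: str
    interview_history_hypertension: bool = False
    visits: list = field(default_factory=list)
    delivery: Optional[DeliveryRecord] = None
    notes: list = field(default_factory=list)  # (ga days or None, text)
    flags: Optional[SubjectFlags] = None


EXCLUSION_REASONS = ("no_delivery_record", "no_bp_pu_data", "no_live_birth", "withdrawn")


@dataclass(frozen=True)
class ExclusionLog:
    subject_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


@dataclass
class SchemaConfig:
    """Column mapping from source files onto the canonical schema.

    Each ``*_columns`` dict maps canonical field name -> source column name.
    Lab columns are optional: leave them out of ``visit_columns`` if absent.
    """

    subjects_file: str = "subjects.csv"
    visits_file: str = "visits.csv"
    delivery_file: str = "delivery.csv"
    notes_file: str = "notes.csv"
    subject_columns: dict = field(
        default_factory=lambda: {
            "subject_id": "subject_id",
            "interview_history_hypertension": "interview_history_hypertension",
        }
    )
    visit_columns: dict = field(
        default_factory=lambda: {
            "subject_id": "subject_id",
            "gestational_age": "gestational_age",
            "sbp": "sbp",
            "dbp": "dbp",
            "dipstick": "dipstick",
            "platelet_count": "platelet_count",
            "serum_creatinine": "serum_creatinine",
            "ast": "ast",
            "alt": "alt",
        }
    )
    delivery_columns: dict = field(
        default_factory=lambda: {
            "subject_id": "subject_id",
            "delivery_ga": "delivery_ga",
            "birth_weight": "birth_weight",
            "infant_sex": "infant_sex",
            "live_birth": "live_birth",
            "parity": "parity",
        }
    )
    note_columns: dict = field(
        default_factory=lambda: {
            "subject_id": "subject_id",
            "gestational_age": "gestational_age",
            "text": "text",
        }
    )
    dipstick_aliases: dict = field(default_factory=dict)


_MANDATORY = {
    "subjects": ("subject_id", "interview_history_hypertension"),
    "visits": ("subject_id", "gestational_age", "sbp", "dbp", "dipstick"),
    "delivery": ("subject_id", "delivery_ga", "live_birth"),
    "notes": ("subject_id", "text"),
}


def _require_columns(df: pd.DataFrame, colmap: Mapping[str, str], table: str) -> None:
    for canonical in _MANDATORY[table]:
        source = colmap.get(canonical, canonical)
        if source not in df.columns:
            raise SchemaError(
                f"{table} file missing mandatory column {source!r} (canonical {canonical!r})"
            )


def _cell(row, col: Optional[str]) -> Optional[str]:
    if col is None or col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    return s if s and s.lower() not in ("nan", "na", "none") else None


def _to_int(s: Optional[str], what: str, where: str) -> Optional[int]:
    if s is None:
        return None
    try:
        return int(float(s))
    except ValueError as exc:
        raise ValueError(f"{where}: unparseable {what} {s!r}") from exc


def _to_float(s: Optional[str]) -> Optional[float]:
    if s is None:
        return None
    return float(s)


def _to_bool(s: Optional[str], default: bool = False) -> bool:
    if s is None:
        return default
    return s.strip().lower() in ("1", "true", "t", "yes", "y")


def _merge_conflicting_visits(a: Visit, b: Visit, issues: Optional[list], sid: str) -> Visit:
    """Same-day visits with conflicting values: keep the higher systolic BP
    pair and the higher dipstick grade (conservative toward detection)."""
    hi, lo = (a, b) if (a.sbp or 0) >= (b.sbp or 0) else (b, a)
    dip = max((v.dipstick for v in (a, b) if v.dipstick is not None), default=None)
    labs = dict(lo.labs)
    labs.update(hi.labs)
    merged = Visit(a.gestational_age, hi.sbp, hi.dbp, dip, labs)
    msg = f"subject {sid}: conflicting duplicate visit at GA {a.gestational_age}; merged conservatively"
    logger.warning(msg)
    if issues is not None:
        issues.append(msg)
    return merged


def read_cohort(
    path: str | Path,
    schema: Optional[SchemaConfig] = None,
    issues: Optional[list] = None,
) -> list[SubjectBundle]:
    """Read the four cohort CSVs under ``path`` into ``SubjectBundle``s.

    Visits are sorted ascending by gestational age; identical duplicate rows
    collapse silently, conflicting same-day rows merge conservatively and
    are reported through ``issues`` (if given) and the module logger.
    Missing mandatory columns raise :class:`SchemaError`; unparseable
    numeric or dipstick cells raise ``ValueError`` naming the row.
    """
    schema = schema or SchemaConfig()
    base = Path(path)

    def _read(name: str) -> pd.DataFrame:
        f = base / name
        if not f.exists():
            return pd.DataFrame()
        return pd.read_csv(f, dtype=str, keep_default_na=False)

    subjects = _read(schema.subjects_file)
    visits = _read(schema.visits_file)
    delivery = _read(schema.delivery_file)
    notes = _read(schema.notes_file)
    if subjects.empty:
        raise SchemaError(f"subjects file {schema.subjects_file!r} missing or empty under {base}")
    _require_columns(subjects, schema.subject_columns, "subjects")
    if not visits.empty:
        _require_columns(visits, schema.visit_columns, "visits")
    if not delivery.empty:
        _require_columns(delivery, schema.delivery_columns, "delivery")
    if not notes.empty:
        _require_columns(notes, schema.note_columns, "notes")

    sc, vc, dc, nc = (
        schema.subject_columns,
        schema.visit_columns,
        schema.delivery_columns,
        schema.note_columns,
    )

    bundles: dict[str, SubjectBundle] = {}
    for _, row in subjects.iterrows():
        sid = _cell(row, sc["subject_id"])
        if sid is None:
            raise ValueError("subjects file: empty subject_id")
        if sid in bundles:
            raise ValueError(f"subjects file: duplicate subject_id {sid!r}")
        bundles[sid] = SubjectBundle(
            subject_id=sid,
            interview_history_hypertension=_to_bool(
                _cell(row, sc["interview_history_hypertension"])
            ),
        )

    def _known(sid: Optional[str], table: str, i: int) -> Optional[SubjectBundle]:
        if sid is None or sid not in bundles:
            msg = f"{table} row {i}: subject {sid!r} not in subjects file; row kept aside"
            logger.warning(msg)
            if issues is not None:
                issues.append(msg)
            return None
        return bundles[sid]

    for i, row in visits.iterrows():
        b = _known(_cell(row, vc["subject_id"]), "visits", i)
        if b is None:
            continue
        where = f"visits row {i}"
        ga = _to_int(_cell(row, vc["gestational_age"]), "gestational_age", where)
        if ga is None:
            raise ValueError(f"{where}: missing gestational_age")
        dip_raw = _cell(row, vc["dipstick"])
        try:
            dip = parse_dipstick(dip_raw, schema.dipstick_aliases) if dip_raw is not None else None
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
        labs = {}
        for lab in LAB_FIELDS:
            val = _to_float(_cell(row, vc.get(lab)))
            if val is not None:
                labs[lab] = val
        b.visits.append(
            Visit(
                gestational_age=ga,
                sbp=_to_int(_cell(row, vc["sbp"]), "sbp", where),
                dbp=_to_int(_cell(row, vc["dbp"]), "dbp", where),
                dipstick=dip,
                labs=labs,
            )
        )

    for i, row in delivery.iterrows():
        b = _known(_cell(row, dc["subject_id"]), "delivery", i)
        if b is None:
            continue
        where = f"delivery row {i}"
        ga = _to_int(_cell(row, dc["delivery_ga"]), "delivery_ga", where)
        if ga is None:
            raise ValueError(f"{where}: missing delivery_ga")
        b.delivery = DeliveryRecord(
            delivery_ga=ga,
            birth_weight=_to_int(_cell(row, dc.get("birth_weight")), "birth_weight", where),
            infant_sex=_cell(row, dc.get("infant_sex")) or "unknown",
            live_birth=_to_bool(_cell(row, dc["live_birth"]), default=True),
            parity=_to_int(_cell(row, dc.get("parity")), "parity", where),
        )

    for i, row in notes.iterrows():
        b = _known(_cell(row, nc["subject_id"]), "notes", i)
        if b is None:
            continue
        ga = _to_int(_cell(row, nc.get("gestational_age")), "gestational_age", f"notes row {i}")
        text = _cell(row, nc["text"]) or ""
        b.notes.append((ga, text))

    for b in bundles.values():
        b.visits = _dedupe_visits(b.visits, issues, b.subject_id)
    return list(bundles.values())


def _dedupe_visits(visits: Sequence[Visit], issues: Optional[list], sid: str) -> list[Visit]:
    by_day: dict[int, Visit] = {}
    for v in sorted(visits, key=lambda v: v.gestational_age):
        prev = by_day.get(v.gestational_age)
        if prev is None:
            by_day[v.gestational_age] = v
        elif prev == v:
            continue  # identical duplicate row
        else:
            by_day[v.gestational_age] = _merge_conflicting_visits(prev, v, issues, sid)
    return [by_day[d] for d in sorted(by_day)]


def write_cohort(bundles: Iterable[SubjectBundle], path: str | Path,
                 schema: Optional[SchemaConfig] = None) -> None:
    """Write bundles back to the four-CSV layout (inverse of ``read_cohort``)."""
    schema = schema or SchemaConfig()
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    subj_rows, visit_rows, deliv_rows, note_rows = [], [], [], []
    for b in bundles:
        subj_rows.append(
            {
                "subject_id": b.subject_id,
                "interview_history_hypertension": str(b.interview_history_hypertension).lower(),
            }
        )
        for v in b.visits:
            row = {
                "subject_id": b.subject_id,
                "gestational_age": v.gestational_age,
                "sbp": "" if v.sbp is None else v.sbp,
                "dbp": "" if v.dbp is None else v.dbp,
                "dipstick": "" if v.dipstick is None else str(v.dipstick),
            }
            for lab in LAB_FIELDS:
                row[lab] = v.labs.get(lab, "")
            visit_rows.append(row)
        if b.delivery is not None:
            d = b.delivery
            deliv_rows.append(
                {
                    "subject_id": b.subject_id,
                    "delivery_ga": d.delivery_ga,
                    "birth_weight": "" if d.birth_weight is None else d.birth_weight,
                    "infant_sex": d.infant_sex,
                    "live_birth": str(d.live_birth).lower(),
                    "parity": "" if d.parity is None else d.parity,
                }
            )
        for ga, text in b.notes:
            note_rows.append(
                {"subject_id": b.subject_id, "gestational_age": "" if ga is None else ga, "text": text}
            )
    pd.DataFrame(subj_rows).to_csv(base / schema.subjects_file, index=False)
    cols = ["subject_id", "gestational_age", "sbp", "dbp", "dipstick", *LAB_FIELDS]
    pd.DataFrame(visit_rows, columns=cols).to_csv(base / schema.visits_file, index=False)
    pd.DataFrame(
        deliv_rows,
        columns=["subject_id", "delivery_ga", "birth_weight", "infant_sex", "live_birth", "parity"],
    ).to_csv(base / schema.delivery_file, index=False)
    pd.DataFrame(note_rows, columns=["subject_id", "gestational_age", "text"]).to_csv(
        base / schema.notes_file, index=False
    )


def apply_inclusion_filters(
    bundles: Sequence[SubjectBundle],
    withdrawn_ids: Iterable[str] = (),
) -> tuple[list[SubjectBundle], list[ExclusionLog]]:
    """Study-inclusion filter.

    A subject is included iff it has a delivery record, at least one visit
    with a BP pair and at least one dipstick value, a live birth, and did
    not withdraw.  Every exclusion is logged with all applicable reasons.
    """
    withdrawn = set(withdrawn_ids)
    included: list[SubjectBundle] = []
    log: list[ExclusionLog] = []
    for b in bundles:
        reasons = []
        if b.delivery is None:
            reasons.append("no_delivery_record")
        if not (any(v.has_bp for v in b.visits) and any(v.dipstick is not None for v in b.visits)):
            reasons.append("no_bp_pu_data")
        if b.delivery is not None and not b.delivery.live_birth:
            reasons.append("no_live_birth")
        if b.subject_id in withdrawn:
            reasons.append("withdrawn")
        if reasons:
            log.extend(ExclusionLog(b.subject_id, r) for r in reasons)
        else:
            included.append(b)
    return included, log


def format_percentage(count: int, total: int) -> float:
    """``100 * count / total`` rounded half-up to two decimals.

    Half-up (not banker's) rounding reproduces conventional cohort-table
    reporting, e.g. 1813/22452 -> 8.0750... -> 8.08.
    """
    if total == 0:
        raise UndefinedDenominatorError("total must be positive")
    if count < 0 or total < 0 or count > total:
        raise ValueError(f"need 0 <= count <= total, got count={count}, total={total}")
    with localcontext() as ctx:
        ctx.prec = 50
        q = (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    return float(q)
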