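"""Validation of phenotyped labels against reference-standard diagnoses.

The reference standard is a clinician chart review delivered as a simple
CSV of (subject_id, diagnosed label).  Each subgroup is evaluated in a
binary one-vs-rest manner; aggregate targets (HDP, GH, SPE, PE) pool their
constituent fine labels.  A metric whose denominator is zero is reported as
not-applicable (``None``), mirroring how validation tables handle strata
with no diagnosed cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

#: Row order of the metric tables.
TABLE_LABELS = (
    "HDP", "GH", "GH_EO", "GH_LO", "SPE", "SPE_EO", "SPE_LO",
    "PE", "PE_EO", "PE_LO", "CH", "NT",
)

#: Fine labels belonging to each evaluable target; coarse diagnosis labels
#: (e.g. a chart review recording just "PE") count toward their aggregates.
_TARGET_MEMBERS = {
    "HDP": {"GH", "GH_EO", "GH_LO", "SPE", "SPE_EO", "SPE_LO", "PE", "PE_EO", "PE_LO"},
    "GH": {"GH", "GH_EO", "GH_LO"},
    "GH_EO": {"GH_EO"},
    "GH_LO": {"GH_LO"},
    "SPE": {"SPE", "SPE_EO", "SPE_LO"},
    "SPE_EO": {"SPE_EO"},
    "SPE_LO": {"SPE_LO"},
    "PE": {"PE", "PE_EO", "PE_LO"},
    "PE_EO": {"PE_EO"},
    "PE_LO": {"PE_LO"},
    "CH": {"CH"},
    "NT": {"NT"},
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricRow:
    label: str
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    counts: Optional[ConfusionCounts] = None


def binarize(labels: Mapping[str, str], target: str) -> dict:
    """Per-subject booleans for one-vs-rest evaluation of ``target``."""
    if target not in _TARGET_MEMBERS:
        raise ValueError(f"unknown target label {target!r}")
    members = _TARGET_MEMBERS[target]
    return {sid: lab in members for sid, lab in labels.items()}


def confusion(pred: Sequence[bool], truth: Sequence[bool]) -> ConfusionCounts:
    """Tally a boolean prediction vector against truth (aligned by position)."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(truth)}")
    tp = fp = tn = fn = 0
    for p, y in zip(pred, truth):
        if p and y:
            tp += 1
        elif p and not y:
            fp += 1
        elif not p and y:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts, label: str = "") -> MetricRow:
    """The five validation metrics; zero denominators give not-applicable."""
    return MetricRow(
        label=label,
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        accuracy=_ratio(c.tp + c.tn, c.n),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        counts=c,
    )


@dataclass(frozen=True)
class LabelDiscordance:
    subject_id: str
    predicted: str
    diagnosed: str


def evaluate_all(
    pred: Mapping[str, str], truth: Mapping[str, str]
) -> tuple[list[MetricRow], list[LabelDiscordance]]:
    """One metric row per table label, plus the discordant-subject ledger."""
    if set(pred) != set(truth):
        raise ValueError("subject sets differ between predictions and diagnoses")
    sids = sorted(pred)
    rows = []
    for target in TABLE_LABELS:
        p = binarize(pred, target)
        y = binarize(truth, target)
        rows.append(metrics(confusion([p[s] for s in sids], [y[s] for s in sids]), target))
    ledger = [
        LabelDiscordance(s, pred[s], truth[s]) for s in sids if pred[s] != truth[s]
    ]
    return rows, ledger


def round_metric(value: Optional[float]) -> Optional[float]:
    """Display rounding: two decimals, half-up; not-applicable passes through."""
    if value is None:
        return None
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def metric_table(rows: Sequence[MetricRow]):
    """Rows as a display-ready pandas DataFrame (NA rendered as '-')."""
    import pandas as pd

    def cell(v):
        return "-" if v is None else f"{round_metric(v):.2f}"

    return pd.DataFrame(
        [
            {
                "label": r.label,
                "PPV": cell(r.ppv),
                "NPV": cell(r.npv),
                "Accuracy": cell(r.accuracy),
                "Sensitivity": cell(r.sensitivity),
                "Specificity": cell(r.specificity),
            }
            for r in rows
        ]
    )
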