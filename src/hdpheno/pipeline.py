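"""End-to-end phenotyping: note mining -> light-for-date -> rule engines."""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .classify import PhenotypeResult, Thresholds, classify_algorithm1, classify_algorithm2
from .cohort import SubjectBundle
from .lfd import default_lfd_table, is_light_for_date
from .notemining import FlagDictionary, aggregate_flags, default_dictionary


def prepare_bundles(
    bundles: Iterable[SubjectBundle], dictionary: Optional[FlagDictionary] = None
) -> None:
    """Mine each bundle's notes into ``SubjectFlags`` (in place, idempotent)."""
    dictionary = dictionary or default_dictionary()
    for b in bundles:
        if b.flags is None:
            b.flags = aggregate_flags(b.notes, dictionary)


def compute_lfd(
    bundle: SubjectBundle,
    table: Optional[pd.DataFrame] = None,
    percentile: int = 10,
) -> bool:
    """Light-for-date status of a bundle; missing delivery data gives False."""
    d = bundle.delivery
    if d is None or d.birth_weight is None:
        return False
    return is_light_for_date(d.birth_weight, d.delivery_ga, d.infant_sex, table, percentile)


def phenotype_cohort(
    bundles: Sequence[SubjectBundle],
    thresholds: Optional[Thresholds] = None,
    algorithm: int = 1,
    dictionary: Optional[FlagDictionary] = None,
    lfd_table: Optional[pd.DataFrame] = None,
) -> dict:
    """Classify every bundle; returns ``{subject_id: PhenotypeResult}``."""
    t = thresholds or Thresholds()
    if algorithm not in (1, 2):
        raise ValueError("algorithm must be 1 or 2")
    prepare_bundles(bundles, dictionary)
    if algorithm == 2 and lfd_table is None:
        lfd_table = default_lfd_table()
    out = {}
    for b in bundles:
        if algorithm == 1:
            out[b.subject_id] = classify_algorithm1(b, t)
        else:
            out[b.subject_id] = classify_algorithm2(
                b, t, lfd=compute_lfd(b, lfd_table, t.lfd_percentile)
            )
    return out


def label_recovery(results: Mapping[str, PhenotypeResult], truth_labels: Mapping[str, str]) -> float:
    """Fraction of subjects whose assigned label equals the truth label."""
    if set(results) != set(truth_labels):
        raise ValueError("subject sets differ between results and truth")
    if not results:
        return float("nan")
    hits = sum(1 for sid, r in results.items() if r.label == truth_labels[sid])
    return hits / len(results)
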