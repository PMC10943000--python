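"""Summary tables and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from typing import Mapping, Optional

import pandas as pd

from .cohort import format_percentage

logger = logging.getLogger(__name__)


def _pct(count: int, total: int) -> Optional[float]:
    return None if total == 0 else format_percentage(count, total)


def table1_summary(labels: Mapping[str, str]) -> pd.DataFrame:
    """Cohort-level subgroup counts in the conventional table shape.

    GH/SPE/PE rows carry early-/late-onset columns; chronic hypertension
    and normotensive are single-column rows; a Total row closes the table.
    Percentages are of the included-cohort size, half-up at two decimals.
    """
    total = len(labels)
    if total == 0:
        logger.warning("empty cohort: summary has Total 0 and no percentages")
    counts: dict = {}
    for lab in labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    rows = []
    for grp in ("GH", "SPE", "PE"):
        eo, lo = counts.get(f"{grp}_EO", 0), counts.get(f"{grp}_LO", 0)
        rows.append(
            {
                "group": grp,
                "eo_count": eo, "eo_pct": _pct(eo, total) if total else None,
                "lo_count": lo, "lo_pct": _pct(lo, total) if total else None,
                "count": eo + lo, "pct": _pct(eo + lo, total) if total else None,
            }
        )
    for grp, name in (("CH", "CH"), ("NT", "Normotensive")):
        c = counts.get(grp, 0)
        rows.append(
            {
                "group": name, "eo_count": None, "eo_pct": None,
                "lo_count": None, "lo_pct": None,
                "count": c, "pct": _pct(c, total) if total else None,
            }
        )
    rows.append(
        {
            "group": "Total", "eo_count": None, "eo_pct": None,
            "lo_count": None, "lo_pct": None, "count": total,
            "pct": _pct(total, total) if total else None,
        }
    )
    return pd.DataFrame(rows)


def run_manifest(config: Mapping, counts: Mapping) -> dict:
    """Machine-readable record sufficient to reproduce a run.

    Contains a canonical-JSON hash of the effective configuration, the
    package version, and headline counts.  Deliberately timestamp-free so
    that identical runs produce identical artifacts.
    """
    from . import __version__

    canonical = json.dumps(config, sort_keys=True, ensure_ascii=False, default=str)
    return {
        "package": "hdpheno",
        "version": __version__,
        "config": json.loads(canonical),
        "config_sha256": hashlib.sha256(canonical.encode("utf-8")).hexdigest(),
        "counts": dict(counts),
    }
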