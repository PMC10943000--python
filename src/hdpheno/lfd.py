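"""Light-for-date (LFD) assessment from a birth-weight percentile table.

An infant is light-for-date when its birth weight falls strictly below a
percentile cutoff (default: 10th) for gestational week and sex.  The
reference table is a CSV with columns ``week, sex, p3, p10, p50, p90, p97``
(grams); users supply their population's standard via ``load_lfd_table``.

The table shipped with the package (``data/lfd_reference_synthetic.csv``)
is SYNTHETIC: it is generated from a smooth parametric growth model
(piecewise-linear mean weight by week, sex-scaled, normal spread) and is a
stand-in for a population reference, adequate for exercising the lookup and
for simulation, not for clinical use.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

PERCENTILE_COLUMNS = ("p3", "p10", "p50", "p90", "p97")

#: z-scores of the tabulated percentiles under a normal spread model.
_Z = {"p3": -1.8808, "p10": -1.2816, "p50": 0.0, "p90": 1.2816, "p97": 1.8808}

# Anchor points (completed week, mean grams) for the synthetic male growth
# curve; intermediate weeks are linearly interpolated.
_ANCHOR_WEEKS = np.array([22.0, 24.0, 28.0, 32.0, 36.0, 40.0, 42.0])
_ANCHOR_MEANS = np.array([450.0, 650.0, 1150.0, 1800.0, 2550.0, 3150.0, 3250.0])
_FEMALE_SCALE = 0.965


class LfdCoverageError(KeyError):
    """The percentile table does not cover the requested week/sex stratum."""


def growth_model(week: float, sex: str) -> tuple[float, float]:
    """Synthetic (mean, sd) birth weight in grams for a gestational week."""
    mean = float(np.interp(week, _ANCHOR_WEEKS, _ANCHOR_MEANS))
    if sex == "female":
        mean *= _FEMALE_SCALE
    sd = 60.0 + 0.09 * mean
    return mean, sd


def build_synthetic_lfd_table(weeks=range(22, 43)) -> pd.DataFrame:
    """Generate the synthetic percentile reference table."""
    rows = []
    for sex in ("male", "female"):
        for w in weeks:
            mean, sd = growth_model(w, sex)
            row = {"week": int(w), "sex": sex}
            for col, z in _Z.items():
                row[col] = int(round(mean + z * sd))
            rows.append(row)
    return pd.DataFrame(rows, columns=["week", "sex", *PERCENTILE_COLUMNS])


def load_lfd_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"week", "sex"}.difference(df.columns)
    if missing:
        raise ValueError(f"LFD table missing columns {sorted(missing)}")
    if not any(c in df.columns for c in PERCENTILE_COLUMNS):
        raise ValueError("LFD table has no percentile columns (p3/p10/p50/p90/p97)")
    return df


def default_lfd_table() -> pd.DataFrame:
    """The shipped synthetic reference table."""
    with resources.as_file(
        resources.files("hdpheno").joinpath("data/lfd_reference_synthetic.csv")
    ) as f:
        return load_lfd_table(f)


def is_light_for_date(
    birth_weight: float,
    delivery_ga: int,
    sex: str,
    table: Optional[pd.DataFrame] = None,
    percentile: int = 10,
) -> bool:
    """True iff ``birth_weight`` is strictly below the percentile cutoff
    for the (completed gestational week, sex) stratum.

    Unknown sex falls back to the male column (the higher cutoffs —
    conservative toward detection).  A week outside the table raises
    :class:`LfdCoverageError`.
    """
    if table is None:
        table = default_lfd_table()
    col = f"p{percentile}"
    if col not in table.columns:
        raise ValueError(f"percentile column {col!r} not in table")
    week = delivery_ga // 7
    lookup_sex = sex if sex in ("male", "female") else "male"
    rows = table[(table["week"] == week) & (table["sex"] == lookup_sex)]
    if rows.empty:
        raise LfdCoverageError(f"no table row for week {week}, sex {lookup_sex!r}")
    return birth_weight < float(rows.iloc[0][col])
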