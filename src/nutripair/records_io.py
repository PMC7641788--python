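"""Reading, writing and aggregating per-item food-diary tables.

The interchange format is a flat CSV with one row per consumed food item::

    participant_id,phase,day,item_label,portion_g,
    ref_energy,...,ref_sodium,app_energy,...,app_sodium

Reference-database (``ref_``) values are complete for every row; app
(``app_``) values may be blank, which models food items whose consumer-app
database entry lacks that nutrient.  Blank app cells are preserved as
missing (NaN), never coerced to zero, so the synthetic generator and the
cleaner can audit them — but they contribute 0 when daily intakes are
summed, because that is how incomplete app rows enter real app totals.

Diary tables are held as pandas DataFrames; :class:`FoodEntry` is a
row-level convenience for building small tables by hand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .nutrients import (
    APP_COLUMNS,
    NUTRIENT_COLUMNS,
    NUTRIENTS,
    PHASES,
    REF_COLUMNS,
    Nutrient,
    app_col,
    ref_col,
)

META_COLUMNS = ["participant_id", "phase", "day", "item_label", "portion_g"]
DIARY_COLUMNS = META_COLUMNS + NUTRIENT_COLUMNS

#: Sentinel for an absent app nutrient value.
MISSING = float("nan")


@dataclass
class FoodEntry:
    """One consumed food item with paired nutrient values under two databases."""

    participant_id: str
    phase: str
    day: int
    item_label: str
    portion_g: float | None
    ref_values: dict[Nutrient, float]
    app_values: dict[Nutrient, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row: dict = {
            "participant_id": self.participant_id,
            "phase": self.phase,
            "day": self.day,
            "item_label": self.item_label,
            "portion_g": math.nan if self.portion_g is None else self.portion_g,
        }
        for n in NUTRIENTS:
            row[ref_col(n)] = self.ref_values[n]
            row[app_col(n)] = self.app_values.get(n, math.nan)
        return row


def entries_to_frame(entries: list[FoodEntry]) -> pd.DataFrame:
    """Assemble FoodEntry objects into a diary table (row order preserved)."""
    if not entries:
        return pd.DataFrame(columns=DIARY_COLUMNS)
    return pd.DataFrame([e.to_row() for e in entries], columns=DIARY_COLUMNS)


def frame_to_entries(diary: pd.DataFrame) -> list[FoodEntry]:
    """Inverse of :func:`entries_to_frame`; NaN app cells become absent values."""
    out = []
    for _, r in diary.iterrows():
        out.append(
            FoodEntry(
                participant_id=str(r["participant_id"]),
                phase=str(r["phase"]),
                day=int(r["day"]),
                item_label=str(r["item_label"]),
                portion_g=None if pd.isna(r["portion_g"]) else float(r["portion_g"]),
                ref_values={n: float(r[ref_col(n)]) for n in NUTRIENTS},
                app_values={
                    n: float(r[app_col(n)])
                    for n in NUTRIENTS
                    if not pd.isna(r[app_col(n)])
                },
            )
        )
    return out


def validate_diary(diary: pd.DataFrame) -> pd.DataFrame:
    """Check schema and value invariants of a diary table.

    Raises
    ------
    SchemaError
        if a required column is absent (the message names it).
    ValidationError
        naming the first offending row (1-based data-row number) for
        negative amounts, missing reference values, or invalid phase/day.
    """
    for c in DIARY_COLUMNS:
        if c not in diary.columns:
            raise SchemaError(f"required column {c!r} is missing")
    diary = diary[DIARY_COLUMNS].copy()
    if len(diary) == 0:
        return diary

    diary["participant_id"] = diary["participant_id"].astype(str)
    diary["phase"] = diary["phase"].astype(str)

    bad_phase = ~diary["phase"].isin(PHASES)
    if bad_phase.any():
        i = int(np.flatnonzero(bad_phase)[0])
        raise ValidationError(
            f"row {i + 1}: phase {diary['phase'].iloc[i]!r} not in {PHASES}"
        )
    day = pd.to_numeric(diary["day"], errors="coerce")
    if day.isna().any() or (day < 1).any() or (day != day.round()).any():
        i = int(np.flatnonzero(day.isna() | (day < 1) | (day != day.round()))[0])
        raise ValidationError(f"row {i + 1}: day must be an integer >= 1")
    diary["day"] = day.astype(int)

    for c in ["portion_g"] + NUTRIENT_COLUMNS:
        vals = pd.to_numeric(diary[c], errors="coerce")
        coerced_bad = vals.isna() & diary[c].notna()
        if coerced_bad.any():
            i = int(np.flatnonzero(coerced_bad)[0])
            raise ValidationError(f"row {i + 1}: non-numeric value in column {c!r}")
        neg = vals < 0
        if neg.any():
            i = int(np.flatnonzero(neg)[0])
            raise ValidationError(
                f"row {i + 1}: negative amount {vals.iloc[i]} in column {c!r}"
            )
        diary[c] = vals.astype(float)

    for c in REF_COLUMNS:
        if diary[c].isna().any():
            i = int(np.flatnonzero(diary[c].isna())[0])
            raise ValidationError(
                f"row {i + 1}: reference value {c!r} is missing; "
                "reference nutrient columns must be complete"
            )
    return diary


def read_diary_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-item diary CSV into a validated diary table.

    Blank app cells are kept as NaN (missing), not zero; row order is
    preserved.  See :func:`validate_diary` for the errors raised.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "phase": str, "item_label": str})
    return validate_diary(df)


def write_diary_csv(diary: pd.DataFrame, path: str | Path) -> None:
    """Write a diary table; missing app values become blank cells."""
    diary[DIARY_COLUMNS].to_csv(path, index=False)


def aggregate_daily_means(diary: pd.DataFrame, phase: str) -> pd.DataFrame:
    """Aggregate a diary table to per-participant mean daily intakes.

    For each participant in *phase*, sums item values per nutrient and
    method and divides by the number of *distinct* observed days (diaries
    need not cover consecutive days, and one diary may have fewer days than
    the others).  Missing app values contribute 0 to the sums.

    Returns a DataFrame indexed by participant_id with columns
    ``phase``, ``n_days``, then ``ref_<nutrient>`` and ``app_<nutrient>``
    mean daily amounts.  An empty phase yields an empty frame with a warning.
    """
    sub = diary[diary["phase"] == phase]
    if len(sub) == 0:
        warnings.warn(f"no diary entries for phase {phase!r}; returning empty result")
        out = pd.DataFrame(columns=["phase", "n_days"] + NUTRIENT_COLUMNS)
        out.index.name = "participant_id"
        return out
    g = sub.groupby("participant_id", sort=True)
    n_days = g["day"].nunique().rename("n_days")
    sums = g[NUTRIENT_COLUMNS].sum()  # NaN app cells count as 0
    means = sums.div(n_days, axis=0)
    out = pd.concat([n_days, means], axis=1)
    out.insert(0, "phase", phase)
    out.index.name = "participant_id"
    return out
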