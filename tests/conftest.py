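"""Shared fixtures: small hand-built diaries and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nutripair import FoodEntry, SyntheticConfig, entries_to_frame, generate_cohort
from nutripair.nutrients import NUTRIENTS, Nutrient


def make_entry(
    pid: str,
    phase: str = "T1",
    day: int = 1,
    label: str = "item",
    energy: float = 500.0,
    app_energy: float | None = None,
    **overrides,
) -> FoodEntry:
    """A FoodEntry with plausible values; app defaults to a copy of ref."""
    ref = {
        Nutrient.ENERGY: energy,
        Nutrient.CARBOHYDRATE: energy * 0.12,
        Nutrient.FAT: energy * 0.04,
        Nutrient.PROTEIN: energy * 0.04,
        Nutrient.FIBER: energy * 0.01,
        Nutrient.SUGAR: energy * 0.05,
        Nutrient.CHOLESTEROL: energy * 0.12,
        Nutrient.SODIUM: energy * 1.3,
    }
    for k, v in overrides.items():
        ref[Nutrient(k)] = v
    app = dict(ref)
    if app_energy is not None:
        app[Nutrient.ENERGY] = app_energy
    return FoodEntry(
        participant_id=pid,
        phase=phase,
        day=day,
        item_label=label,
        portion_g=100.0,
        ref_values=ref,
        app_values=app,
    )


def identity_config(seed: int = 0, **kw) -> SyntheticConfig:
    """Generator config whose app channel is the identity (app == ref)."""
    base = dict(
        n_participants=10,
        n_days=2,
        items_per_day=(4, 6),
        app_noise_sd={n: 0.0 for n in NUTRIENTS},
        app_participant_noise_sd={n: 0.0 for n in NUTRIENTS},
        app_bias={n: 1.0 for n in NUTRIENTS},
        missing_prob={n: 0.0 for n in NUTRIENTS},
        contamination_rate=0.0,
        seed=seed,
    )
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.fixture
def identity_cohort() -> pd.DataFrame:
    return generate_cohort(identity_config(seed=11))


@pytest.fixture
def small_default_cohort() -> pd.DataFrame:
    """Reduced-size cohort with the default error channel."""
    return generate_cohort(
        SyntheticConfig(seed=21, n_participants=15, n_days=2, items_per_day=(5, 8))
    )


@pytest.fixture
def toy_diary() -> pd.DataFrame:
    """Three participants, two days, hand-enterable numbers."""
    entries = []
    for i, pid in enumerate(["A", "B", "C"]):
        for day in (1, 2):
            for j in range(2):
                entries.append(
                    make_entry(
                        pid,
                        day=day,
                        label=f"item_{j + 1}",
                        energy=400.0 + 100.0 * i + 50.0 * day + 10.0 * j,
                    )
                )
    return entries_to_frame(entries)
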