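"""Limit learner vs a brute-force oracle, and cleaner behavior."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nutripair import (
    DegenerateDataError,
    LimitSet,
    SyntheticConfig,
    apply_limits,
    default_grid,
    entries_to_frame,
    generate_cohort,
    learn_limit,
    learn_limits,
)
from nutripair.nutrients import NUTRIENTS, Nutrient, app_col, ref_col

from .conftest import identity_config, make_entry


def naive_learn_limit(train: pd.DataFrame, nutrient: Nutrient, grid, assoc: str):
    """Independent re-derivation: full recomputation per candidate via pandas."""
    n_days = train.groupby("participant_id")["day"].nunique()
    ref_mean = train.groupby("participant_id")[ref_col(nutrient)].sum() / n_days
    best, best_limit = -np.inf, None
    for cand in grid:  # ascending, so >= keeps the largest tied candidate
        col = train[app_col(nutrient)]
        included = train[col.notna() & (col <= cand)]
        app_sum = (
            included.groupby("participant_id")[app_col(nutrient)]
            .sum()
            .reindex(n_days.index, fill_value=0.0)
        )
        app_mean = app_sum / n_days
        if app_mean.std(ddof=1) == 0 or ref_mean.std(ddof=1) == 0:
            continue
        r = app_mean.corr(ref_mean, method=assoc)
        if r >= best:
            best, best_limit = r, cand
    return best_limit


def test_no_value_above_smallest_candidate_returns_top_of_grid(identity_cohort):
    top = float(identity_cohort[app_col(Nutrient.ENERGY)].max())
    grid = np.linspace(top + 1.0, top + 100.0, 10)
    res = learn_limit(identity_cohort, Nutrient.ENERGY, grid=grid)
    assert res.limit == pytest.approx(grid[-1])
    assert (res.trace["n_removed"] == 0).all()


def test_planted_energy_error_is_bracketed_and_matches_oracle():
    """A single x100 energy entry at 45000 kcal: the learned limit separates
    it from the clean maximum and equals the exhaustive-grid argmax."""
    cohort = generate_cohort(identity_config(seed=31, n_participants=12))
    cohort = cohort.reset_index(drop=True)
    clean_max = float(cohort[app_col(Nutrient.ENERGY)].max())
    cohort.loc[3, app_col(Nutrient.ENERGY)] = 45000.0
    grid = default_grid(cohort, Nutrient.ENERGY, n_steps=100)
    res = learn_limit(cohort, Nutrient.ENERGY, grid=grid, assoc="pearson")
    assert clean_max < res.limit < 45000.0
    assert res.limit == naive_learn_limit(cohort, Nutrient.ENERGY, grid, "pearson")


def test_hand_built_carbohydrate_flip():
    """Six participants; one aberrant 500 g carbohydrate item destroys the
    correlation, so the learned limit lands in [clean max, 500)."""
    entries = []
    carbs = [30.0, 40.0, 50.0, 60.0, 70.0, 80.0]
    for i, c in enumerate(carbs):
        entries.append(make_entry(f"P{i}", day=1, label="meal", carbohydrate=c))
    frame = entries_to_frame(entries)
    # participant P0 logs one extra item whose app carbohydrate is absurd
    extra = make_entry("P0", day=1, label="typo", carbohydrate=5.0)
    extra.app_values[Nutrient.CARBOHYDRATE] = 500.0
    frame = pd.concat([frame, entries_to_frame([extra])], ignore_index=True)
    grid = np.linspace(30.0, 500.0, 95)
    res = learn_limit(frame, Nutrient.CARBOHYDRATE, grid=grid, assoc="pearson")
    assert 80.0 <= res.limit < 500.0
    assert res.limit == naive_learn_limit(frame, Nutrient.CARBOHYDRATE, grid, "pearson")
    full = res.trace["correlation"].iloc[-1]  # no exclusion
    best = res.trace["correlation"].max()
    assert full < 0.5 < best


@pytest.mark.parametrize("seed", [41, 42, 43])
def test_learner_equals_bruteforce_on_contaminated_cohorts(seed):
    cfg = SyntheticConfig(
        seed=seed, n_participants=12, n_days=2, items_per_day=(4, 7), contamination_rate=0.05
    )
    train = generate_cohort(cfg)
    train = train[train["phase"] == "T1"]
    for nutrient, assoc in [(Nutrient.ENERGY, "pearson"), (Nutrient.SODIUM, "spearman")]:
        grid = default_grid(train, nutrient, n_steps=60)
        res = learn_limit(train, nutrient, grid=grid, assoc=assoc)
        assert res.limit == naive_learn_limit(train, nutrient, grid, assoc)


def test_identity_cohort_learns_top_of_grid_everywhere(identity_cohort):
    limit_set, details = learn_limits(identity_cohort)
    for n in NUTRIENTS:
        assert limit_set[n] == pytest.approx(float(identity_cohort[app_col(n)].max()))
    cleaned, report = apply_limits(identity_cohort, limit_set)
    assert report.total_removed == 0
    assert report.fraction_items_affected == 0.0


def test_training_correlation_never_worse_than_uncleaned():
    """argmax construction: the learned limit's correlation >= the
    no-cleaning correlation (top of grid) on the training phase."""
    cfg = SyntheticConfig(seed=51, n_participants=15, n_days=2, contamination_rate=0.05)
    train = generate_cohort(cfg)
    train = train[train["phase"] == "T1"]
    _, details = learn_limits(train)
    for n, res in details.items():
        at_best = res.trace.loc[res.trace["candidate"] == res.limit, "correlation"].iloc[0]
        no_cleaning = res.trace["correlation"].iloc[-1]
        assert at_best >= no_cleaning - 1e-12


def test_limit_set_yaml_round_trip(tmp_path):
    limits = LimitSet({n: float(i + 1) * 10.0 for i, n in enumerate(NUTRIENTS)})
    limits.limits[Nutrient.SODIUM] = float("inf")
    path = tmp_path / "limits.yaml"
    limits.to_yaml(path)
    back = LimitSet.from_yaml(path)
    assert back.limits == limits.limits


def test_apply_known_carbohydrate_limit():
    """Five items with app carbohydrate {20, 40, 90, 96, 300} g against an
    upper limit of 95 g per portion: exactly two values removed."""
    entries = []
    for j, c in enumerate([20.0, 40.0, 90.0, 96.0, 300.0]):
        e = make_entry("P1", day=1, label=f"i{j}")
        e.app_values[Nutrient.CARBOHYDRATE] = c
        entries.append(e)
    frame = entries_to_frame(entries)
    cleaned, report = apply_limits(frame, LimitSet({Nutrient.CARBOHYDRATE: 95.0}))
    assert report.removed[Nutrient.CARBOHYDRATE] == 2
    assert report.items_affected == 2
    assert cleaned[app_col(Nutrient.CARBOHYDRATE)].isna().sum() == 2
    # other nutrients untouched, items retained
    assert len(cleaned) == 5
    assert cleaned[app_col(Nutrient.FAT)].notna().all()


def test_infinite_limits_remove_nothing(small_default_cohort):
    limits = LimitSet({n: float("inf") for n in NUTRIENTS})
    cleaned, report = apply_limits(small_default_cohort, limits)
    assert report.total_removed == 0
    pd.testing.assert_frame_equal(cleaned, small_default_cohort)


def test_apply_limits_is_idempotent(small_default_cohort):
    limit_set, _ = learn_limits(small_default_cohort[small_default_cohort["phase"] == "T1"])
    once, r1 = apply_limits(small_default_cohort, limit_set)
    twice, r2 = apply_limits(once, limit_set)
    pd.testing.assert_frame_equal(once, twice)
    assert r2.total_removed == 0


def test_removal_count_monotone_in_limit(small_default_cohort):
    col = app_col(Nutrient.ENERGY)
    vals = small_default_cohort[col].dropna()
    previous = -1
    for q in (0.9, 0.7, 0.5, 0.3):
        lim = float(vals.quantile(q))
        _, report = apply_limits(small_default_cohort, LimitSet({Nutrient.ENERGY: lim}))
        assert report.removed[Nutrient.ENERGY] >= previous
        previous = report.removed[Nutrient.ENERGY]


def test_degenerate_nutrient_yields_infinite_limit_with_warning():
    frame = entries_to_frame(
        [make_entry(f"P{i}", day=1, energy=100.0 * (i + 1)) for i in range(5)]
    )
    frame[app_col(Nutrient.FIBER)] = 2.0  # constant app fiber: no usable signal
    with pytest.warns(UserWarning, match="fiber"):
        limit_set, _ = learn_limits(frame)
    assert np.isinf(limit_set[Nutrient.FIBER])


def test_too_few_participants_raise():
    frame = entries_to_frame([make_entry("P1"), make_entry("P2")])
    with pytest.raises(DegenerateDataError, match="participants"):
        learn_limit(frame, Nutrient.ENERGY, grid=np.array([100.0, 200.0]))
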