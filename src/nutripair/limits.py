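"""Learning and applying per-nutrient upper limits per food portion.

Consumer-app food databases are partially user-entered and contain gross
errors (unit mistakes, misplaced decimal points) that inflate single item
values by an order of magnitude or more.  The cleaner learns, on a training
phase, one upper limit per nutrient per food portion: candidate limits are
swept in ascending order, app values above the candidate are excluded from
the daily sums, participant-level mean daily intakes are recomputed, and
the cross-method correlation (app vs reference) is recorded.  The limit is
the candidate that maximizes this correlation — the best compromise between
removing erroneous values and keeping correct ones.  Ties are broken toward
the largest tied candidate, which minimizes false-positive removals.

Learned limits are then applied to a held-out phase: app values strictly
above the limit are set to missing (the item itself is kept, other
nutrients untouched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import DataError, DegenerateDataError
from .nutrients import DEFAULT_ASSOC, NUTRIENTS, UNITS, Nutrient, app_col, parse_nutrient, ref_col


@dataclass
class LimitSet:
    """Learned per-nutrient upper limit per food portion (+inf = no limit)."""

    limits: dict[Nutrient, float] = field(default_factory=dict)

    def __getitem__(self, nutrient: Nutrient) -> float:
        return self.limits.get(nutrient, float("inf"))

    def to_yaml(self, path) -> None:
        d = {
            n.value: {"limit": float(self.limits[n]), "unit": UNITS[n]}
            for n in NUTRIENTS
            if n in self.limits
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LimitSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        limits = {}
        for name, entry in raw.items():
            value = entry["limit"] if isinstance(entry, dict) else entry
            limits[parse_nutrient(name)] = float(value)
        return cls(limits)


@dataclass
class CleaningReport:
    """Counts of app values removed by :func:`apply_limits`."""

    removed: dict[Nutrient, int]
    total_items: int
    items_affected: int

    @property
    def total_removed(self) -> int:
        return int(sum(self.removed.values()))

    @property
    def fraction_items_affected(self) -> float:
        return self.items_affected / self.total_items if self.total_items else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"nutrient": n.value, "removed": int(self.removed.get(n, 0))}
            for n in NUTRIENTS
        ]
        df = pd.DataFrame(rows)
        df.attrs["total_items"] = self.total_items
        return df


def default_grid(
    entries: pd.DataFrame,
    nutrient: Nutrient,
    n_steps: int = 200,
    lower_quantile: float = 0.5,
) -> np.ndarray:
    """Ascending candidate limits for one nutrient.

    Spans the ``lower_quantile`` of the observed app per-portion values up
    to the observed maximum in ``n_steps`` evenly spaced candidates.  The
    top candidate equals the observed maximum, so "remove nothing" is
    always in the sweep.
    """
    vals = entries[app_col(nutrient)].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise DegenerateDataError(f"no observed app values for {nutrient}")
    lo = float(np.quantile(vals, lower_quantile))
    hi = float(vals.max())
    if hi <= lo:
        return np.array([hi])
    return np.linspace(lo, hi, n_steps)


def _correlate(x: np.ndarray, y: np.ndarray, assoc: str) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return np.nan
    if assoc == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if assoc == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown association kind {assoc!r}")


@dataclass
class LimitLearnResult:
    nutrient: Nutrient
    limit: float
    assoc: str
    trace: pd.DataFrame  # columns: candidate, correlation, n_removed


def learn_limit(
    train_entries: pd.DataFrame,
    nutrient: Nutrient,
    grid: np.ndarray | None = None,
    assoc: str = "pearson",
) -> LimitLearnResult:
    """Learn the upper limit for one nutrient on a training diary table.

    For each candidate limit in ascending order, app values of this
    nutrient strictly above the candidate are excluded (contribute 0 to the
    daily sums), participant mean daily intakes are recomputed, and the
    app-vs-reference correlation across participants is recorded.  Returns
    the correlation-maximizing candidate (largest on ties) together with
    the full (candidate, correlation, removals) trace for audit.

    Raises :class:`DegenerateDataError` if fewer than 3 participants are
    present or no candidate yields a defined correlation.
    """
    if grid is None:
        grid = default_grid(train_entries, nutrient)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("candidate grid must be non-empty and strictly increasing")

    pids, codes = np.unique(train_entries["participant_id"].to_numpy(), return_inverse=True)
    if pids.size < 3:
        raise DegenerateDataError("need at least 3 participants to learn a limit")
    n_days = (
        train_entries.groupby("participant_id", sort=True)["day"].nunique().to_numpy(dtype=float)
    )
    ref_mean = (
        np.bincount(codes, weights=train_entries[ref_col(nutrient)].to_numpy(dtype=float), minlength=pids.size)
        / n_days
    )

    v = train_entries[app_col(nutrient)].to_numpy(dtype=float)
    observed = np.isfinite(v)  # missing app cells always contribute 0

    corrs = np.empty(grid.size)
    removed = np.empty(grid.size, dtype=int)
    for i, cand in enumerate(grid):
        include = observed & (v <= cand)
        app_mean = np.bincount(codes[include], weights=v[include], minlength=pids.size) / n_days
        corrs[i] = _correlate(app_mean, ref_mean, assoc)
        removed[i] = int((observed & (v > cand)).sum())

    trace = pd.DataFrame({"candidate": grid, "correlation": corrs, "n_removed": removed})
    if np.all(np.isnan(corrs)):
        raise DegenerateDataError(
            f"every candidate limit yields an undefined correlation for {nutrient}"
        )
    best = np.nanmax(corrs)
    best_idx = int(np.flatnonzero(corrs == best)[-1])  # largest tied candidate
    return LimitLearnResult(nutrient=nutrient, limit=float(grid[best_idx]), assoc=assoc, trace=trace)


def learn_limits(
    train_entries: pd.DataFrame,
    grid_spec: dict[Nutrient, np.ndarray] | None = None,
    assoc_policy: dict[Nutrient, str] | None = None,
    n_steps: int = 200,
) -> tuple[LimitSet, dict[Nutrient, LimitLearnResult]]:
    """Learn limits independently for all 8 nutrients.

    ``assoc_policy`` maps each nutrient to its association measure; the
    default uses Pearson for energy/macronutrients/sugar/fiber and Spearman
    for cholesterol/sodium.  A nutrient whose data are degenerate gets
    limit +inf with a warning instead of failing the whole set.
    """
    assoc_policy = assoc_policy or DEFAULT_ASSOC
    limits: dict[Nutrient, float] = {}
    details: dict[Nutrient, LimitLearnResult] = {}
    for n in NUTRIENTS:
        grid = grid_spec.get(n) if grid_spec else None
        if grid is None:
            try:
                grid = default_grid(train_entries, n, n_steps=n_steps)
            except DegenerateDataError as exc:
                warnings.warn(f"{exc}; limit for {n} set to +inf")
                limits[n] = float("inf")
                continue
        try:
            res = learn_limit(train_entries, n, grid=grid, assoc=assoc_policy[n])
        except DegenerateDataError as exc:
            warnings.warn(f"{exc}; limit for {n} set to +inf")
            limits[n] = float("inf")
            continue
        limits[n] = res.limit
        details[n] = res
    return LimitSet(limits), details


def apply_limits(
    test_entries: pd.DataFrame, limits: LimitSet
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove app values strictly above their nutrient's limit.

    Removed cells are set to missing; the food item itself is retained and
    other nutrients are untouched, mirroring per-nutrient-value removal.
    Idempotent: cleaning a cleaned table again removes nothing.
    """
    for n, lim in limits.limits.items():
        if not lim > 0:
            raise DataError(f"limit for {n} must be positive, got {lim}")
    cleaned = test_entries.copy()
    removed: dict[Nutrient, int] = {}
    affected = np.zeros(len(cleaned), dtype=bool)
    for n in NUTRIENTS:
        col = app_col(n)
        over = cleaned[col].to_numpy(dtype=float) > limits[n]  # NaN-safe: NaN > x is False
        removed[n] = int(over.sum())
        affected |= over
        if over.any():
            cleaned.loc[over, col] = np.nan
    report = CleaningReport(
        removed=removed, total_items=len(cleaned), items_affected=int(affected.sum())
    )
    return cleaned, report
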