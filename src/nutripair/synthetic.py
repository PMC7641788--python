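"""Synthetic paired-database diary cohorts.

Generates food-diary tables with the statistical structure the validation
pipeline assumes, so every downstream stage is testable without real data:

* Each participant has a latent habitual daily-intake vector drawn from a
  multivariate log-normal whose marginal means/SDs match the configured
  daily targets (defaults emulate a 50-participant reference cohort: e.g.
  energy 1958 (SD 543) kcal/day across participants) and whose log-scale
  correlation couples energy to each other nutrient.  Realized daily
  totals multiply in mean-one day-to-day log-normal variation.
* The daily vector is split across the day's food items by a symmetric
  Dirichlet weight vector shared across nutrients, so daily totals are
  preserved exactly and item sizes vary realistically.
* Reference-database values are the truth.  App values pass through an
  error channel: a multiplicative bias factor (≤ 1 models systematic
  under-reporting), mean-one multiplicative log-normal noise with a
  per-participant component (people who consistently pick poorly curated
  database items) and a per-item component, a per-nutrient missingness
  probability (elevated for cholesterol and sodium, whose app database
  rows are often incomplete), and finally gross user-entry errors: with
  probability ``contamination_rate`` one nutrient of the item is
  multiplied by a large factor (unit mistakes such as x10 or x100).
* Every planted anomaly is recorded in an audit log so cleaner sensitivity
  and false-positive rates can be measured exactly.

Randomness is split over independent child streams (structure, noise,
missingness, contamination) so that raising the contamination rate under
the same seed contaminates a superset of items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .nutrients import NUTRIENTS, Nutrient, app_col, parse_nutrient, ref_col
from .records_io import DIARY_COLUMNS

AUDIT_ATTR = "nutripair_audit"
AUDIT_COLUMNS = [
    "participant_id",
    "phase",
    "day",
    "item_label",
    "nutrient",
    "kind",
    "original",
]

#: Daily-intake targets (mean, SD) per nutrient for the reference database.
DEFAULT_DAILY_TARGETS: dict[Nutrient, tuple[float, float]] = {
    Nutrient.ENERGY: (1958.0, 543.0),
    Nutrient.CARBOHYDRATE: (225.0, 61.0),
    Nutrient.FAT: (81.0, 27.0),
    Nutrient.PROTEIN: (78.0, 26.0),
    Nutrient.FIBER: (19.0, 8.0),
    Nutrient.SUGAR: (85.0, 35.0),
    Nutrient.CHOLESTEROL: (242.0, 131.0),
    Nutrient.SODIUM: (2638.0, 848.0),
}

#: Item-level log-scale SD of the multiplicative app noise.
DEFAULT_APP_NOISE_SD: dict[Nutrient, float] = {
    Nutrient.ENERGY: 0.20,
    Nutrient.CARBOHYDRATE: 0.30,
    Nutrient.FAT: 0.35,
    Nutrient.PROTEIN: 0.35,
    Nutrient.FIBER: 0.50,
    Nutrient.SUGAR: 0.50,
    Nutrient.CHOLESTEROL: 0.80,
    Nutrient.SODIUM: 0.70,
}

#: Participant-level log-scale SD of the app noise: a systematic per-person
#: error that does not average out over items.  Together with the item
#: noise these defaults put the participant-level app-vs-ref correlations
#: near the pattern seen in validation studies of consumer-app databases
#: (energy ~0.96, macronutrients ~0.9, sugar/fiber ~0.8,
#: cholesterol/sodium ~0.5); see docs/methods.md for the derivation.
DEFAULT_APP_PARTICIPANT_NOISE_SD: dict[Nutrient, float] = {
    Nutrient.ENERGY: 0.08,
    Nutrient.CARBOHYDRATE: 0.13,
    Nutrient.FAT: 0.16,
    Nutrient.PROTEIN: 0.16,
    Nutrient.FIBER: 0.30,
    Nutrient.SUGAR: 0.32,
    Nutrient.CHOLESTEROL: 0.90,
    Nutrient.SODIUM: 0.50,
}

#: Multiplicative app bias (≤ 1 = under-reporting).
DEFAULT_APP_BIAS: dict[Nutrient, float] = {
    Nutrient.ENERGY: 1.01,
    Nutrient.CARBOHYDRATE: 0.93,
    Nutrient.FAT: 0.99,
    Nutrient.PROTEIN: 0.92,
    Nutrient.FIBER: 0.79,
    Nutrient.SUGAR: 0.87,
    Nutrient.CHOLESTEROL: 0.45,
    Nutrient.SODIUM: 0.98,
}

DEFAULT_MISSING_PROB: dict[Nutrient, float] = {
    n: (0.5 if n in (Nutrient.CHOLESTEROL, Nutrient.SODIUM) else 0.02)
    for n in NUTRIENTS
}


@dataclass
class SyntheticConfig:
    """Parameters of the cohort generator.

    With ``contamination_rate=0``, all noise SDs 0, all biases 1 and all
    missing probabilities 0 the app channel is the identity and app values
    equal reference values exactly.
    """

    n_participants: int = 50
    n_days: int = 4
    items_per_day: tuple[int, int] = (12, 16)
    ref_daily_targets: dict[Nutrient, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DAILY_TARGETS)
    )
    app_noise_sd: dict[Nutrient, float] = field(
        default_factory=lambda: dict(DEFAULT_APP_NOISE_SD)
    )
    app_participant_noise_sd: dict[Nutrient, float] = field(
        default_factory=lambda: dict(DEFAULT_APP_PARTICIPANT_NOISE_SD)
    )
    day_noise_sd: float = 0.15
    app_bias: dict[Nutrient, float] = field(
        default_factory=lambda: dict(DEFAULT_APP_BIAS)
    )
    missing_prob: dict[Nutrient, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_PROB)
    )
    contamination_rate: float = 0.03
    contamination_multipliers: tuple[float, ...] = (10.0, 100.0)
    energy_corr: float = 0.5  # log-scale corr between energy and each nutrient
    other_corr: float = 0.25  # log-scale corr between non-energy pairs
    dirichlet_alpha: float = 2.0
    phases: tuple[str, ...] = ("T1", "T2")
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ConfigError("n_participants and n_days must be >= 1")
        lo, hi = self.items_per_day
        if not (1 <= lo <= hi):
            raise ConfigError("items_per_day must satisfy 1 <= low <= high")
        for n in NUTRIENTS:
            mean, sd = self.ref_daily_targets[n]
            if mean <= 0:
                raise ConfigError(f"daily target mean for {n} must be > 0")
            if sd < 0:
                raise ConfigError(f"daily target SD for {n} must be >= 0")
            if self.app_noise_sd[n] < 0 or self.app_participant_noise_sd[n] < 0:
                raise ConfigError(f"app noise SDs for {n} must be >= 0")
            if self.app_bias[n] < 0:
                raise ConfigError(f"app bias for {n} must be >= 0")
            if not 0.0 <= self.missing_prob[n] <= 1.0:
                raise ConfigError(f"missing probability for {n} must be in [0, 1]")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ConfigError("contamination_rate must be in [0, 1]")
        if self.dirichlet_alpha <= 0:
            raise ConfigError("dirichlet_alpha must be > 0")

    # -- config file round trip -------------------------------------------
    def to_yaml(self, path) -> None:
        d = {
            "n_participants": self.n_participants,
            "n_days": self.n_days,
            "items_per_day": list(self.items_per_day),
            "ref_daily_targets": {
                n.value: list(v) for n, v in self.ref_daily_targets.items()
            },
            "app_noise_sd": {n.value: v for n, v in self.app_noise_sd.items()},
            "app_participant_noise_sd": {
                n.value: v for n, v in self.app_participant_noise_sd.items()
            },
            "day_noise_sd": self.day_noise_sd,
            "app_bias": {n.value: v for n, v in self.app_bias.items()},
            "missing_prob": {n.value: v for n, v in self.missing_prob.items()},
            "contamination_rate": self.contamination_rate,
            "contamination_multipliers": list(self.contamination_multipliers),
            "energy_corr": self.energy_corr,
            "other_corr": self.other_corr,
            "dirichlet_alpha": self.dirichlet_alpha,
            "phases": list(self.phases),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SyntheticConfig":
        kw: dict = {}
        nutrient_maps = {
            "ref_daily_targets": tuple,
            "app_noise_sd": float,
            "app_participant_noise_sd": float,
            "app_bias": float,
            "missing_prob": float,
        }
        defaults = cls()
        for key, val in raw.items():
            if key in nutrient_maps:
                base = dict(getattr(defaults, key))
                for name, v in val.items():
                    nut = parse_nutrient(name)
                    base[nut] = tuple(v) if key == "ref_daily_targets" else float(v)
                kw[key] = base
            elif key in ("items_per_day", "contamination_multipliers", "phases"):
                kw[key] = tuple(val)
            elif hasattr(defaults, key):
                kw[key] = val
            else:
                raise ConfigError(f"unknown synthetic config key {key!r}")
        return cls(**kw)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal: returns (mu, sigma) on the log scale."""
    if sd == 0:
        return np.log(mean), 0.0
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _log_cov(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    mus = np.empty(len(NUTRIENTS))
    sigmas = np.empty(len(NUTRIENTS))
    for i, n in enumerate(NUTRIENTS):
        mus[i], sigmas[i] = _lognormal_params(*config.ref_daily_targets[n])
    k = len(NUTRIENTS)
    corr = np.full((k, k), config.other_corr)
    corr[0, :] = corr[:, 0] = config.energy_corr
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sigmas, sigmas)
    return mus, cov


def generate_cohort(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Generate a paired-database diary table covering the configured phases.

    Returns a diary table (see :mod:`nutripair.records_io`).  The audit log
    of planted anomalies is attached under ``DataFrame.attrs`` and retrieved
    with :func:`audit_log`; it is not part of the CSV schema and is lost on
    a write/read round trip.
    """
    config = config or SyntheticConfig()
    config.validate()

    rng_struct = np.random.default_rng([config.seed, 0])
    rng_noise = np.random.default_rng([config.seed, 1])
    rng_missing = np.random.default_rng([config.seed, 2])
    rng_contam = np.random.default_rng([config.seed, 3])

    mus, cov = _log_cov(config)
    k_nut = len(NUTRIENTS)
    pid_width = max(2, len(str(config.n_participants)))
    pids = [f"P{i + 1:0{pid_width}d}" for i in range(config.n_participants)]

    # Latent habitual intake per participant (between-person variation);
    # realized daily totals add mean-one day-to-day variation around it.
    participant_log = rng_struct.multivariate_normal(mus, cov, size=config.n_participants)
    pdays = [
        (i, pid, phase, day)
        for i, pid in enumerate(pids)
        for phase in config.phases
        for day in range(1, config.n_days + 1)
    ]
    lo, hi = config.items_per_day
    item_counts = rng_struct.integers(lo, hi + 1, size=len(pdays))
    sd_day = config.day_noise_sd
    day_factor = np.exp(
        -0.5 * sd_day**2 + sd_day * rng_struct.standard_normal((len(pdays), k_nut))
    )
    daily_totals = np.exp(participant_log[[t[0] for t in pdays]]) * day_factor

    meta_rows: list[tuple] = []
    ref_blocks: list[np.ndarray] = []
    item_pidx: list[int] = []
    for (pidx, pid, phase, day), count, totals in zip(pdays, item_counts, daily_totals):
        w = rng_struct.dirichlet(np.full(count, config.dirichlet_alpha))
        ref_blocks.append(np.outer(w, totals))
        portions = rng_struct.lognormal(np.log(120.0), 0.6, size=count)
        for j in range(count):
            meta_rows.append((pid, phase, day, f"item_{j + 1:02d}", portions[j]))
            item_pidx.append(pidx)
    ref = np.vstack(ref_blocks)  # (n_items, 8)
    n_items = ref.shape[0]
    item_pidx_arr = np.asarray(item_pidx)

    # App error channel.  Both noise components have log-mean -sd^2/2 so
    # E[multiplier] = 1 and the bias factors control the app means exactly.
    sd_p = np.array([config.app_participant_noise_sd[n] for n in NUTRIENTS])
    sd = np.array([config.app_noise_sd[n] for n in NUTRIENTS])
    bias = np.array([config.app_bias[n] for n in NUTRIENTS])
    person_factor = np.exp(
        -0.5 * sd_p**2
        + sd_p * rng_noise.standard_normal((config.n_participants, k_nut))
    )
    z = rng_noise.standard_normal((n_items, k_nut))
    app = ref * bias * person_factor[item_pidx_arr] * np.exp(-0.5 * sd**2 + sd * z)

    miss_p = np.array([config.missing_prob[n] for n in NUTRIENTS])
    miss = rng_missing.uniform(size=(n_items, k_nut)) < miss_p

    # Contamination stream draws are unconditional on the rate so that a
    # higher rate contaminates a superset of items under the same seed.
    u_item = rng_contam.uniform(size=n_items)
    u_nut = rng_contam.uniform(size=n_items)
    u_mult = rng_contam.uniform(size=n_items)
    contam = u_item < config.contamination_rate
    mults = np.asarray(config.contamination_multipliers, dtype=float)

    audit: list[tuple] = []
    app_out = app.copy()
    app_out[miss] = np.nan
    for i in np.flatnonzero(miss.any(axis=1)):
        for j in np.flatnonzero(miss[i]):
            audit.append((*meta_rows[i][:4], NUTRIENTS[j].value, "missing", app[i, j]))
    for i in np.flatnonzero(contam):
        avail = np.flatnonzero(~miss[i])
        if avail.size == 0:
            continue  # every nutrient of this item is missing; nothing to corrupt
        j = avail[int(u_nut[i] * avail.size)]
        mult = mults[int(u_mult[i] * mults.size)]
        audit.append((*meta_rows[i][:4], NUTRIENTS[j].value, "gross_error", app[i, j]))
        app_out[i, j] = app[i, j] * mult

    diary = pd.DataFrame(meta_rows, columns=["participant_id", "phase", "day", "item_label", "portion_g"])
    for j, n in enumerate(NUTRIENTS):
        diary[ref_col(n)] = ref[:, j]
    for j, n in enumerate(NUTRIENTS):
        diary[app_col(n)] = app_out[:, j]
    diary = diary[DIARY_COLUMNS]
    diary.attrs[AUDIT_ATTR] = pd.DataFrame(audit, columns=AUDIT_COLUMNS)
    return diary


def audit_log(cohort: pd.DataFrame) -> pd.DataFrame:
    """Table of planted anomalies for a cohort from :func:`generate_cohort`.

    One row per planted missing value or gross error, with the app value the
    error channel produced before the anomaly was applied.
    """
    if AUDIT_ATTR not in cohort.attrs:
        raise DataError(
            "cohort has no audit log; it was not produced by generate_cohort "
            "(or was round-tripped through CSV, which drops the log)"
        )
    return cohort.attrs[AUDIT_ATTR].copy()
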