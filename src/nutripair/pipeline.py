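"""End-to-end validation pipeline.

Train per-nutrient upper limits on the T1 phase, clean the held-out T2
phase, quantify cross-method agreement before and after cleaning, and run
the attenuation power analysis with the cleaned correlations.  All outputs
are plain CSV/YAML/JSON files in the configured output directory; a rerun
with an identical configuration is byte-identical (no timestamps are
written).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_table, bland_altman_points
from .errors import ConfigError
from .limits import apply_limits, learn_limits
from .nutrients import NUTRIENTS
from .power import PowerSimConfig, inflation_table, power_curves, power_loss_at_target
from .records_io import aggregate_daily_means, read_diary_csv, write_diary_csv
from .synthetic import AUDIT_ATTR, SyntheticConfig, generate_cohort

log = logging.getLogger("nutripair")


@dataclass
class RunConfig:
    """Configuration of one full validation run."""

    out_dir: Path
    cohort_csv: Path | None = None  # single CSV containing both phases
    t1_csv: Path | None = None
    t2_csv: Path | None = None
    synthetic: SyntheticConfig | None = None
    alpha: float = 0.05
    power: PowerSimConfig = field(default_factory=PowerSimConfig)
    headline_n: int = 50
    train_phase: str = "T1"
    test_phase: str = "T2"
    allow_self_clean: bool = False
    seed: int = 0

    def validate(self) -> None:
        sources = sum(
            [
                self.cohort_csv is not None,
                self.t1_csv is not None or self.t2_csv is not None,
                self.synthetic is not None,
            ]
        )
        if sources != 1:
            raise ConfigError(
                "exactly one input source required: cohort_csv, t1_csv+t2_csv, or synthetic"
            )
        if (self.t1_csv is None) != (self.t2_csv is None):
            raise ConfigError("t1_csv and t2_csv must be given together")
        if self.train_phase == self.test_phase and not self.allow_self_clean:
            raise ConfigError(
                "training and test phase are identical; set allow_self_clean to override"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw: dict = {}
        if "synthetic" in raw:
            kw["synthetic"] = SyntheticConfig.from_dict(raw.pop("synthetic") or {})
        if "power" in raw:
            p = raw.pop("power") or {}
            cfg = PowerSimConfig()
            for k, v in p.items():
                if not hasattr(cfg, k):
                    raise ConfigError(f"unknown power config key {k!r}")
                setattr(cfg, k, tuple(v) if k == "n_list" else v)
            kw["power"] = cfg
        for k in ("out_dir", "cohort_csv", "t1_csv", "t2_csv"):
            if k in raw and raw[k] is not None:
                kw[k] = Path(raw.pop(k))
            else:
                raw.pop(k, None)
        for k, v in raw.items():
            if not hasattr(cls, "__dataclass_fields__") or k not in cls.__dataclass_fields__:
                raise ConfigError(f"unknown run config key {k!r}")
            kw[k] = v
        if "out_dir" not in kw:
            raise ConfigError("run config must name an out_dir")
        return cls(**kw)


@dataclass
class RunResult:
    out_dir: Path
    limits: "object"
    cleaning_report: "object"
    agreement: pd.DataFrame
    inflation: pd.DataFrame
    power_loss: pd.DataFrame
    paths: dict[str, Path]


def _load_cohort(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    if config.synthetic is not None:
        sim = config.synthetic
        sim.seed = config.seed  # the run seed drives every stochastic stage
        cohort = generate_cohort(sim)
        return cohort, cohort.attrs[AUDIT_ATTR]
    if config.cohort_csv is not None:
        return read_diary_csv(config.cohort_csv), None
    t1 = read_diary_csv(config.t1_csv)
    t2 = read_diary_csv(config.t2_csv)
    return pd.concat([t1, t2], ignore_index=True), None


def run_validation(config: RunConfig) -> RunResult:
    """Run the full train/clean/agree/power pipeline and write all reports."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        cohort, audit = _load_cohort(config)
        if config.synthetic is not None:
            paths["cohort"] = out / "cohort.csv"
            write_diary_csv(cohort, paths["cohort"])
            paths["audit"] = out / "audit.csv"
            audit.to_csv(paths["audit"], index=False)

        t1 = cohort[cohort["phase"] == config.train_phase]
        t2 = cohort[cohort["phase"] == config.test_phase]
        if len(t1) == 0:
            raise ConfigError(f"no entries for training phase {config.train_phase!r}")
        if len(t2) == 0:
            raise ConfigError(f"no entries for test phase {config.test_phase!r}")
        log.info("cohort: %d items (%d train, %d test)", len(cohort), len(t1), len(t2))

        limit_set, details = learn_limits(t1)
        for n in NUTRIENTS:
            log.info("learned limit %s = %.6g", n.value, limit_set[n])
        paths["limits"] = out / "limits.yaml"
        limit_set.to_yaml(paths["limits"])
        traces = pd.concat(
            [d.trace.assign(nutrient=n.value) for n, d in details.items()],
            ignore_index=True,
        ) if details else pd.DataFrame(columns=["candidate", "correlation", "n_removed", "nutrient"])
        paths["limit_traces"] = out / "limit_traces.csv"
        traces.to_csv(paths["limit_traces"], index=False)

        cleaned_t2, report = apply_limits(t2, limit_set)
        for n in NUTRIENTS:
            log.info("removed %d app values for %s", report.removed.get(n, 0), n.value)
        log.info(
            "cleaning affected %d of %d items (%.2f%%)",
            report.items_affected,
            report.total_items,
            100 * report.fraction_items_affected,
        )
        paths["cleaned_t2"] = out / "t2_cleaned.csv"
        write_diary_csv(cleaned_t2, paths["cleaned_t2"])
        paths["cleaning_report"] = out / "cleaning_report.csv"
        report.to_frame().to_csv(paths["cleaning_report"], index=False)

        diaries = aggregate_daily_means(t2, config.test_phase)
        cleaned_diaries = aggregate_daily_means(cleaned_t2, config.test_phase)
        agreement = agreement_table(diaries, cleaned_diaries, alpha=config.alpha)
        paths["agreement"] = out / "agreement.csv"
        agreement.to_csv(paths["agreement"], index=False)
        paths["bland_altman"] = out / "bland_altman_points.csv"
        bland_altman_points(cleaned_diaries).to_csv(paths["bland_altman"], index=False)

        cleaned_rows = agreement[agreement["state"] == "cleaned"].set_index("nutrient")
        r_by_nutrient: dict[str, float] = {}
        for n in NUTRIENTS:
            r = float(cleaned_rows.loc[n.value, "corr"])
            if not 0.0 < r <= 1.0:
                log.warning(
                    "cleaned correlation for %s is %.3f; skipped in power analysis",
                    n.value,
                    r,
                )
                continue
            r_by_nutrient[n.value] = min(r, 1.0)

        inflation = inflation_table(
            r_by_nutrient,
            n_list=tuple(config.power.n_list),
            target_power=config.power.target_power,
            alpha=config.power.alpha,
        )
        paths["inflation"] = out / "inflation.csv"
        inflation.to_csv(paths["inflation"], index=False)

        curve_frames = []
        loss_rows = []
        for name, r in r_by_nutrient.items():
            curve = power_curves(
                config=PowerSimConfig(
                    rho_grid=config.power.rho_grid,
                    alpha=config.power.alpha,
                    target_power=config.power.target_power,
                    mode="analytic",
                ),
                r_nm=r,
                n=config.headline_n,
            )
            curve_frames.append(curve.to_frame().assign(nutrient=name))
            loss_rows.append(
                {
                    "nutrient": name,
                    "r_nm": r,
                    "n": config.headline_n,
                    "power_loss_points": power_loss_at_target(
                        curve, config.power.target_power
                    ),
                }
            )
        paths["power_curves"] = out / "power_curves.csv"
        pd.concat(curve_frames, ignore_index=True).to_csv(paths["power_curves"], index=False)
        power_loss = pd.DataFrame(loss_rows)
        paths["power_loss"] = out / "power_loss.csv"
        power_loss.to_csv(paths["power_loss"], index=False)

        manifest = {
            "nutripair_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "train_phase": config.train_phase,
            "test_phase": config.test_phase,
            "headline_n": config.headline_n,
            "limits": {n.value: limit_set[n] for n in NUTRIENTS},
            "removed": {n.value: report.removed.get(n, 0) for n in NUTRIENTS},
            "fraction_items_affected": report.fraction_items_affected,
            "power": {
                "n_list": list(config.power.n_list),
                "target_power": config.power.target_power,
                "alpha": config.power.alpha,
                "reps": config.power.reps,
            },
        }
        paths["manifest"] = out / "manifest.json"
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)

        return RunResult(
            out_dir=out,
            limits=limit_set,
            cleaning_report=report,
            agreement=agreement,
            inflation=inflation,
            power_loss=power_loss,
            paths=paths,
        )
    finally:
        log.removeHandler(handler)
        handler.close()
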