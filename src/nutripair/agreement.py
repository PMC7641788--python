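"""Method-agreement statistics between app and reference daily intakes.

For each nutrient the module computes the classical method-comparison
battery on participant-level mean daily intakes:

* a Shapiro-Wilk normality gate on both margins and their differences that
  selects Pearson + paired t (all normal) or Spearman + Wilcoxon signed
  rank (otherwise);
* a paired location test for a systematic level difference;
* cross-method correlation;
* Bland-Altman agreement: mean difference (app − ref), 95% limits of
  agreement at ±1.96 SD, a fixed-bias test (one-sample t confidence
  interval on the differences excluding zero) and a proportional-bias test
  (OLS slope of the differences on the pair means, two-sided at α).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .nutrients import NUTRIENTS, UNITS, Nutrient, app_col, ref_col


@dataclass
class BlandAltmanSummary:
    """Agreement summary for one nutrient; differences are app − ref."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    fixed_bias: bool
    fixed_bias_p: float
    prop_slope: float
    prop_bias: bool
    prop_bias_p: float


@dataclass
class AgreementResult:
    nutrient: Nutrient
    ref_mean: float
    ref_sd: float
    app_mean: float
    app_sd: float
    test_used: str
    test_p: float
    corr_used: str
    corr: float
    corr_p: float
    ba: BlandAltmanSummary


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("paired samples must be 1-D and of equal length")
    return x, y


def _shapiro_normal(v: np.ndarray, alpha: float) -> bool:
    if np.ptp(v) == 0.0:
        return False  # zero variance cannot be normality-tested; treat as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(stats.shapiro(v).pvalue >= alpha)


def choose_methods(x, y, alpha: float = 0.05) -> tuple[str, str]:
    """Select the test/correlation pair from a composite normality gate.

    Shapiro-Wilk is applied to x, to y and to the differences x − y;
    (paired_t, pearson) is chosen iff all three look normal at *alpha*,
    otherwise (wilcoxon_signed_rank, spearman).
    """
    x, y = _paired(x, y)
    if x.size < 4:
        raise DataError("need at least 4 pairs for the normality gate")
    normal = (
        _shapiro_normal(x, alpha)
        and _shapiro_normal(y, alpha)
        and _shapiro_normal(x - y, alpha)
    )
    return ("paired_t", "pearson") if normal else ("wilcoxon_signed_rank", "spearman")


def paired_location_test(x, y, test_used: str) -> tuple[float, dict]:
    """Two-sided paired test of a level difference; returns (p, summary).

    All-zero differences are reported as p = 1 by convention (there is no
    evidence of any shift, and both tests are degenerate there).
    """
    x, y = _paired(x, y)
    d = x - y
    summary = {"mean_diff": float(d.mean()), "n": int(d.size), "test": test_used}
    if np.all(d == 0.0):
        summary["note"] = "all differences zero; p = 1 by convention"
        return 1.0, summary
    if test_used == "paired_t":
        res = stats.ttest_rel(x, y)
        summary["statistic"] = float(res.statistic)
        return float(res.pvalue), summary
    if test_used == "wilcoxon_signed_rank":
        res = stats.wilcoxon(x, y)
        summary["statistic"] = float(res.statistic)
        return float(res.pvalue), summary
    raise ValueError(f"unknown test {test_used!r}")


def correlation(x, y, corr_used: str) -> tuple[float, float]:
    """Cross-method correlation coefficient and two-sided p-value."""
    x, y = _paired(x, y)
    if corr_used == "pearson":
        res = stats.pearsonr(x, y)
    elif corr_used == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation kind {corr_used!r}")
    return float(res.statistic), float(res.pvalue)


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanSummary:
    """Bland-Altman agreement of app (*y*) versus reference (*x*).

    Differences are d = y − x.  Limits of agreement are mean ± 1.96 SD.
    Fixed bias: the (1 − alpha) one-sample t confidence interval of the
    mean difference excludes 0.  Proportional bias: the OLS slope of d on
    the pair means (x + y)/2 differs from 0 at *alpha*; skipped with a note
    if the pair means have zero variance.
    """
    x, y = _paired(x, y)
    if x.size < 4:
        raise DataError("need at least 4 pairs for Bland-Altman analysis")
    d = y - x
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_lower = mean_diff - 1.96 * sd_diff
    loa_upper = mean_diff + 1.96 * sd_diff

    if sd_diff == 0.0:
        fixed_p = 0.0 if mean_diff != 0.0 else 1.0
    else:
        fixed_p = float(stats.ttest_1samp(d, 0.0).pvalue)
    fixed = fixed_p < alpha

    means = (x + y) / 2.0
    if np.ptp(means) == 0.0:
        warnings.warn("pair means have zero variance; proportional-bias test skipped")
        slope, prop_p = 0.0, 1.0
    else:
        fit = stats.linregress(means, d)
        slope = float(fit.slope)
        prop_p = float(fit.pvalue) if np.isfinite(fit.pvalue) else 1.0
    return BlandAltmanSummary(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        fixed_bias=bool(fixed),
        fixed_bias_p=fixed_p,
        prop_slope=slope,
        prop_bias=bool(prop_p < alpha),
        prop_bias_p=prop_p,
    )


def _one_state(diaries: pd.DataFrame, alpha: float) -> list[AgreementResult]:
    results = []
    for n in NUTRIENTS:
        x = diaries[ref_col(n)].to_numpy(dtype=float)  # reference
        y = diaries[app_col(n)].to_numpy(dtype=float)  # app
        test_used, corr_used = choose_methods(x, y, alpha)
        p, _ = paired_location_test(x, y, test_used)
        r, rp = correlation(x, y, corr_used)
        results.append(
            AgreementResult(
                nutrient=n,
                ref_mean=float(x.mean()),
                ref_sd=float(x.std(ddof=1)),
                app_mean=float(y.mean()),
                app_sd=float(y.std(ddof=1)),
                test_used=test_used,
                test_p=p,
                corr_used=corr_used,
                corr=r,
                corr_p=rp,
                ba=bland_altman(x, y, alpha),
            )
        )
    return results


def results_to_frame(results: list[AgreementResult], state: str) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "nutrient": r.nutrient.value,
                "unit_per_day": UNITS[r.nutrient] + "/day",
                "state": state,
                "ref_mean": r.ref_mean,
                "ref_sd": r.ref_sd,
                "app_mean": r.app_mean,
                "app_sd": r.app_sd,
                "test_used": r.test_used,
                "test_p": r.test_p,
                "corr_used": r.corr_used,
                "corr": r.corr,
                "corr_p": r.corr_p,
                "ba_mean_diff": r.ba.mean_diff,
                "ba_sd_diff": r.ba.sd_diff,
                "ba_loa_lower": r.ba.loa_lower,
                "ba_loa_upper": r.ba.loa_upper,
                "ba_fixed_bias": r.ba.fixed_bias,
                "ba_prop_slope": r.ba.prop_slope,
                "ba_prop_bias": r.ba.prop_bias,
            }
        )
    return pd.DataFrame(rows)


def agreement_table(
    diaries: pd.DataFrame,
    cleaned_diaries: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-nutrient agreement summary on aggregated daily intakes.

    *diaries* (and optionally *cleaned_diaries*) are outputs of
    :func:`nutripair.records_io.aggregate_daily_means`.  Returns one row
    per nutrient and cleaning state with means/SDs for both methods, the
    gate-selected paired test and correlation with p-values, and the
    Bland-Altman summary.
    """
    if len(diaries) < 4:
        raise DataError("need at least 4 participants for the agreement table")
    frames = [results_to_frame(_one_state(diaries, alpha), "original")]
    if cleaned_diaries is not None:
        frames.append(results_to_frame(_one_state(cleaned_diaries, alpha), "cleaned"))
    return pd.concat(frames, ignore_index=True)


def bland_altman_points(diaries: pd.DataFrame) -> pd.DataFrame:
    """Plot data for Bland-Altman scatter: one row per participant/nutrient.

    Columns: nutrient, participant_id, pair_mean, difference (app − ref),
    plus the per-nutrient mean difference and limits of agreement repeated
    on each row so any plotting front end can draw the reference lines.
    """
    frames = []
    for n in NUTRIENTS:
        x = diaries[ref_col(n)].to_numpy(dtype=float)
        y = diaries[app_col(n)].to_numpy(dtype=float)
        ba = bland_altman(x, y)
        frames.append(
            pd.DataFrame(
                {
                    "nutrient": n.value,
                    "participant_id": diaries.index,
                    "pair_mean": (x + y) / 2.0,
                    "difference": y - x,
                    "mean_diff": ba.mean_diff,
                    "loa_lower": ba.loa_lower,
                    "loa_upper": ba.loa_upper,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
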