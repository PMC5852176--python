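"""Normal-database statistics: reference limits, age regressions, group splits.

The clinical question behind a normal database is "what range of HMR and
washout values should a subject without cardiac sympathetic denervation
show, and does that range drift with age?".  This module provides

* :func:`summarize_measure` — mean, SD, empirical 2.5%/97.5% quantile
  reference limits and a Shapiro-Wilk normality check per measure;
* :func:`fit_age_regression` — OLS of a measure on age with a two-sided
  slope test; a regression line is displayed only when p < 0.10;
* :func:`years_per_decline` — translation of a negative slope into
  "years per fixed HMR loss";
* :func:`split_and_compare` — median-age split (older group takes the
  tie by default) with a Welch t-test and per-group lower limits;
* :func:`run_full_analysis` — the whole report over the five standard
  measures, with machine-readable CSV/JSON output and figures.

No multiple-testing correction is applied across the five measures; the
per-measure p-values are reported as-is, which callers comparing many
measures should keep in mind.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "MEASURES",
    "CohortSummary",
    "AgeRegressionResult",
    "GroupComparison",
    "summarize_measure",
    "fit_age_regression",
    "years_per_decline",
    "split_and_compare",
    "run_full_analysis",
]

#: The five measures the normal-database report covers, in table order.
MEASURES = ("hmr_early_std", "hmr_late_std", "wr_bdc", "wr_dc", "wr_hmr")

#: Display precision per measure family (decimals).
_PRECISION = {"hmr": 2, "wr": 1}
SLOPE_DECIMALS = 4


def _decimals(measure: str) -> int:
    return _PRECISION["hmr"] if measure.startswith("hmr") else _PRECISION["wr"]


@dataclass(frozen=True)
class CohortSummary:
    measure: str
    n: int
    mean: float
    sd: float
    q025: float
    q975: float
    shapiro_w: float
    shapiro_p: float


@dataclass(frozen=True)
class AgeRegressionResult:
    measure: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_ci: tuple[float, float]
    ci_level: float = 0.95
    show_line: bool = False  # drawn only when p < 0.10


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    threshold_age: float
    n_younger: int
    n_older: int
    mean_younger: float
    mean_older: float
    q025_younger: float
    q025_older: float
    t_statistic: float
    p_value: float


def summarize_measure(
    values: Sequence[float], measure: str, quantile_method: str = "linear"
) -> CohortSummary:
    """Reference-limit summary of one measure.

    SD uses the n-1 denominator; quantiles default to the linear
    interpolation estimator ("type 7"), selectable via
    ``quantile_method``.  A constant vector leaves Shapiro-Wilk
    undefined: W and p are returned as NaN with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValidationError(f"need >= 3 one-dimensional values, got shape {x.shape}")
    if np.any(~np.isfinite(x)):
        raise ValidationError(f"{measure}: missing/non-finite values are not allowed")
    if np.ptp(x) == 0:
        warnings.warn(f"{measure}: constant values, Shapiro-Wilk undefined", stacklevel=2)
        w = p = float("nan")
    else:
        w, p = sps.shapiro(x)
    q025, q975 = np.quantile(x, [0.025, 0.975], method=quantile_method)
    return CohortSummary(
        measure=measure,
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        q025=float(q025),
        q975=float(q975),
        shapiro_w=float(w),
        shapiro_p=float(p),
    )


def fit_age_regression(
    ages: Sequence[float], values: Sequence[float], measure: str = "", ci_level: float = 0.95
) -> AgeRegressionResult:
    """OLS of a measure on age with a two-sided slope test.

    ``show_line`` follows the display convention of regression plots in
    this kind of normal-database report: the fitted line (with CI band)
    is drawn only when the slope is significant at p < 0.10.
    """
    age = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if age.size != y.size or age.size < 3:
        raise ValidationError("ages and values must be equal-length with n >= 3")
    if np.ptp(age) == 0:
        raise ValidationError("age variance is zero; regression on age undefined")
    fit = sm.OLS(y, sm.add_constant(age)).fit()
    ci = fit.conf_int(alpha=1 - ci_level)
    p = float(fit.pvalues[1])
    return AgeRegressionResult(
        measure=measure,
        n=int(age.size),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=p,
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        ci_level=ci_level,
        show_line=bool(p < 0.10),
    )


def years_per_decline(slope: float, delta: float = 0.1) -> float:
    """Years of aging corresponding to a loss of ``delta`` measure units.

    Defined for declining measures only (slope < 0).  Rounding to whole
    years is left to the reporting layer.
    """
    if not slope < 0:
        raise ValidationError(f"decline undefined for non-negative slope {slope!r}")
    if not delta > 0:
        raise ValidationError(f"delta must be > 0, got {delta!r}")
    return delta / abs(slope)


def split_and_compare(
    cohort: pd.DataFrame,
    measure: str,
    threshold_age: float = 63.0,
    ties_to_older: bool = True,
    welch: bool = True,
) -> GroupComparison:
    """Compare a measure between age groups split at ``threshold_age``.

    The older group takes subjects exactly at the threshold by default
    (age >= threshold); a Welch t-test is the default comparison, the
    equal-variance Student variant selectable with ``welch=False``.
    """
    age = cohort["age_years"].to_numpy(dtype=float)
    x = cohort[measure].to_numpy(dtype=float)
    older_mask = age >= threshold_age if ties_to_older else age > threshold_age
    older, younger = x[older_mask], x[~older_mask]
    if older.size == 0 or younger.size == 0:
        raise ValidationError(
            f"age split at {threshold_age} leaves an empty group "
            f"(n_younger={younger.size}, n_older={older.size})"
        )
    t, p = sps.ttest_ind(younger, older, equal_var=not welch)
    return GroupComparison(
        measure=measure,
        threshold_age=float(threshold_age),
        n_younger=int(younger.size),
        n_older=int(older.size),
        mean_younger=float(younger.mean()),
        mean_older=float(older.mean()),
        q025_younger=float(np.quantile(younger, 0.025)),
        q025_older=float(np.quantile(older, 0.025)),
        t_statistic=float(t),
        p_value=float(p),
    )


def _round(value: float, decimals: int) -> float:
    return float(np.round(value, decimals))


def run_full_analysis(
    cohort: pd.DataFrame,
    out_dir: str | Path | None = None,
    threshold_age: float = 63.0,
    measures: Sequence[str] = MEASURES,
    make_figures: bool = True,
    decline_delta: float = 0.1,
) -> dict:
    """Full normal-database report over a standardized cohort with washout.

    Requires the standardized-HMR and washout columns (see
    :func:`mibgquant.standardize.standardize_cohort` and
    :func:`mibgquant.washout.add_washout_columns`).  Returns the report as
    a plain dict; when ``out_dir`` is given, additionally writes
    ``summary.csv``, ``regressions.csv``, ``groups.csv``, ``report.json``
    and (optionally) one figure per measure.  Output is deterministic:
    the same cohort yields byte-identical text reports.
    """
    missing = [m for m in measures if m not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort is missing measure columns {missing}")
    age = cohort["age_years"].to_numpy(dtype=float)

    summaries = [summarize_measure(cohort[m], m) for m in measures]
    regressions = [fit_age_regression(age, cohort[m], measure=m) for m in measures]
    groups = [split_and_compare(cohort, m, threshold_age) for m in measures]

    declines = {}
    for reg in regressions:
        if reg.show_line and reg.slope < 0 and reg.measure.startswith("hmr"):
            declines[reg.measure] = {
                "delta": decline_delta,
                "years": years_per_decline(reg.slope, decline_delta),
                "years_rounded": int(round(years_per_decline(reg.slope, decline_delta))),
                "decline_per_decade": _round(abs(reg.slope) * 10.0, 2),
            }

    report = {
        "n": int(len(cohort)),
        "threshold_age": float(threshold_age),
        "summaries": {
            s.measure: {
                **{k: v for k, v in asdict(s).items() if k != "measure"},
                "mean_display": _round(s.mean, _decimals(s.measure)),
                "sd_display": _round(s.sd, _decimals(s.measure)),
                "q025_display": _round(s.q025, _decimals(s.measure)),
                "q975_display": _round(s.q975, _decimals(s.measure)),
            }
            for s in summaries
        },
        "age_regressions": {
            r.measure: {
                **{k: v for k, v in asdict(r).items() if k != "measure"},
                "slope_display": _round(r.slope, SLOPE_DECIMALS),
            }
            for r in regressions
        },
        "group_comparisons": {g.measure: {k: v for k, v in asdict(g).items() if k != "measure"} for g in groups},
        "age_declines": declines,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(out / "summary.csv", index=False)
        reg_df = pd.DataFrame([asdict(r) for r in regressions])
        reg_df["slope_ci"] = reg_df["slope_ci"].map(lambda ci: f"{ci[0]:.6g}..{ci[1]:.6g}")
        reg_df.to_csv(out / "regressions.csv", index=False)
        pd.DataFrame([asdict(g) for g in groups]).to_csv(out / "groups.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        if make_figures:
            _write_figures(cohort, regressions, out, threshold_age)
    return report


def _write_figures(
    cohort: pd.DataFrame,
    regressions: Sequence[AgeRegressionResult],
    out: Path,
    threshold_age: float,
) -> None:
    """Scatter of each measure vs age; regression line and CI band only
    when the slope is significant at p < 0.10.  Plus a group box plot for
    the two HMR measures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    age = cohort["age_years"].to_numpy(dtype=float)
    for reg in regressions:
        y = cohort[reg.measure].to_numpy(dtype=float)
        fig, ax = plt.subplots(figsize=(4.2, 3.4))
        older = age >= threshold_age
        ax.scatter(age[~older], y[~older], facecolors="none", edgecolors="tab:blue", s=22)
        ax.scatter(age[older], y[older], color="tab:blue", s=22)
        if reg.show_line:
            grid = np.linspace(age.min(), age.max(), 50)
            fit = sm.OLS(y, sm.add_constant(age)).fit()
            pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
            ax.plot(grid, pred["mean"], color="tab:red")
            ax.fill_between(grid, pred["mean_ci_lower"], pred["mean_ci_upper"],
                            color="tab:red", alpha=0.2, linewidth=0)
        ax.set_xlabel("age (years)")
        ax.set_ylabel(reg.measure)
        ax.set_title(
            f"{reg.measure}: slope={reg.slope:.4f}, r$^2$={reg.r_squared:.3f}, p={reg.p_value:.3f}"
        )
        fig.tight_layout()
        fig.savefig(out / f"fig_{reg.measure}_age.png", dpi=110)
        plt.close(fig)

    hmr_measures = [m for m in ("hmr_early_std", "hmr_late_std") if m in cohort.columns]
    if hmr_measures:
        fig, axes = plt.subplots(1, len(hmr_measures), figsize=(3.2 * len(hmr_measures), 3.4))
        axes = np.atleast_1d(axes)
        older = age >= threshold_age
        for ax, m in zip(axes, hmr_measures):
            data = [cohort.loc[~older, m], cohort.loc[older, m]]
            ax.boxplot(data, tick_labels=[f"< {threshold_age:g}", f">= {threshold_age:g}"])
            ax.set_ylabel(m)
            ax.set_xlabel("age group (years)")
        fig.tight_layout()
        fig.savefig(out / "fig_group_hmr.png", dpi=110)
        plt.close(fig)
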