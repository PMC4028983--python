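"""Median-split survival screening on an independent cohort.

Each candidate feature dichotomizes the validation cohort at its median
expression; the high-vs-low hazard ratio comes from a Cox proportional
hazards fit (Efron tie handling), Kaplan-Meier curves give per-group
median survival, and BH adjustment across the screened feature list
selects significant prognostic features.  Selected features are refit
with age and gender adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .de import bh_adjust
from .io import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)


def median_split(values) -> np.ndarray:
    """Split samples at the median: 'high' if value > median, else 'low'."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 samples for a median split")
    if np.ptp(v) == 0:
        raise ValueError("constant expression: median split is degenerate")
    med = np.median(v)
    return np.where(v > med, "high", "low")


@dataclass
class KMEstimate:
    curve: pd.DataFrame           # columns: time, survival
    median: float | None          # smallest t with S(t) <= 0.5, None if never


def km_estimate(times, events) -> KMEstimate:
    """Product-limit survival estimate and median survival time."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_.reset_index()
    surv.columns = ["time", "survival"]
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMEstimate(curve=surv, median=median)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    g = np.asarray(list(groups))
    uniq = pd.unique(g)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    if e.sum() == 0:
        raise ValueError("no events observed")
    mask = g == uniq[0]
    res = _ll_logrank(t[mask], t[~mask], event_observed_A=e[mask], event_observed_B=e[~mask])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(times, events, covariates: pd.DataFrame, ties: str = "efron") -> pd.DataFrame:
    """Cox proportional-hazards fit.

    Returns one row per covariate: coef, hr, se, p, ci_lower, ci_upper
    (hazard-ratio scale CIs).  Non-convergence / perfect separation is
    flagged by NaN p with a ``converged`` column set False.
    """
    df = covariates.copy()
    df["__time"] = np.asarray(times, dtype=float)
    df["__event"] = np.asarray(events, dtype=float)
    if df["__event"].sum() == 0:
        raise ValueError("no events observed")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="__time", event_col="__event")
    except (ConvergenceError, ValueError) as exc:
        logger.warning("Cox fit failed (%s); returning flagged row", exc)
        out = pd.DataFrame(
            {"coef": np.nan, "hr": np.nan, "se": np.nan, "p": np.nan,
             "ci_lower": np.nan, "ci_upper": np.nan, "converged": False},
            index=covariates.columns,
        )
        return out
    summ = cph.summary
    out = pd.DataFrame({
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "se": summ["se(coef)"],
        "p": summ["p"],
        "ci_lower": summ["exp(coef) lower 95%"],
        "ci_upper": summ["exp(coef) upper 95%"],
        "converged": True,
    })
    out.index = summ.index
    return out


def _group_median_survival(times, events, high_mask) -> tuple[float | None, float | None]:
    med_low = km_estimate(times[~high_mask], events[~high_mask]).median
    med_high = km_estimate(times[high_mask], events[high_mask]).median
    return med_low, med_high


def survival_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    features=None,
    fdr_max: float = 0.05,
    stages: tuple[str, ...] = ("II", "III"),
) -> pd.DataFrame:
    """Median-split Cox screen of features on the validation cohort.

    Per feature: median split of the validation samples (stage II/III by
    default), univariate Cox on the high-group indicator (Wald p; log-rank
    p also reported), BH across the screened list, and — for selected
    features only — a multivariate refit adjusting for age and gender
    (samples with missing age/gender dropped from that refit).
    """
    validation = clinical.stage_subset(stages)
    samples = [s for s in validation.sample_ids if s in set(expr.sample_ids)]
    if len(samples) < 4:
        raise ValueError("validation cohort too small after stage filtering")
    validation = validation.subset(samples)
    surv = validation.data[["time", "event"]].dropna()
    samples = surv.index.tolist()
    times = surv["time"].to_numpy(dtype=float)
    events = surv["event"].to_numpy(dtype=float)
    if events.sum() == 0:
        raise ValueError("validation cohort has zero events")
    sub = expr.data[samples]
    if features is None:
        features = expr.feature_ids
    missing = [f for f in features if f not in set(expr.feature_ids)]
    if missing:
        raise ValueError(f"features absent from matrix: {missing[:10]}")

    rows = []
    for fid in features:
        v = sub.loc[fid].to_numpy(dtype=float)
        try:
            grp = median_split(v)
        except ValueError:
            logger.warning("feature %s: degenerate median split; skipped", fid)
            continue
        high = grp == "high"
        uni = cox_fit(times, events, pd.DataFrame({"high": high.astype(float)}))
        try:
            _, p_lr = logrank_test(times, events, grp)
        except ValueError:
            p_lr = np.nan
        med_low, med_high = _group_median_survival(times, events, high)
        rows.append({
            "feature": fid, "level": expr.level,
            "n_low": int((~high).sum()), "n_high": int(high.sum()),
            "hr": float(uni.loc["high", "hr"]),
            "p": float(uni.loc["high", "p"]),
            "p_logrank": float(p_lr) if np.isfinite(p_lr) else np.nan,
            "median_low": med_low, "median_high": med_high,
            "converged": bool(uni.loc["high", "converged"]),
        })
    if not rows:
        raise ValueError("no screenable feature (all degenerate)")
    table = pd.DataFrame(rows).set_index("feature")
    valid_p = table["p"].notna()
    fdr = pd.Series(np.nan, index=table.index)
    if valid_p.any():
        fdr[valid_p] = bh_adjust(table.loc[valid_p, "p"].to_numpy())
    table["fdr"] = fdr
    table["selected"] = table["fdr"] <= fdr_max

    # multivariate refit (group + age + male indicator) for selected rows only
    covars = validation.data.loc[samples, ["age", "gender"]]
    complete = covars["age"].notna() & covars["gender"].notna()
    table["hr_multivariate"] = np.nan
    table["p_multivariate"] = np.nan
    for fid in table.index[table["selected"]]:
        v = sub.loc[fid].to_numpy(dtype=float)
        keep = complete.to_numpy()
        design = pd.DataFrame({
            "high": (median_split(v) == "high")[keep].astype(float),
            "age": covars.loc[complete, "age"].to_numpy(dtype=float),
            "male": (covars.loc[complete, "gender"] == "male").to_numpy(dtype=float),
        })
        multi = cox_fit(times[keep], events[keep], design)
        table.loc[fid, "hr_multivariate"] = multi.loc["high", "hr"]
        table.loc[fid, "p_multivariate"] = multi.loc["high", "p"]
    return table
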