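"""Cohort statistics: group comparison, FDR control, and survival analysis.

Per-patient quantities are compared across subtypes with the Kruskal-Wallis
rank sum test (tie-corrected H, chi-square reference with groups-1 df), and
p-values from a tested family are adjusted with the Benjamini-Hochberg
step-up procedure. Survival is summarized per group by the Kaplan-Meier
product-limit estimator (median = first time S(t) <= 0.5), groups are
compared with the k-sample log-rank test, and covariate effects are
estimated by Cox proportional-hazards regression on the partial likelihood
(Breslow tie handling by default, Efron switchable), reporting hazard
ratios, Wald 95% CIs from the observed information, and Wald p-values.
Two-sided alpha = 0.05 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis comparison of one quantity across subtypes."""

    quantity: str
    statistic: float
    raw_p: float
    adjusted_p: float | None
    group_summaries: pd.DataFrame  # per-group n, mean, sd, ci_low, ci_high


@dataclass
class KaplanMeierCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    median: float  # NaN if S never reaches 0.5
    n: int
    events: int


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Returns (0, 1) when every value across all groups is identical, where
    the statistic is degenerate.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    values: pd.Series, labels: pd.Series, quantity: str = "value"
) -> GroupComparisonResult:
    """Kruskal-Wallis test of a per-patient quantity across cluster labels.

    Group summaries carry mean +/- SD and a normal-theory 95% CI of the mean.
    The adjusted p is filled in later by :func:`adjust_family` across the
    whole family of comparisons.
    """
    df = pd.DataFrame({"value": values, "group": labels}).dropna()
    parts = [g["value"].to_numpy() for _, g in df.groupby("group", sort=True)]
    h, p = kruskal_wallis(parts)
    rows = []
    for name, g in df.groupby("group", sort=True):
        v = g["value"].to_numpy()
        mean = v.mean()
        sd = v.std(ddof=1) if v.size > 1 else 0.0
        half = 1.959963984540054 * sd / np.sqrt(v.size) if v.size > 1 else 0.0
        rows.append(
            {"group": name, "n": v.size, "mean": mean, "sd": sd,
             "ci_low": mean - half, "ci_high": mean + half}
        )
    return GroupComparisonResult(
        quantity=quantity,
        statistic=h,
        raw_p=p,
        adjusted_p=None,
        group_summaries=pd.DataFrame(rows),
    )


def adjust_family(results: list[GroupComparisonResult]) -> list[GroupComparisonResult]:
    """Apply Benjamini-Hochberg across a family of group comparisons in place."""
    adj = bh_adjust([r.raw_p for r in results])
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return results


def kaplan_meier(
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> dict[str, KaplanMeierCurve]:
    """Per-group product-limit survival curves.

    Median survival is the smallest observed time with S(t) <= 0.5, NaN if
    the curve never reaches 0.5.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    if event.sum() < 1:
        logger.warning("no events observed; survival curves are flat")
    out: dict[str, KaplanMeierCurve] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event_observed=event[sel])
        sf = kmf.survival_function_
        t = sf.index.to_numpy(dtype=float)
        s = sf.iloc[:, 0].to_numpy(dtype=float)
        below = s <= 0.5
        median = float(t[below][0]) if below.any() else float("nan")
        out[str(g)] = KaplanMeierCurve(
            group=str(g), times=t, survival=s, median=median,
            n=int(sel.sum()), events=int(event[sel].sum()),
        )
    return out


def logrank_test(
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> tuple[float, float]:
    """k-group log-rank chi-square (k-1 df) and p-value."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    if event.sum() < 1:
        raise ValueError("log-rank test undefined with no events")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time_days",
    event_col: str = "event",
    ties: str = "breslow",
    model_type: str = "multivariate",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate.

    ``model_type='multivariate'`` fits all covariates jointly;
    ``'univariate'`` fits each covariate in its own model (the screening
    columns of a typical survival-modeling table). Rows with missing values
    in the model's columns are dropped with a logged count. Returns a frame
    with columns covariate, hazard_ratio, ci_low, ci_high, p_value, n, events,
    model_type.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    if model_type not in ("multivariate", "univariate"):
        raise ValueError(f"unknown model_type {model_type!r}")
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates given")
    if model_type == "univariate":
        parts = [
            cox_fit(df, [c], time_col, event_col, ties, "multivariate")
            for c in covariates
        ]
        out = pd.concat(parts, ignore_index=True)
        out["model_type"] = "univariate"
        return out

    cols = [time_col, event_col, *covariates]
    data = df[cols].dropna()
    n_dropped = len(df) - len(data)
    if n_dropped:
        logger.info("Cox model: dropped %d row(s) with missing covariates", n_dropped)
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r}")
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        logger.warning(
            "Cox model: %d events for %d covariates; estimates may be unstable",
            n_events, len(covariates),
        )
    model = PHReg(
        np.asarray(data[time_col], dtype=float),
        np.asarray(data[covariates], dtype=float),
        status=np.asarray(data[event_col], dtype=int),
        ties=ties,
    )
    try:
        res = model.fit(maxiter=100, disp=False)
    except Exception as exc:  # pragma: no cover - statsmodels error surface
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    coef = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(coef)) or np.max(np.abs(coef)) > 50:
        abs_coef = np.where(np.isfinite(coef), np.abs(coef), np.inf)
        bad = covariates[int(np.argmax(abs_coef))]
        raise RuntimeError(
            f"Cox fit did not converge to a finite estimate (covariate {bad!r}); "
            "possible monotone likelihood / perfect separation"
        )
    se = np.asarray(res.bse, dtype=float)
    z = 1.959963984540054
    with np.errstate(over="ignore"):  # a huge SE exponentiates to an inf CI bound
        ci_low = np.exp(coef - z * se)
        ci_high = np.exp(coef + z * se)
    return pd.DataFrame(
        {
            "covariate": covariates,
            "hazard_ratio": np.exp(coef),
            "ci_low": ci_low,
            "ci_high": ci_high,
            "p_value": np.asarray(res.pvalues, dtype=float),
            "n": len(data),
            "events": n_events,
            "model_type": model_type,
        }
    )


def subtype_indicators(
    labels: pd.Series, reference: int | str
) -> pd.DataFrame:
    """Encode subtype as indicator columns against a reference subtype.

    Mirrors the convention of reporting the low- and high-interdependence
    subtypes against the intermediate one: each non-reference level gets a
    column ``subtype_<level>`` that is 1 for members of that level.
    """
    levels = sorted(pd.unique(labels), key=str)
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among labels {levels}")
    out = pd.DataFrame(index=labels.index)
    for lev in levels:
        if lev == reference:
            continue
        out[f"subtype_{lev}"] = (labels == lev).astype(int)
    return out
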