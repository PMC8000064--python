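"""Kaplan-Meier curves, log-rank tests and hazard ratios for gene screens.

Each screened gene dichotomizes the cohort at a quantile of its expression
(default the median; subjects exactly at the cut go to the low group — a
deterministic, documented tie rule).  Per gene the screen reports the
log-rank p-value, the hazard ratio of high vs low from a single-covariate
proportional-hazards fit (partial likelihood, Efron tie handling), its 95%
Wald interval and p-value.  A gene is flagged significant when either the
log-rank p or the hazard-ratio p is <= 0.05 (inclusive).

Times are in months throughout.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)

__all__ = [
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "screen_genes",
]


def dichotomize(
    table: pd.DataFrame, gene: str, cutoff_quantile: float = 0.5
) -> pd.Series:
    """Split subjects into high/low expression groups at a quantile cut.

    High iff expression strictly exceeds the cut value; exact ties go low.
    """
    values = table[gene].astype(float)
    if values.isna().any():
        raise ValueError(f"{gene}: missing expression values")
    cut = values.quantile(cutoff_quantile)
    if values.nunique() == 1:
        raise ValueError(f"{gene}: all expression values identical, degenerate split")
    groups = pd.Series(
        np.where(values > cut, "high", "low"), index=table.index, name=gene
    )
    return groups


def km_estimate(
    table: pd.DataFrame, groups: pd.Series
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns group -> DataFrame(time, survival); censored subjects decrement
    the risk set without a probability step.
    """
    out: dict[str, pd.DataFrame] = {}
    for name in sorted(groups.unique()):
        mask = groups == name
        if mask.sum() == 0:
            raise ValueError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(table.loc[mask, "time_months"], table.loc[mask, "event"])
        sf = kmf.survival_function_
        out[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    return out


def logrank_test(table: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Mantel-Haenszel log-rank comparison of two groups; returns (chi2, p)."""
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {names}")
    if table["event"].sum() == 0:
        raise ValueError("no events in either group")
    a = groups == names[0]
    res = _ll_logrank(
        table.loc[a, "time_months"],
        table.loc[~a, "time_months"],
        event_observed_A=table.loc[a, "event"],
        event_observed_B=table.loc[~a, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(
    table: pd.DataFrame, groups: pd.Series
) -> tuple[float, tuple[float, float], float]:
    """High-vs-low hazard ratio from a single-covariate proportional-hazards fit.

    Returns (hr, (ci_low, ci_high), p) with a 95% Wald interval.  Complete
    separation (all events in one group before any in the other) yields an
    infinite bound and is logged rather than raised.
    """
    if set(groups.unique()) - {"high", "low"}:
        raise ValueError("groups must be labelled high/low")
    df = pd.DataFrame(
        {
            "time": table["time_months"].to_numpy(float),
            "event": table["event"].to_numpy(int),
            "high": (groups == "high").astype(int).to_numpy(),
        }
    )
    for label in ("high", "low"):
        mask = df["high"] == (1 if label == "high" else 0)
        if df.loc[mask, "event"].sum() == 0:
            logger.warning("hazard_ratio: zero events in the %s group", label)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        logger.warning("hazard_ratio: separation detected, unbounded estimate")
        sign = 1.0 if df.loc[df["high"] == 1, "event"].mean() > 0 else -1.0
        return (np.inf if sign > 0 else 0.0), (0.0, np.inf), np.nan
    coef = float(cph.params_["high"])
    se = float(cph.standard_errors_["high"])
    hr = float(np.exp(coef))
    ci = (float(np.exp(coef - 1.959963984540054 * se)),
          float(np.exp(coef + 1.959963984540054 * se)))
    p = float(cph.summary.loc["high", "p"])
    return hr, ci, p


def screen_genes(
    table: pd.DataFrame,
    genes: Sequence[str],
    cutoff_quantile: float = 0.5,
) -> pd.DataFrame:
    """Median-split survival screen over a gene list.

    One row per gene, in input order, with the log-rank p, hazard ratio,
    95% CI, hazard-ratio p, per-group median survival (for transparency)
    and the dual significance flag (log-rank p <= 0.05 or HR p <= 0.05).
    Genes missing from the table yield a flagged NaN row and the screen
    continues.
    """
    rows = []
    for gene in genes:
        gene = str(gene)
        if gene not in table.columns:
            logger.warning("screen_genes: %s missing from the survival table", gene)
            rows.append(
                {
                    "gene": gene, "logrank_p": np.nan, "hazard_ratio": np.nan,
                    "hr_ci_low": np.nan, "hr_ci_high": np.nan, "hr_p": np.nan,
                    "median_survival_high": np.nan, "median_survival_low": np.nan,
                    "significant": False, "missing": True,
                }
            )
            continue
        groups = dichotomize(table, gene, cutoff_quantile)
        chi2, lr_p = logrank_test(table, groups)
        hr, (lo, hi), hr_p = hazard_ratio(table, groups)
        med = {}
        for name in ("high", "low"):
            kmf = KaplanMeierFitter()
            mask = groups == name
            kmf.fit(table.loc[mask, "time_months"], table.loc[mask, "event"])
            med[name] = float(kmf.median_survival_time_)
        significant = bool(
            (lr_p <= 0.05) or (not np.isnan(hr_p) and hr_p <= 0.05)
        )
        rows.append(
            {
                "gene": gene, "logrank_p": lr_p, "hazard_ratio": hr,
                "hr_ci_low": lo, "hr_ci_high": hi, "hr_p": hr_p,
                "median_survival_high": med["high"],
                "median_survival_low": med["low"],
                "significant": significant, "missing": False,
            }
        )
    return pd.DataFrame(rows)
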