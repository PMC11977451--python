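"""Standardised climate anomalies for census intervals.

Monthly series of heat and drought-stress proxies (maximum temperature
``T_max``, vapour pressure deficit ``VPD``, climatic water deficit ``CWD``)
are converted to z-scores against a multi-decadal monthly climatology, then
averaged over the 24 months preceding each census to give one interval-level
anomaly ``CA_t`` per variable, in SD units.  Positive anomalies always mean
*more* stress than usual (for CWD the sign convention is deficit-positive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ClimatologyScaler",
    "monthly_climatology",
    "standardize_months",
    "interval_anomaly",
    "interval_anomalies",
    "census_interval_ends",
]

#: columns expected of a monthly climate table
CLIMATE_COLUMNS = ("variable", "year", "month", "value")


def _check_monthly(series: pd.DataFrame) -> pd.DataFrame:
    missing = set(CLIMATE_COLUMNS) - set(series.columns)
    if missing:
        raise ValueError(f"monthly climate table lacks columns {sorted(missing)}")
    if series.duplicated(["variable", "year", "month"]).any():
        raise ValueError("duplicate (variable, year, month) rows in climate table")
    return series


class ClimatologyScaler(BaseEstimator, TransformerMixin):
    """Standardise monthly climate values against a baseline climatology.

    ``fit`` learns, for every (variable, calendar month) pair, the mean and
    sample SD (denominator ``n - 1``) over the baseline years.  ``transform``
    returns the input table with an ``anomaly`` column, the per-month z-score.

    Parameters
    ----------
    baseline : (int, int)
        First and last year (inclusive) of the climatology window.  The
        default spans the 30-year study window 1991-2021.
    """

    def __init__(self, baseline: tuple[int, int] = (1991, 2021)):
        self.baseline = baseline

    def fit(self, X: pd.DataFrame, y=None) -> "ClimatologyScaler":
        X = _check_monthly(X)
        lo, hi = self.baseline
        base = X[(X["year"] >= lo) & (X["year"] <= hi)]
        gaps = []
        for var, sub in base.groupby("variable"):
            have = set(zip(sub["year"], sub["month"]))
            for year in range(lo, hi + 1):
                for month in range(1, 13):
                    if (year, month) not in have:
                        gaps.append((var, year, month))
        if gaps:
            raise ValueError(f"baseline window has missing months: {gaps[:10]}"
                             + ("..." if len(gaps) > 10 else ""))
        stats = (
            base.groupby(["variable", "month"])["value"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1))
            .reset_index()
        )
        zero = stats[stats["sd"] == 0]
        if len(zero):
            rows = list(zip(zero["variable"], zero["month"]))
            raise ValueError(f"zero climatological SD for (variable, month): {rows}")
        stats["baseline_start"] = lo
        stats["baseline_end"] = hi
        self.climatology_ = stats
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "climatology_"):
            raise ValueError("ClimatologyScaler is not fitted")
        X = _check_monthly(X)
        merged = X.merge(self.climatology_[["variable", "month", "mean", "sd"]],
                         on=["variable", "month"], how="left")
        if merged["mean"].isna().any():
            bad = merged.loc[merged["mean"].isna(), ["variable", "month"]]
            raise ValueError(
                "months outside the fitted climatology: "
                f"{sorted(set(map(tuple, bad.itertuples(index=False))))}"
            )
        merged["anomaly"] = (merged["value"] - merged["mean"]) / merged["sd"]
        return merged.drop(columns=["mean", "sd"])


def monthly_climatology(series: pd.DataFrame,
                        baseline: tuple[int, int] = (1991, 2021)) -> pd.DataFrame:
    """Per-variable, per-calendar-month mean and sample SD over the baseline."""
    return ClimatologyScaler(baseline=baseline).fit(series).climatology_


def standardize_months(series: pd.DataFrame,
                       climatology: pd.DataFrame) -> pd.DataFrame:
    """z-score each monthly value against the supplied climatology."""
    scaler = ClimatologyScaler()
    scaler.climatology_ = climatology
    return scaler.transform(series)


def _window_months(t_end: int, window: int, census_month: int):
    """(year, month) pairs of the ``window`` months ending at the census month."""
    months = []
    year, month = t_end, census_month
    for _ in range(window):
        months.append((year, month))
        month -= 1
        if month == 0:
            year, month = year - 1, 12
    return months[::-1]


def interval_anomaly(std_anomalies: pd.DataFrame, t_end: int, *,
                     variable: str | None = None, window: int = 24,
                     census_month: int = 12) -> float:
    """Mean standardised anomaly over the ``window`` months before census ``t_end``.

    Censuses are assigned to ``census_month`` (December by default), so for
    the default 24-month window the interval covers Jan(t_end-1)..Dec(t_end).
    """
    sub = std_anomalies
    if variable is not None:
        sub = sub[sub["variable"] == variable]
    if sub["variable"].nunique() > 1:
        raise ValueError("pass `variable=` when the table holds several variables")
    wanted = _window_months(t_end, window, census_month)
    lookup = dict(zip(zip(sub["year"], sub["month"]), sub["anomaly"]))
    try:
        values = [lookup[key] for key in wanted]
    except KeyError as err:
        raise ValueError(
            f"interval ending {t_end}: month {err.args[0]} not standardised"
        ) from None
    return float(np.mean(values))


def interval_anomalies(std_anomalies: pd.DataFrame, t_ends, *,
                       window: int = 24, census_month: int = 12) -> pd.DataFrame:
    """Table of CA_t for every variable and every census end-year in ``t_ends``."""
    rows = []
    for var, sub in std_anomalies.groupby("variable"):
        for t_end in t_ends:
            rows.append({
                "variable": var,
                "t_end": int(t_end),
                "ca": interval_anomaly(sub, int(t_end), window=window,
                                       census_month=census_month),
                "window_months": window,
            })
    return pd.DataFrame(rows)


def census_interval_ends(first_year: int = 1991, last_year: int = 2021,
                         step: int = 2) -> list[int]:
    """End-years of the biennial census intervals inside [first, last].

    Biennial censuses from 1991 to 2021 define 15 two-year growth intervals
    ending 1993, 1995, ..., 2021.
    """
    return list(range(first_year + step, last_year + 1, step))
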