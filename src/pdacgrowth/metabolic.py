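"""Soft-tissue wasting rates and blood-glucose trends in the pre-diagnostic window.

Body-composition areas (subcutaneous abdominal fat, visceral abdominal fat,
muscle) quantified on a single axial CT slice are converted to volumes via
the slice thickness. Wasting is summarized per patient as the percent
change per month between the earliest pre-diagnostic and the diagnostic
scan. Blood glucose is summarized as an ordinary-least-squares slope over
the 24 months before diagnosis. Group contrasts (high vs low delta) use
Welch's unequal-variance two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, TimeSeries

logger = logging.getLogger(__name__)

BG_WINDOW_MONTHS = (-24.0, 0.0)


class InsufficientDataError(ValueError):
    """Too few usable points for a rate or trend estimate."""


def tissue_volume(area_cm2: float, slice_thickness_mm: float) -> float:
    """Single-slice compartment volume, cm^3 = area (cm^2) x thickness (cm)."""
    if slice_thickness_mm <= 0:
        raise ValueError(f"slice thickness must be positive, got {slice_thickness_mm}")
    if area_cm2 < 0:
        raise ValueError(f"area must be non-negative, got {area_cm2}")
    return area_cm2 * slice_thickness_mm / 10.0


def wasting_rate(series: TimeSeries) -> float:
    """Percent change per month between the first and last scans.

    100 * (V_last - V_first) / (V_first * (t_last - t_first)); negative for
    tissue loss. Invariant to rescaling the volumes by a positive constant.
    """
    if len(series) < 2:
        raise InsufficientDataError(f"need >=2 points, got {len(series)}")
    v = series.values_array
    t = series.times_array
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("zero time span between first and last scan")
    return float(100.0 * (v[-1] - v[0]) / (v[0] * span))


def wasting_rate_regression(series: TimeSeries) -> float:
    """Alternative estimator: OLS slope of volume on time, as % of baseline/month."""
    if len(series) < 2:
        raise InsufficientDataError(f"need >=2 points, got {len(series)}")
    t = series.times_array
    v = series.values_array
    if t[-1] - t[0] <= 0:
        raise ValueError("zero time span")
    slope = stats.linregress(t, v).slope
    return float(100.0 * slope / v[0])


def bg_trend(series: TimeSeries, window: tuple[float, float] = BG_WINDOW_MONTHS) -> float:
    """OLS slope (mg/dL per month) of glucose on time within the window."""
    t = series.times_array
    v = series.values_array
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need >=2 glucose readings in [{window[0]}, {window[1]}] months, "
            f"got {int(mask.sum())}"
        )
    t, v = t[mask], v[mask]
    if np.ptp(t) == 0:
        raise InsufficientDataError("all in-window readings share one timestamp")
    if np.ptp(v) == 0:
        return 0.0
    return float(stats.linregress(t, v).slope)


@dataclass(frozen=True)
class WastingRate:
    patient_id: str
    tissue: str
    rate: float  # % change per month


@dataclass(frozen=True)
class GroupComparison:
    """Welch's t-test contrast between two groups of per-patient summaries."""

    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    df: float
    n_a: int
    n_b: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "t_statistic": self.t_statistic, "p_value": self.p_value,
            "df": self.df, "n_a": self.n_a, "n_b": self.n_b,
        }


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-tailed Welch's t-test (unequal variances) between two groups.

    If both groups are constant the test is degenerate: p=1 when the means
    agree, p=0 (flagged) when they differ.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >=2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        equal = np.isclose(a.mean(), b.mean())
        return GroupComparison(
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            t_statistic=0.0 if equal else float("inf"),
            p_value=1.0 if equal else 0.0,
            df=float(len(a) + len(b) - 2),
            n_a=len(a), n_b=len(b), degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_statistic=float(res.statistic), p_value=float(res.pvalue),
        df=float(res.df), n_a=len(a), n_b=len(b),
    )


def cohort_wasting_rates(cohort: Cohort, method: str = "endpoints") -> pd.DataFrame:
    """Per-patient, per-tissue wasting rates for a cohort.

    Returns a tidy frame (patient_id, delta_class, tissue, rate_pct_per_month);
    patients lacking a tissue series are simply absent for that tissue.
    """
    estimator = {"endpoints": wasting_rate, "regression": wasting_rate_regression}[method]
    rows = []
    for p in cohort:
        if not p.tissue_series:
            continue
        for tissue, series in p.tissue_series.items():
            if len(series) < 2:
                logger.warning("patient %s: %s series too short, skipped", p.patient_id, tissue)
                continue
            rows.append({
                "patient_id": p.patient_id,
                "delta_class": p.delta_class.value,
                "tissue": tissue,
                "rate_pct_per_month": estimator(series),
            })
    return pd.DataFrame(rows, columns=["patient_id", "delta_class", "tissue", "rate_pct_per_month"])


def cohort_bg_trends(cohort: Cohort, window=BG_WINDOW_MONTHS) -> pd.DataFrame:
    """Per-patient BG slopes; patients with <2 in-window readings are excluded
    with a warning (returned frame notes only included patients)."""
    rows = []
    for p in cohort:
        if p.bg_series is None:
            continue
        try:
            slope = bg_trend(p.bg_series, window=window)
        except InsufficientDataError as err:
            logger.warning("patient %s excluded from BG trend: %s", p.patient_id, err)
            continue
        rows.append({
            "patient_id": p.patient_id,
            "delta_class": p.delta_class.value,
            "bg_slope_mg_dl_per_month": slope,
        })
    return pd.DataFrame(rows, columns=["patient_id", "delta_class", "bg_slope_mg_dl_per_month"])
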