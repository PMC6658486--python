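"""Otolith-derived life-history analytics.

Daily otolith increments give pelagic larval duration (PLD, core to
settlement mark) and total age (core to margin) for a read subset of
juveniles; ages of the rest are predicted from body length by ordinary
least squares, hatch dates are back-calculated from collection dates, and
individuals are binned into season cohorts (early/late hatchers) and
settlement classes (recent settlers vs survivors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeLengthModel",
    "calibrate_age_length",
    "estimate_ages",
    "hatch_dates",
    "SeasonConfig",
    "assign_season_cohort",
    "assign_settlement_class",
    "pld_hatchdate_correlation",
]


@dataclass
class AgeLengthModel:
    """OLS regression of otolith age (days) on body length (mm)."""

    slope: float
    intercept: float
    pearson_r: float
    n: int
    length_min: float
    length_max: float

    def predict(self, length_mm) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(length_mm, dtype=float)


def calibrate_age_length(lengths_mm, ages_days) -> AgeLengthModel:
    """Fit age ~ length by ordinary least squares and report Pearson's R."""
    x = np.asarray(lengths_mm, dtype=float)
    y = np.asarray(ages_days, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration pairs")
    if np.std(x) == 0:
        raise ValueError("constant lengths: regression undefined")
    res = stats.linregress(x, y)
    return AgeLengthModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=int(x.size),
        length_min=float(x.min()),
        length_max=float(x.max()),
    )


def estimate_ages(model: AgeLengthModel, lengths_mm) -> tuple[np.ndarray, np.ndarray]:
    """Predict integer ages (days) from lengths; predictions are rounded to
    the nearest day and clipped below at 1. Returns (ages, extrapolated)
    where the flag marks lengths outside the calibration range."""
    x = np.asarray(lengths_mm, dtype=float)
    pred = np.rint(model.predict(x)).astype(int)
    pred = np.maximum(pred, 1)
    extrapolated = (x < model.length_min) | (x > model.length_max)
    return pred, extrapolated


def hatch_dates(collection_dates, age_days) -> pd.Series:
    """Calendar-correct hatch date = collection date - age (days)."""
    cd = pd.to_datetime(pd.Series(collection_dates))
    ages = np.asarray(age_days)
    if np.any(ages > 400):
        warnings.warn("age exceeds 400 days for a juvenile")
    return cd - pd.to_timedelta(ages, unit="D")


@dataclass
class SeasonConfig:
    """Calendar windows for hatch-season cohorts.

    'Early' hatchers fall between the season start and mid-May; 'late'
    hatchers between mid-June and the end of the recruitment season (taken
    as the beginning of September); everyone else is 'mid'.
    """

    year: int
    early_start: tuple[int, int] = (4, 1)   # Apr 1
    early_end: tuple[int, int] = (5, 15)    # May 15
    late_start: tuple[int, int] = (6, 15)   # Jun 15
    season_end: tuple[int, int] = (9, 7)    # beginning of September

    def _d(self, md: tuple[int, int]) -> date:
        return date(self.year, md[0], md[1])


def assign_season_cohort(hatch, config: SeasonConfig) -> np.ndarray:
    """Label hatch dates early / late / mid according to the season windows."""
    hd = pd.to_datetime(pd.Series(hatch)).dt.date
    lo, hi = date(config.year, 3, 1), date(config.year, 10, 31)
    if any(d < lo or d > hi for d in hd):
        warnings.warn("hatch date outside March-October window")
    out = np.full(len(hd), "mid", dtype=object)
    e0, e1 = config._d(config.early_start), config._d(config.early_end)
    l0, l1 = config._d(config.late_start), config._d(config.season_end)
    for i, d in enumerate(hd):
        if e0 <= d <= e1:
            out[i] = "early"
        elif l0 <= d <= l1:
            out[i] = "late"
    return out


def assign_settlement_class(length_mm, age_days) -> np.ndarray:
    """Recent settlers: < 30 mm and < 30 days total age. Survivors (alive at
    least ~30 days past settlement): > 35 mm and > 50 days. Otherwise
    neither (the rule gap is deliberate)."""
    ln = np.asarray(length_mm, dtype=float)
    ag = np.asarray(age_days, dtype=float)
    out = np.full(ln.shape, "neither", dtype=object)
    out[(ln < 30) & (ag < 30)] = "recent_settler"
    out[(ln > 35) & (ag > 50)] = "survivor"
    return out


def pld_hatchdate_correlation(pld_days, hatch) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) of PLD against hatch
    day-of-year: later-born larvae settle faster in warmer water."""
    pld = np.asarray(pld_days, dtype=float)
    doy = pd.to_datetime(pd.Series(hatch)).dt.dayofyear.to_numpy(dtype=float)
    if pld.size < 3:
        raise ValueError("need at least 3 records")
    if np.std(pld) == 0 or np.std(doy) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(pld, doy)
    return float(r), float(p)
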