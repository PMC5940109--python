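"""Telomere qPCR T/S ratios and biological-age calibration.

Telomere length is read out as the T/S ratio — the abundance of the
telomeric repeat relative to a single-copy reference gene (36B4) —
computed from qPCR cycle thresholds as T/S = 2^-dCt with
dCt = Ct(telomere) - Ct(reference).  Relative T/S anchors the youngest
group to 1.0.  A linear calibration of relative T/S on chronological age
in wild-type animals then converts any relative T/S into a biological
age; the disease-model adjustment multiplies the wild-type-old relative
T/S by the measured disease/wild-type ratio before inversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Calibration cannot be fitted or inverted."""


def ts_ratio(
    ct_telomere,
    ct_reference,
    efficiency: float = 2.0,
    replicate_mode: str = "mean_ct",
) -> float:
    """T/S ratio from cycle thresholds: efficiency^(ct_ref - ct_tel).

    Replicate lists are averaged on the Ct scale before exponentiation
    (standard delta-Ct practice); ``replicate_mode='mean_ts'`` averages
    the per-replicate ratios instead.  PCR efficiency defaults to
    exactly 2.
    """
    ct_t = np.atleast_1d(np.asarray(ct_telomere, dtype=float))
    ct_r = np.atleast_1d(np.asarray(ct_reference, dtype=float))
    if not (np.isfinite(ct_t).all() and np.isfinite(ct_r).all()):
        raise ValueError("Ct values must be finite")
    if efficiency <= 1.0:
        raise ValueError("PCR efficiency must be > 1")
    if replicate_mode == "mean_ct":
        return float(efficiency ** (ct_r.mean() - ct_t.mean()))
    if replicate_mode == "mean_ts":
        if ct_t.size != ct_r.size:
            raise ValueError("paired replicates required for mean_ts mode")
        return float(np.mean(efficiency ** (ct_r - ct_t)))
    raise ValueError("replicate_mode must be 'mean_ct' or 'mean_ts'")


def relativize(
    ts_by_sample: pd.Series, baseline: list[str] | pd.Index
) -> pd.Series:
    """Divide every T/S by the baseline-group mean so baseline maps to 1.0."""
    baseline = list(baseline)
    if not baseline:
        raise ValueError("baseline sample set is empty")
    base_mean = float(ts_by_sample.loc[baseline].mean())
    if base_mean == 0.0 or not math.isfinite(base_mean):
        raise ValueError("baseline mean T/S is zero or non-finite")
    return ts_by_sample / base_mean


@dataclass(frozen=True)
class TelomereCalibration:
    """Linear model of relative T/S on age (months)."""

    slope: float
    intercept: float
    r_squared: float
    decline_rate_pct_per_month: float
    baseline_age_months: float
    fit_ages: tuple[float, ...]

    def predict(self, age_months: float) -> float:
        return self.slope * age_months + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "decline_rate_pct_per_month": self.decline_rate_pct_per_month,
            "baseline_age_months": self.baseline_age_months,
            "fit_ages": list(self.fit_ages),
        }


class TelomereClock(RegressorMixin, BaseEstimator):
    """sklearn-style regressor: relative T/S as a linear function of age.

    ``fit(ages, relative_ts)`` exposes ``slope_``, ``intercept_``,
    ``r_squared_`` and ``decline_rate_pct_per_month_`` (= -slope x 100,
    in relative-T/S units per month); ``predict(ages)`` gives the fitted
    relative T/S and ``infer_age(relative_ts)`` inverts the line.
    """

    def __init__(self, baseline_age_months: float = 2.0):
        self.baseline_age_months = baseline_age_months

    def fit(self, ages, relative_ts, y=None):
        x = np.asarray(ages, dtype=float).ravel()
        t = np.asarray(relative_ts, dtype=float).ravel()
        if x.size != t.size or x.size < 2:
            raise CalibrationError("need >= 2 (age, relative T/S) points")
        if np.unique(x).size < 2:
            raise CalibrationError("need >= 2 distinct ages")
        fit = stats.linregress(x, t)
        self.slope_ = float(fit.slope)
        self.intercept_ = float(fit.intercept)
        self.r_squared_ = float(fit.rvalue**2)
        self.decline_rate_pct_per_month_ = -self.slope_ * 100.0
        self.fit_ages_ = tuple(sorted(set(x.tolist())))
        return self

    def predict(self, ages) -> np.ndarray:
        self._check_fitted()
        return self.slope_ * np.asarray(ages, dtype=float) + self.intercept_

    def infer_age(self, relative_ts: float) -> float:
        """Invert the calibration: the wild-type age whose fitted relative
        T/S equals the given value (the sample's biological age)."""
        self._check_fitted()
        if self.slope_ >= 0:
            raise CalibrationError(
                "calibration slope is non-negative; cannot invert a "
                "non-declining telomere trend"
            )
        age = (float(relative_ts) - self.intercept_) / self.slope_
        if self.fit_ages_ and age > max(self.fit_ages_):
            logger.warning(
                "biological age %.2f months extrapolates beyond the oldest "
                "calibration age (%.2f months)", age, max(self.fit_ages_),
            )
        return age

    def _check_fitted(self):
        if not hasattr(self, "slope_"):
            raise RuntimeError("TelomereClock is not fitted")


def fit_calibration(
    ages,
    relative_ts,
    baseline_age_months: float = 2.0,
) -> TelomereCalibration:
    """OLS of relative T/S on age; decline rate = -slope x 100 %/month."""
    clock = TelomereClock(baseline_age_months).fit(ages, relative_ts)
    return TelomereCalibration(
        slope=clock.slope_,
        intercept=clock.intercept_,
        r_squared=clock.r_squared_,
        decline_rate_pct_per_month=clock.decline_rate_pct_per_month_,
        baseline_age_months=baseline_age_months,
        fit_ages=clock.fit_ages_,
    )


def infer_bio_age(
    calib: TelomereCalibration, relative_ts: float
) -> tuple[float, int]:
    """Biological age at a relative T/S: (relative_ts - intercept)/slope.

    Returns the unrounded value and its nearest-month rounding.
    """
    if calib.slope >= 0:
        raise CalibrationError("cannot invert a non-declining calibration")
    age = (float(relative_ts) - calib.intercept) / calib.slope
    if calib.fit_ages and age > max(calib.fit_ages):
        logger.warning(
            "biological age %.2f months extrapolates beyond the oldest "
            "calibration age (%.2f months)", age, max(calib.fit_ages),
        )
    return age, int(round(age))


def hd_adjustment(
    reference_relative_ts: float, ratio_to_reference: float
) -> tuple[float, float]:
    """Disease-group relative T/S: reference relative T/S x measured
    disease/reference ratio; returned at full precision and 2 dp."""
    if reference_relative_ts <= 0 or ratio_to_reference <= 0:
        raise ValueError("both inputs must be > 0")
    full = reference_relative_ts * ratio_to_reference
    return full, round(full, 2)


def acceleration(bio_age_months: float, chrono_age_months: float) -> float:
    """Aging-acceleration factor: biological / chronological age."""
    if chrono_age_months <= 0:
        raise ValueError("chronological age must be > 0")
    return bio_age_months / chrono_age_months


def ts_table_from_ct(
    ct_table: pd.DataFrame,
    efficiency: float = 2.0,
    replicate_mode: str = "mean_ct",
) -> pd.DataFrame:
    """Collapse a long Ct table (sample_id, age_months, ct_telomere,
    ct_ref) into one T/S ratio per sample."""
    required = {"sample_id", "age_months", "ct_telomere", "ct_ref"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = ct_table[
        ~ct_table["ct_telomere"].between(0, 45, inclusive="neither")
        | ~ct_table["ct_ref"].between(0, 45, inclusive="neither")
    ]
    if len(bad):
        raise ValueError(
            f"Ct values outside (0, 45) for samples "
            f"{bad['sample_id'].unique().tolist()[:5]}"
        )
    rows = []
    for (sid, age), grp in ct_table.groupby(["sample_id", "age_months"]):
        rows.append(
            {
                "sample_id": sid,
                "age_months": age,
                "ts": ts_ratio(
                    grp["ct_telomere"].to_numpy(),
                    grp["ct_ref"].to_numpy(),
                    efficiency=efficiency,
                    replicate_mode=replicate_mode,
                ),
            }
        )
    return pd.DataFrame(rows)


def calibrate_from_ct_table(
    ct_table: pd.DataFrame,
    baseline_age_months: float = 2.0,
    fit_on: str = "age_means",
    efficiency: float = 2.0,
) -> tuple[TelomereCalibration, pd.DataFrame]:
    """Full path from a Ct table to a calibration.

    T/S per sample, relativized to the baseline-age group mean, then OLS
    on age means (default) or on all samples (``fit_on='samples'``).
    Returns the calibration and the per-sample table with relative T/S.
    """
    ts = ts_table_from_ct(ct_table, efficiency=efficiency)
    baseline_samples = ts.loc[
        ts["age_months"] == baseline_age_months, "sample_id"
    ]
    if baseline_samples.empty:
        raise CalibrationError(
            f"no samples at baseline age {baseline_age_months} months"
        )
    rel = relativize(
        ts.set_index("sample_id")["ts"], list(baseline_samples)
    )
    ts = ts.assign(relative_ts=rel.loc[ts["sample_id"]].to_numpy())
    if fit_on == "age_means":
        by_age = ts.groupby("age_months")["relative_ts"].mean()
        calib = fit_calibration(
            by_age.index.to_numpy(), by_age.to_numpy(), baseline_age_months
        )
    elif fit_on == "samples":
        calib = fit_calibration(
            ts["age_months"].to_numpy(),
            ts["relative_ts"].to_numpy(),
            baseline_age_months,
        )
    else:
        raise ValueError("fit_on must be 'age_means' or 'samples'")
    return calib, ts
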