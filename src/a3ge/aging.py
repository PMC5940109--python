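"""Linear model of A3GE as a function of age.

A3GE points — one per sample group, at chronological age or (for the
accelerated-aging disease group) the telomere-derived biological age —
are fitted with ordinary least squares.  The regression coefficient is
the drift rate per month; the x-intercept is the onset age at which
drift becomes detectable; inverting the line answers questions like
"at what age does A3GE reach 50%?".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin


class RateModelError(ValueError):
    """Degenerate aging-rate fit."""


class AgingRateModel(RegressorMixin, BaseEstimator):
    """OLS of A3GE on age (months).

    Fitted attributes: ``rate_per_month_`` (the regression coefficient),
    ``intercept_``, ``r_squared_`` and ``onset_age_months_`` — the age
    where the fitted line crosses 0 (None when the rate is not
    positive).  ``predict`` clips to the A3GE range [0, 1];
    ``age_at_level`` inverts the unclipped line.
    """

    def fit(self, ages, a3ge_values, y=None):
        x = np.asarray(ages, dtype=float).ravel()
        v = np.asarray(a3ge_values, dtype=float).ravel()
        if x.size != v.size or x.size < 2:
            raise RateModelError("need >= 2 (age, A3GE) points")
        if np.unique(x).size < 2:
            raise RateModelError("need >= 2 distinct ages")
        fit = stats.linregress(x, v)
        self.rate_per_month_ = float(fit.slope)
        self.intercept_ = float(fit.intercept)
        self.r_squared_ = float(fit.rvalue**2)
        self.onset_age_months_ = (
            -self.intercept_ / self.rate_per_month_
            if self.rate_per_month_ > 0
            else None
        )
        return self

    def predict(self, ages) -> np.ndarray:
        self._check_fitted()
        raw = self.rate_per_month_ * np.asarray(ages, dtype=float) + self.intercept_
        return np.clip(raw, 0.0, 1.0)

    def age_at_level(self, level: float) -> float:
        """Age at which the fitted (unclipped) line reaches an A3GE level."""
        self._check_fitted()
        if not (0.0 < level <= 1.0):
            raise RateModelError("level must be in (0, 1]")
        if self.rate_per_month_ <= 0:
            raise RateModelError(
                "rate is not positive; the line never reaches the level"
            )
        return (level - self.intercept_) / self.rate_per_month_

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "rate_per_month": self.rate_per_month_,
            "intercept": self.intercept_,
            "r_squared": self.r_squared_,
            "onset_age_months": self.onset_age_months_,
        }

    def _check_fitted(self):
        if not hasattr(self, "rate_per_month_"):
            raise RuntimeError("AgingRateModel is not fitted")


@dataclass(frozen=True)
class A3gePoint:
    """One labeled (age, A3GE) observation."""

    label: str
    age_months: float
    a3ge: float

    def __post_init__(self):
        if not (0.0 <= self.a3ge <= 1.0):
            raise RateModelError(f"point {self.label}: A3GE must be in [0, 1]")


def fit_a3ge_trajectory(points: list[A3gePoint]) -> AgingRateModel:
    """Fit the aging-rate model from labeled points."""
    ages = [p.age_months for p in points]
    values = [p.a3ge for p in points]
    return AgingRateModel().fit(ages, values)


def age_at_level(model: AgingRateModel, level: float) -> float:
    return model.age_at_level(level)


def predict_a3ge(model: AgingRateModel, age_months: float) -> float:
    return float(model.predict([age_months])[0])


def read_points_tsv(path) -> list[A3gePoint]:
    """Points TSV with columns label, age_months, a3ge."""
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "age_months", "a3ge"} - set(df.columns)
    if missing:
        raise RateModelError(f"points table missing columns: {sorted(missing)}")
    return [
        A3gePoint(str(r.label), float(r.age_months), float(r.a3ge))
        for r in df.itertuples()
    ]
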