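"""Shade-selection analysis.

Quantifies how strongly fish select the shaded square during daylight:

* hourly occupancy fractions (share of detections under shade per 1-h
  window, pooled by hour of day across trial days);
* a random-movement baseline, the area fraction of the pond covered by the
  shade square;
* a logistic regression of ``under_shade ~ is_day`` whose headline quantity
  is the *probability increment* p(shade | day) - p(shade | night) implied
  by the fitted model;
* a shifted-shade control, refitting against the shade position of the
  previous/next trial — a genuine preference for the platform (rather than
  for a corner of the pond) makes the control increment vanish.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .geometry import PondGeometry, TrialSchedule
from .preprocess import classify_detections

__all__ = [
    "ShadeLogisticFit",
    "occupancy_fractions",
    "random_baseline",
    "fit_shade_preference",
    "control_shift_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShadeLogisticFit:
    """Logistic fit of under-shade status on a daylight indicator."""

    intercept: float
    daylight_coef: float
    probability_increment: float
    p_value: float
    n_day: int
    n_night: int
    separable: bool = False

    @property
    def p_shade_day(self) -> float:
        return float(expit(self.intercept + self.daylight_coef))

    @property
    def p_shade_night(self) -> float:
        return float(expit(self.intercept))


def occupancy_fractions(
    classified: pd.DataFrame, window: float = 3600.0
) -> pd.DataFrame:
    """Fraction of detections under shade per non-overlapping time window.

    Windows are aligned to the trial clock (clock hours for the default 1-h
    window); empty windows are omitted.  Returns columns ``window_start``,
    ``hour_of_day``, ``fraction``, ``n``.
    """
    if "under_shade" not in classified.columns:
        raise ValueError("detections must be classified first (under_shade column)")
    t = classified["t"].to_numpy(float)
    shade = classified["under_shade"].to_numpy(bool)
    idx = np.floor(t / window).astype(int)
    df = pd.DataFrame({"idx": idx, "shade": shade})
    grouped = df.groupby("idx")["shade"].agg(["mean", "size"]).reset_index()
    out = pd.DataFrame(
        {
            "window_start": grouped["idx"] * window,
            "hour_of_day": (grouped["idx"] * window / 3600.0) % 24.0,
            "fraction": grouped["mean"],
            "n": grouped["size"].astype(int),
        }
    )
    return out.sort_values("window_start").reset_index(drop=True)


def random_baseline(geometry: PondGeometry, label: str | None = None) -> float:
    """Expected under-shade fraction for spatially uniform movement.

    Equals area(shade square within pond) / area(pond); independent of which
    labelled square is active when all squares are congruent.
    """
    return geometry.shade_area_fraction(label)


def fit_shade_preference(classified: pd.DataFrame) -> ShadeLogisticFit:
    """Maximum-likelihood logistic fit of under_shade on the day indicator.

    With a single binary predictor the MLE reproduces the empirical
    class-conditional proportions, so the probability increment equals
    p̂(shade | day) - p̂(shade | night).  Complete separation (e.g. shade
    never entered at night) is flagged; the increment is then reported from
    the empirical proportions and the p-value is NaN.
    """
    for col in ("under_shade", "is_day"):
        if col not in classified.columns:
            raise ValueError(f"classified detections need a {col!r} column")
    y = classified["under_shade"].to_numpy(bool)
    day = classified["is_day"].to_numpy(bool)
    n_day = int(day.sum())
    n_night = int((~day).sum())
    if n_day == 0 or n_night == 0:
        raise ValueError("both day and night detections are required")
    if y.all() or not y.any():
        raise ValueError("both under-shade and open outcomes are required")

    p_day = y[day].mean()
    p_night = y[~day].mean()
    separable = p_day in (0.0, 1.0) or p_night in (0.0, 1.0)
    if separable:
        warnings.warn(
            "complete separation in shade-preference fit; increment reported "
            "from empirical proportions",
            RuntimeWarning,
            stacklevel=2,
        )
        eps = 0.5 / max(n_day, n_night)
        logit = lambda p: float(np.log(np.clip(p, eps, 1 - eps) / np.clip(1 - p, eps, 1 - eps)))
        return ShadeLogisticFit(
            intercept=logit(p_night),
            daylight_coef=logit(p_day) - logit(p_night),
            probability_increment=float(p_day - p_night),
            p_value=float("nan"),
            n_day=n_day,
            n_night=n_night,
            separable=True,
        )

    exog = sm.add_constant(day.astype(float))
    fit = sm.Logit(y.astype(float), exog).fit(disp=False)
    b0, b1 = fit.params
    increment = float(expit(b0 + b1) - expit(b0))
    return ShadeLogisticFit(
        intercept=float(b0),
        daylight_coef=float(b1),
        probability_increment=increment,
        p_value=float(fit.pvalues[1]),
        n_day=n_day,
        n_night=n_night,
        separable=False,
    )


def control_shift_analysis(
    detections: pd.DataFrame,
    geometry: PondGeometry,
    schedule: TrialSchedule,
) -> dict:
    """Refit shade preference against the neighbor trials' shade squares.

    Positions are reclassified using the shade square of the previous and of
    the next trial in the rotation (not the actual one) and the logistic
    model is refit for each available side.  Returns a dict with keys
    ``previous`` / ``next`` mapping to :class:`ShadeLogisticFit` (absent
    sides of the rotation are omitted).
    """
    out = {}
    for side, label in schedule.neighbor_labels().items():
        if label is None:
            logger.info("no %s trial in the shade rotation; side skipped", side)
            continue
        reclassified = classify_detections(
            detections, geometry, schedule, shade_label=label
        )
        out[side] = fit_shade_preference(reclassified)
    if not out:
        raise ValueError("trial has no neighbors in the shade rotation")
    return out
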