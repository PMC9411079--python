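"""The Data Quality Score (DQS) and its quality categories.

DQS maps the propagated relative error of the Gaussian peak area through the
Gaussian error function: ``DQS = 1 - erf(dA / A)``. A relative error of 0
gives a DQS of 1 (perfect agreement with the Gaussian model); the score
decays to 0 as the relative error grows without bound.

Categories I-IV correspond to relative area errors of at most 1%, 5% and
33% — the levels commonly used for significance testing — with IV collecting
everything worse. Their DQS thresholds are computed from those three relative
errors at import time, never hard-coded as decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .regression import GaussianPeak

#: Relative Gaussian-area errors bounding categories I, II and III.
CATEGORY_REL_ERRORS = (0.01, 0.05, 0.33)

CATEGORIES = ("I", "II", "III", "IV")


def dqs_from_relative_error(rel_err: float) -> float:
    """DQS of a peak with relative area error ``rel_err`` (taken absolute).

    Strictly decreasing; clamped into [0, 1] to absorb floating-point
    underflow of ``erf``.
    """
    if math.isnan(rel_err):
        raise ValueError("relative area error is NaN")
    return min(1.0, max(0.0, 1.0 - math.erf(abs(rel_err))))


#: DQS lower bounds of categories I, II, III (descending), derived at runtime.
CATEGORY_THRESHOLDS = tuple(dqs_from_relative_error(r) for r in CATEGORY_REL_ERRORS)


def categorize(dqs: float) -> str:
    """Quality category of a DQS value.

    Boundaries are half-open with the better category claiming the boundary:
    a relative area error of exactly 1% still falls in category I.
    """
    if math.isnan(dqs) or not (0.0 <= dqs <= 1.0):
        raise ValueError(f"DQS out of range: {dqs!r}")
    for category, threshold in zip(CATEGORIES, CATEGORY_THRESHOLDS):
        if dqs >= threshold:
            return category
    return CATEGORIES[-1]


@dataclass
class ScoredPeak:
    """A Gaussian peak annotated with its relative area error, DQS and category."""

    peak: GaussianPeak
    rel_area_error: float
    dqs: float
    category: str


def score_peak(peak: GaussianPeak) -> ScoredPeak:
    """Attach DQS and category to a back-transformed Gaussian peak."""
    rel_err = abs(peak.d_area / peak.area)
    dqs = dqs_from_relative_error(rel_err)
    return ScoredPeak(peak=peak, rel_area_error=rel_err, dqs=dqs, category=categorize(dqs))
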