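"""Weighted log-parabola (Caruana) regression of Gaussian peak profiles.

A Gaussian peak ``I(x) = I0 exp(-(x - x0)^2 / (2 sigma^2))`` becomes, after
log-transform, the second-order polynomial

    ln I(x) = b0 + b1 x + b2 x^2

with ``x0 = -b1/(2 b2)``, ``sigma = sqrt(-1/(2 b2))`` and
``I0 = exp(b0 - b1^2/(4 b2))``. Fitting the parabola by weighted linear
least squares avoids iterative optimization, and the coefficient
variance-covariance matrix propagates into uncertainties of the Gaussian
parameters and of the peak area ``A = I0 sigma sqrt(2 pi)``.

Two numerically equivalent solver paths are provided: an independent
3x3 normal-equation solve per profile, and a blocked sparse solve that
stacks all profiles of a spectrum into one block-diagonal system.

Before fitting, each profile's m/z axis is shifted so its most intense point
sits at zero. Raw m/z values of order 1e2-1e3 combined with peak widths of
order 1e-3 would otherwise make the Vandermonde normal equations
catastrophically ill-conditioned; the shift is undone when the centroid is
reported and leaves sigma, height and all uncertainties untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .isolation import PeakProfile

#: Fewer data points than this cannot give a fit with a residual degree of
#: freedom (three coefficients + 1).
MIN_POINTS = 4

#: Default exponent of the intensity weights w_i = (I_i / sum I)^p.
DEFAULT_WEIGHT_POWER = 2.0

REJECT_REASONS = ("min_points", "beta2_nonneg", "nonfinite")


@dataclass
class RejectRecord:
    """A profile removed by the acceptance filters, with the reason."""

    profile: PeakProfile
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REJECT_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass(eq=False)
class RegressionResult:
    """Coefficients and uncertainty of one weighted parabola fit.

    ``beta`` refers to the *centered* coordinate ``x - x_shift``; ``nrmse``
    is sqrt(MSE) normalized by the mean logarithmic intensity of the profile.
    """

    profile: PeakProfile
    beta: np.ndarray          # (b0, b1, b2)
    cov_beta: np.ndarray      # 3x3, MSE * (X^T W X)^-1
    mse: float
    dof: int
    nrmse: float
    x_shift: float


@dataclass
class GaussianPeak:
    """Back-transformed Gaussian parameters with propagated standard errors."""

    x0: float
    sigma: float
    height: float
    area: float
    d_height: float
    d_sigma: float
    d_area: float


def compute_weights(
    intensity: np.ndarray, weight_power: float = DEFAULT_WEIGHT_POWER
) -> np.ndarray:
    """Regression weights ``w_i = (I_i / sum I)^p`` over a single profile.

    The default power of 2 suits Orbitrap data; the weights are invariant
    under rescaling of the intensities.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.size == 0:
        raise ValueError("cannot compute weights of an empty profile")
    if np.any(intensity <= 0):
        raise ValueError("weights require strictly positive intensities")
    if weight_power < 0:
        raise ValueError("weight power must be nonnegative")
    return (intensity / intensity.sum()) ** weight_power


def _design(profile: PeakProfile) -> tuple[np.ndarray, np.ndarray, float]:
    """Centered design matrix, log-intensities and the applied x shift."""
    intensity = profile.intensity
    # leftmost maximum-intensity point (np.argmax tie-break) anchors x = 0
    x_shift = float(profile.mz[int(np.argmax(intensity))])
    x = profile.mz - x_shift
    design = np.column_stack((np.ones_like(x), x, x * x))
    return design, np.log(intensity), x_shift


def _finalize(
    profile: PeakProfile,
    beta: np.ndarray,
    normal_inv: np.ndarray,
    design: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    x_shift: float,
) -> Union[RegressionResult, RejectRecord]:
    if not np.all(np.isfinite(beta)):
        return RejectRecord(profile, "nonfinite")
    dof = y.size - 3
    residual = y - design @ beta
    mse = float(weights @ (residual * residual)) / dof
    cov_beta = mse * normal_inv
    nrmse = math.sqrt(mse) / float(np.mean(y)) if np.mean(y) != 0 else math.inf
    return RegressionResult(
        profile=profile,
        beta=beta,
        cov_beta=cov_beta,
        mse=mse,
        dof=dof,
        nrmse=nrmse,
        x_shift=x_shift,
    )


def _fit_one(
    profile: PeakProfile, weight_power: float
) -> Union[RegressionResult, RejectRecord]:
    design, y, x_shift = _design(profile)
    if not np.all(np.isfinite(y)):
        return RejectRecord(profile, "nonfinite")
    weights = compute_weights(profile.intensity, weight_power)
    xtw = design.T * weights
    normal = xtw @ design
    try:
        normal_inv = np.linalg.inv(normal)
    except np.linalg.LinAlgError:
        return RejectRecord(profile, "nonfinite")
    beta = normal_inv @ (xtw @ y)
    return _finalize(profile, beta, normal_inv, design, y, weights, x_shift)


def _fit_blocked(
    profiles: Sequence[PeakProfile], weight_power: float
) -> list[Union[RegressionResult, RejectRecord]]:
    """Solve all profiles of one batch as a single block-diagonal sparse system.

    The stacked design has one 3-column block per profile (elsewhere zero),
    so X^T W X is block diagonal with 3x3 blocks and the sparse solve is
    numerically equivalent to independent per-profile solves.
    """
    blocks = []
    payload = []
    for profile in profiles:
        design, y, x_shift = _design(profile)
        if not np.all(np.isfinite(y)):
            payload.append(None)
            continue
        weights = compute_weights(profile.intensity, weight_power)
        payload.append((design, y, weights, x_shift))
        blocks.append((design, y, weights))
    results: list[Union[RegressionResult, RejectRecord]] = [None] * len(profiles)  # type: ignore[list-item]
    if blocks:
        big_x = scipy.sparse.block_diag(
            [design for design, _, _ in blocks], format="csr"
        )
        big_w = scipy.sparse.diags(
            np.concatenate([weights for _, _, weights in blocks])
        )
        big_y = np.concatenate([y for _, y, _ in blocks])
        normal = (big_x.T @ big_w @ big_x).tocsc()
        rhs = big_x.T @ (big_w @ big_y)
        stacked_beta = scipy.sparse.linalg.spsolve(normal, rhs)
        normal_dense = normal.toarray()
    cursor = 0
    for index, profile in enumerate(profiles):
        if payload[index] is None:
            results[index] = RejectRecord(profile, "nonfinite")
            continue
        design, y, weights, x_shift = payload[index]
        sl = slice(3 * cursor, 3 * cursor + 3)
        beta = stacked_beta[sl]
        try:
            normal_inv = np.linalg.inv(normal_dense[sl, sl])
        except np.linalg.LinAlgError:
            results[index] = RejectRecord(profile, "nonfinite")
            cursor += 1
            continue
        results[index] = _finalize(
            profile, beta, normal_inv, design, y, weights, x_shift
        )
        cursor += 1
    return results


def fit_profiles(
    profiles: Iterable[PeakProfile],
    weight_power: float = DEFAULT_WEIGHT_POWER,
    min_points: int = MIN_POINTS,
    method: str = "per_profile",
) -> list[Union[RegressionResult, RejectRecord]]:
    """Fit every profile with the weighted log-parabola model.

    Profiles with fewer than ``min_points`` points are returned as
    :class:`RejectRecord` with reason ``min_points`` without fitting.
    ``method`` selects the per-profile dense solve (default) or the
    spectrum-level blocked sparse solve (``"blocked"``); both give the same
    coefficients to better than 1e-9 relative. Output order matches input.
    """
    profiles = list(profiles)
    results: list[Union[RegressionResult, RejectRecord]] = [None] * len(profiles)  # type: ignore[list-item]
    fittable: list[int] = []
    for index, profile in enumerate(profiles):
        if len(profile) < min_points:
            results[index] = RejectRecord(profile, "min_points")
        else:
            fittable.append(index)
    if method == "per_profile":
        for index in fittable:
            results[index] = _fit_one(profiles[index], weight_power)
    elif method == "blocked":
        fitted = _fit_blocked([profiles[i] for i in fittable], weight_power)
        for index, result in zip(fittable, fitted):
            results[index] = result
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return results


def backtransform(
    result: RegressionResult,
) -> Union[GaussianPeak, RejectRecord]:
    """Recover Gaussian parameters and propagated errors from a parabola fit.

    An upward-opening or degenerate parabola (``b2 >= 0``) has no real
    Gaussian width and is rejected. Uncertainty of the height uses the full
    coefficient covariance (the height depends on all three coefficients);
    the area error combines the height and width variances without a
    cross term.
    """
    b0, b1, b2 = result.beta
    if not (b2 < 0):
        return RejectRecord(result.profile, "beta2_nonneg")
    xc = -b1 / (2.0 * b2)                      # centroid in centered coords
    sigma = math.sqrt(-1.0 / (2.0 * b2))
    height = math.exp(b0 - b1 * b1 / (4.0 * b2))
    area = height * sigma * math.sqrt(2.0 * math.pi)

    cov = result.cov_beta
    grad_height = height * np.array([1.0, xc, xc * xc])
    var_height = float(grad_height @ cov @ grad_height)
    d_height = math.sqrt(max(var_height, 0.0))
    # d sigma / d b2 = 1 / (4 sigma b2^2)
    d_sigma = abs(1.0 / (4.0 * sigma * b2 * b2)) * math.sqrt(max(cov[2, 2], 0.0))
    d_area = math.sqrt(2.0 * math.pi) * math.hypot(sigma * d_height, height * d_sigma)

    x0 = xc + result.x_shift
    values = (x0, sigma, height, area, d_height, d_sigma, d_area)
    if not all(math.isfinite(v) for v in values):
        return RejectRecord(result.profile, "nonfinite")
    return GaussianPeak(x0, sigma, height, area, d_height, d_sigma, d_area)
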