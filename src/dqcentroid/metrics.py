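"""Derived peak quantities and validation analyses.

Covers the Gaussian FWHM/sigma relation, mass resolution R = m/dm, signed
ppm mass accuracy, the resolution-vs-m/z power law R = a * m^b fitted by
non-linear regression, and grouping of centroids across consecutive scans
(EIC-style) to measure m/z precision.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize

from .ms_io import CentroidRecord

#: FWHM of a unit-sigma Gaussian.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_from_sigma(sigma: float) -> float:
    """Full width at half maximum of a Gaussian with standard deviation sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return FWHM_FACTOR * sigma


def sigma_from_fwhm(fwhm: float) -> float:
    """Inverse of :func:`fwhm_from_sigma`."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    return fwhm / FWHM_FACTOR


def mass_resolution(mz: float, fwhm: float) -> float:
    """Mass resolution R = m / dm with dm the FWHM at mass m."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    return mz / fwhm


def mass_accuracy_ppm(measured: float, exact: float) -> float:
    """Signed relative mass error in parts per million."""
    if exact <= 0:
        raise ValueError("exact mass must be positive")
    return (measured - exact) / exact * 1e6


@dataclass
class ResolutionFit:
    """Power law R = a * m^b fitted to (m/z, resolution) points."""

    a: float
    b: float
    se_a: float
    se_b: float
    n: int

    def __call__(self, mz):
        return self.a * np.asarray(mz, dtype=float) ** self.b


def fit_resolution_power_law(
    points: Sequence[tuple[float, float]]
) -> ResolutionFit:
    """Fit R = a * m^b by iterative non-linear least squares.

    Initial values come from the linear fit in log-log space, which is exact
    for noiseless power-law data. Standard errors are the square roots of the
    diagonal of the parameter covariance.
    """
    data = np.asarray(points, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 3:
        raise ValueError("need at least 3 (mz, resolution) pairs")
    mz, resolution = data[:, 0], data[:, 1]
    if np.any(mz <= 0) or np.any(resolution <= 0):
        raise ValueError("m/z and resolution values must be positive")
    if np.ptp(mz) == 0:
        raise ValueError("degenerate fit: all m/z values equal")
    slope, intercept = np.polyfit(np.log(mz), np.log(resolution), 1)
    popt, pcov = scipy.optimize.curve_fit(
        lambda m, a, b: a * m ** b,
        mz,
        resolution,
        p0=(math.exp(intercept), slope),
        maxfev=10000,
    )
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return ResolutionFit(
        a=float(popt[0]), b=float(popt[1]), se_a=float(se[0]), se_b=float(se[1]),
        n=int(mz.size),
    )


@dataclass
class CentroidGroup:
    """Centroids of (presumably) one ion species chained across scans.

    ``rsd_ppm`` is the relative standard deviation of the member m/z values
    in ppm, the per-species measure of m/z precision.
    """

    members: list[CentroidRecord]
    mean_mz: float
    rsd_ppm: float


class _OpenGroup:
    __slots__ = ("members", "scans", "mz_sum", "last_scan")

    def __init__(self) -> None:
        self.members: list[CentroidRecord] = []
        self.mz_sum = 0.0
        self.last_scan = -1

    @property
    def mean_mz(self) -> float:
        return self.mz_sum / len(self.members)

    def add(self, record: CentroidRecord, scan_index: int) -> None:
        self.members.append(record)
        self.mz_sum += record.mz_centroid
        self.last_scan = scan_index


def _scan_numbers(records: Sequence[CentroidRecord]) -> dict[str, int]:
    """Scan number per scan_id: the id's trailing integer when every id has
    one (so missing scans count as gaps), else order of first appearance."""
    ids: list[str] = []
    for record in records:
        if record.scan_id not in ids:
            ids.append(record.scan_id)
    numbers = [re.search(r"(\d+)\s*$", scan_id) for scan_id in ids]
    if ids and all(numbers) and len({m.group(1) for m in numbers}) == len(ids):
        return {scan_id: int(m.group(1)) for scan_id, m in zip(ids, numbers)}
    return {scan_id: index for index, scan_id in enumerate(ids)}


def group_centroids(
    records: Sequence[CentroidRecord],
    ppm_tol: float = 3.0,
    max_gap: int = 2,
    min_size: int = 10,
) -> list[CentroidGroup]:
    """Chain centroids of consecutive scans into per-ion groups.

    Scan order is the order of first appearance of each ``scan_id`` in
    ``records``. A centroid joins the open group whose running mean m/z is
    within ``ppm_tol`` (closest wins) provided no more than ``max_gap``
    scans are missing since the group's last member; groups smaller than
    ``min_size`` are discarded. Default tolerance of 3 ppm matches a typical
    Orbitrap mass-extraction window; the defaults require groups of at least
    10 centroids with fewer than three consecutive missing scans.
    """
    scan_index = _scan_numbers(records)
    ordered = sorted(
        records, key=lambda r: (scan_index[r.scan_id], r.mz_centroid)
    )
    open_groups: list[_OpenGroup] = []
    closed: list[_OpenGroup] = []
    for record in ordered:
        scan = scan_index[record.scan_id]
        still_open: list[_OpenGroup] = []
        for group in open_groups:
            if scan - group.last_scan - 1 > max_gap and group.last_scan != scan:
                closed.append(group)
            else:
                still_open.append(group)
        open_groups = still_open
        best: _OpenGroup | None = None
        best_ppm = ppm_tol
        for group in open_groups:
            if group.last_scan == scan:
                continue  # one member per scan per group
            ppm = abs(record.mz_centroid - group.mean_mz) / group.mean_mz * 1e6
            if ppm <= best_ppm:
                best, best_ppm = group, ppm
        if best is None:
            best = _OpenGroup()
            open_groups.append(best)
        best.add(record, scan)
    closed.extend(open_groups)
    groups: list[CentroidGroup] = []
    for group in closed:
        if len(group.members) < min_size:
            continue
        mz_values = np.array([m.mz_centroid for m in group.members])
        mean_mz = float(mz_values.mean())
        rsd_ppm = float(mz_values.std(ddof=1) / mean_mz * 1e6)
        groups.append(CentroidGroup(group.members, mean_mz, rsd_ppm))
    groups.sort(key=lambda g: (scan_index[g.members[0].scan_id], g.mean_mz))
    return groups
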