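"""Splitting profile spectra into isolated peak profiles.

Orbitrap profile spectra surround each resolved peak with true zero
intensities, so zeros act as predefined peak boundaries. Overlapping peaks
share a valley point (a strict local intensity minimum inside a nonzero run);
the run is split there and the valley point is assigned to *both* adjacent
profiles, so no deconvolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ms_io import Spectrum

#: Break a nonzero run where the m/z step exceeds this multiple of the run's
#: median grid step (vendors may omit zero points instead of storing them).
#: Chosen to be inert on fully zero-padded data.
DEFAULT_GAP_FACTOR = 4.0


@dataclass(eq=False)
class PeakProfile:
    """A contiguous, possibly valley-split run of nonzero points.

    ``start``/``end`` are 0-based inclusive indices into the parent spectrum.
    ``split_left``/``split_right`` mark edges that are valley points shared
    with the neighbouring profile.
    """

    spectrum: Spectrum
    start: int
    end: int
    split_left: bool = False
    split_right: bool = False

    @property
    def mz(self) -> np.ndarray:
        return self.spectrum.mz[self.start : self.end + 1]

    @property
    def intensity(self) -> np.ndarray:
        return self.spectrum.intensity[self.start : self.end + 1]

    @property
    def n_points(self) -> int:
        return self.end - self.start + 1

    def __len__(self) -> int:
        return self.n_points


def _nonzero_runs(intensity: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] runs of consecutive nonzero intensities."""
    nonzero = intensity != 0
    if not nonzero.any():
        return []
    boundaries = np.flatnonzero(np.diff(nonzero.astype(np.int8)))
    starts = [int(i) + 1 for i in boundaries[::1] if not nonzero[i]]
    ends = [int(i) for i in boundaries if nonzero[i]]
    if nonzero[0]:
        starts.insert(0, 0)
    if nonzero[-1]:
        ends.append(intensity.size - 1)
    return list(zip(starts, ends))


def _split_on_gaps(
    mz: np.ndarray, start: int, end: int, gap_factor: float
) -> list[tuple[int, int]]:
    """Break [start, end] where the grid step jumps by > gap_factor x median."""
    if end - start < 1 or not np.isfinite(gap_factor):
        return [(start, end)]
    steps = np.diff(mz[start : end + 1])
    median_step = float(np.median(steps))
    if median_step <= 0:
        return [(start, end)]
    pieces: list[tuple[int, int]] = []
    piece_start = start
    for offset, step in enumerate(steps):
        if step > gap_factor * median_step:
            pieces.append((piece_start, start + offset))
            piece_start = start + offset + 1
    pieces.append((piece_start, end))
    return pieces


def _valley_indices(intensity: np.ndarray, start: int, end: int) -> list[int]:
    """Strict local minima in (start, end); a flat minimal plateau between two
    higher neighbours counts as one valley at its leftmost index."""
    valleys: list[int] = []
    i = start + 1
    while i < end:
        if intensity[i] < intensity[i - 1]:
            j = i
            while j < end and intensity[j + 1] == intensity[i]:
                j += 1
            if j < end and intensity[j + 1] > intensity[i]:
                valleys.append(i)
            i = j + 1
        else:
            i += 1
    return valleys


def isolate_profiles(
    spectrum: Spectrum, gap_factor: float = DEFAULT_GAP_FACTOR
) -> list[PeakProfile]:
    """Split a spectrum into peak profiles, left to right.

    Profiles are maximal nonzero runs, additionally broken at large m/z grid
    gaps (implicit zeros) and at valley points. A valley point belongs to both
    neighbouring profiles and carries ``split_right``/``split_left`` flags.
    The union of the returned profiles covers every nonzero point; an
    all-zero or empty spectrum yields an empty list.
    """
    profiles: list[PeakProfile] = []
    for run_start, run_end in _nonzero_runs(spectrum.intensity):
        for start, end in _split_on_gaps(spectrum.mz, run_start, run_end, gap_factor):
            valleys = _valley_indices(spectrum.intensity, start, end)
            edges = [start] + valleys + [end]
            if not valleys:
                profiles.append(PeakProfile(spectrum, start, end))
                continue
            for k in range(len(edges) - 1):
                profiles.append(
                    PeakProfile(
                        spectrum,
                        edges[k],
                        edges[k + 1],
                        split_left=k > 0,
                        split_right=k < len(edges) - 2,
                    )
                )
    return profiles
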