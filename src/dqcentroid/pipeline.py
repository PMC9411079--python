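"""End-to-end wiring: read -> isolate -> fit -> score -> write.

The pipeline never drops a profile silently: every detected profile either
becomes a centroid row or a reason-coded entry in the rejects table, so
``profiles_found == centroids + rejects`` always holds (an optional DQS
floor removes rows from the *output* but the removals are counted).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import metrics, ms_io, regression, scoring
from .isolation import DEFAULT_GAP_FACTOR, isolate_profiles
from .ms_io import CentroidRecord, Spectrum
from .regression import RejectRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    weight_power: float = regression.DEFAULT_WEIGHT_POWER
    min_points: int = regression.MIN_POINTS
    ms_level: Optional[int] = None       # None = all levels
    dqs_min: float = 0.0                 # 0 keeps everything
    gap_factor: float = DEFAULT_GAP_FACTOR
    fit_method: str = "per_profile"
    allow_few_points: bool = False       # explicit override to go below 4

    def __post_init__(self) -> None:
        if self.min_points < regression.MIN_POINTS and not self.allow_few_points:
            raise ValueError(
                f"min_points < {regression.MIN_POINTS} loses the residual degree "
                "of freedom; set allow_few_points to override"
            )


@dataclass
class PipelineSummary:
    spectra_read: int = 0
    profiles_found: int = 0
    centroids: int = 0
    centroids_written: int = 0
    dqs_filtered: int = 0
    rejects: dict = field(
        default_factory=lambda: {r: 0 for r in regression.REJECT_REASONS}
    )

    @property
    def rejects_total(self) -> int:
        return sum(self.rejects.values())


def centroid_spectrum(
    spectrum: Spectrum,
    *,
    weight_power: float = regression.DEFAULT_WEIGHT_POWER,
    min_points: int = regression.MIN_POINTS,
    gap_factor: float = DEFAULT_GAP_FACTOR,
    fit_method: str = "per_profile",
) -> tuple[list[CentroidRecord], list[RejectRecord]]:
    """Centroid one spectrum; returns (accepted records, reason-coded rejects)."""
    profiles = isolate_profiles(spectrum, gap_factor=gap_factor)
    records: list[CentroidRecord] = []
    rejects: list[RejectRecord] = []
    for result in regression.fit_profiles(
        profiles, weight_power=weight_power, min_points=min_points, method=fit_method
    ):
        if isinstance(result, RejectRecord):
            rejects.append(result)
            continue
        peak = regression.backtransform(result)
        if isinstance(peak, RejectRecord):
            rejects.append(peak)
            continue
        scored = scoring.score_peak(peak)
        profile = result.profile
        records.append(
            CentroidRecord(
                scan_id=spectrum.scan_id,
                retention_time=spectrum.retention_time,
                ms_level=spectrum.ms_level,
                mz_centroid=peak.x0,
                height=peak.height,
                area=peak.area,
                sigma=peak.sigma,
                fwhm=metrics.fwhm_from_sigma(peak.sigma),
                dqs=scored.dqs,
                category=scored.category,
                n_points=profile.n_points,
                nrmse=result.nrmse,
                apex_inside=bool(profile.mz[0] <= peak.x0 <= profile.mz[-1]),
            )
        )
    return records, rejects


def centroid_spectra(
    spectra: Sequence[Spectrum], config: Optional[PipelineConfig] = None
) -> tuple[list[CentroidRecord], list[RejectRecord], PipelineSummary]:
    """Centroid a sequence of spectra under one configuration."""
    config = config or PipelineConfig()
    summary = PipelineSummary()
    all_records: list[CentroidRecord] = []
    all_rejects: list[RejectRecord] = []
    for spectrum in spectra:
        summary.spectra_read += 1
        records, rejects = centroid_spectrum(
            spectrum,
            weight_power=config.weight_power,
            min_points=config.min_points,
            gap_factor=config.gap_factor,
            fit_method=config.fit_method,
        )
        summary.profiles_found += len(records) + len(rejects)
        summary.centroids += len(records)
        for reject in rejects:
            summary.rejects[reject.reason] += 1
        all_records.extend(records)
        all_rejects.extend(rejects)
    if config.dqs_min > 0:
        kept = [r for r in all_records if r.dqs >= config.dqs_min]
        summary.dqs_filtered = len(all_records) - len(kept)
        all_records = kept
    summary.centroids_written = len(all_records)
    return all_records, all_rejects, summary


def write_rejects_table(rejects: Sequence[RejectRecord], path) -> None:
    """CSV ledger of rejected profiles: scan, index range, point count, reason."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scan_id", "start_index", "end_index", "n_points", "reason"])
        for reject in rejects:
            profile = reject.profile
            writer.writerow(
                [
                    profile.spectrum.scan_id,
                    profile.start,
                    profile.end,
                    profile.n_points,
                    reject.reason,
                ]
            )


def run_pipeline(
    input_path,
    output_path,
    config: Optional[PipelineConfig] = None,
    rejects_path=None,
) -> PipelineSummary:
    """Process one mzML/mzXML file into a centroid CSV (plus optional rejects CSV)."""
    config = config or PipelineConfig()
    spectra = ms_io.read_profile_spectra(input_path, ms_level_filter=config.ms_level)
    records, rejects, summary = centroid_spectra(spectra, config)
    ms_io.write_centroid_table(records, output_path)
    if rejects_path is not None:
        write_rejects_table(rejects, rejects_path)
    logger.info(
        "spectra=%d profiles=%d centroids=%d written=%d dqs_filtered=%d rejects=%s",
        summary.spectra_read,
        summary.profiles_found,
        summary.centroids,
        summary.centroids_written,
        summary.dqs_filtered,
        summary.rejects,
    )
    return summary
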