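"""Reading profile-mode mass spectra and writing annotated centroid tables.

Input formats are mzML 1.1 and mzXML 3.x (dialect detected from the XML root
element, not the file extension). Output is a fixed-schema CSV with one row
per accepted peak profile. Zero-intensity points are *retained* on reading:
they are the peak boundaries consumed by :mod:`dqcentroid.isolation`.
"""

from __future__ import annotations

import base64
import csv
import io
import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
from lxml import etree
from pyteomics import mzxml as _mzxml_reader

logger = logging.getLogger(__name__)

#: Column order of the centroid CSV. Fixed; never reordered.
CENTROID_COLUMNS = (
    "scan_id",
    "retention_time",
    "ms_level",
    "mz_centroid",
    "height",
    "area",
    "sigma",
    "fwhm",
    "dqs",
    "category",
    "n_points",
    "nrmse",
    "apex_inside",
)


class FormatError(ValueError):
    """Raised when an input spectrum violates the format contract."""


@dataclass(eq=False)
class Spectrum:
    """One profile-mode scan: parallel m/z and intensity arrays plus metadata.

    Invariants: ``len(mz) == len(intensity)``, ``mz`` strictly increasing,
    all intensities nonnegative. ``retention_time`` is in seconds and may be
    ``None`` for direct-infusion data.
    """

    scan_id: str
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    retention_time: Optional[float] = None
    polarity: str = "unknown"  # {"positive", "negative", "unknown"}

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise FormatError(
                f"scan {self.scan_id!r}: m/z and intensity arrays differ in shape"
            )
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise FormatError(f"scan {self.scan_id!r}: m/z values not strictly increasing")
        if self.mz.size and np.any(self.intensity < 0):
            raise FormatError(f"scan {self.scan_id!r}: negative intensity value")
        if self.ms_level < 1:
            raise FormatError(f"scan {self.scan_id!r}: ms_level must be >= 1")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class CentroidRecord:
    """One accepted peak profile reduced to its fitted Gaussian parameters.

    ``fwhm`` and ``area`` are redundant with ``sigma``/``height`` through the
    Gaussian relations (``fwhm = 2 sqrt(2 ln 2) sigma``,
    ``area = height * sigma * sqrt(2 pi)``) and are stored for convenience.
    ``apex_inside`` flags whether the fitted centroid lies within the m/z span
    of the profile's data points; it is reported, never used as a filter.
    """

    scan_id: str
    retention_time: Optional[float]
    ms_level: int
    mz_centroid: float
    height: float
    area: float
    sigma: float
    fwhm: float
    dqs: float
    category: str
    n_points: int
    nrmse: float
    apex_inside: bool


def _detect_dialect(path: Path) -> str:
    """Return ``"mzml"`` or ``"mzxml"`` from the document root element."""
    with open(path, "rb") as fh:
        head = fh.read(8192)
    for _event, element in etree.iterparse(
        io.BytesIO(head), events=("start",), recover=True
    ):
        tag = etree.QName(element).localname
        if tag in ("mzML", "indexedmzML"):
            return "mzml"
        if tag == "mzXML":
            return "mzxml"
        break
    raise FormatError(f"{path}: not a recognized mzML or mzXML document")


def _rt_seconds(value) -> Optional[float]:
    """Normalize a pyteomics scan-start-time to seconds."""
    if value is None:
        return None
    unit = getattr(value, "unit_info", None)
    seconds = float(value)
    if unit in ("minute", "minutes", "min"):
        seconds *= 60.0
    return seconds


def _decode_binary_array(array_element) -> tuple[Optional[str], np.ndarray]:
    """Decode one mzML <binaryDataArray> into (kind, values).

    ``kind`` is ``"mz"``, ``"intensity"`` or ``None`` for other array types.
    Handles 32/64-bit floats and zlib compression per the cvParams.
    """
    dtype = "<f8"
    compressed = False
    kind: Optional[str] = None
    payload = b""
    for child in array_element:
        tag = etree.QName(child).localname
        if tag == "cvParam":
            accession = child.get("accession", "")
            if accession == "MS:1000521":
                dtype = "<f4"
            elif accession == "MS:1000523":
                dtype = "<f8"
            elif accession == "MS:1000574":
                compressed = True
            elif accession == "MS:1000514":
                kind = "mz"
            elif accession == "MS:1000515":
                kind = "intensity"
        elif tag == "binary" and child.text:
            payload = base64.b64decode(child.text)
    if compressed:
        import zlib

        payload = zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(float)


_SCAN_TIME_UNITS = {"UO:0000031": 60.0, "UO:0000010": 1.0}  # minute, second


def _parse_mzml_spectrum(element) -> Spectrum:
    ms_level = 1
    polarity = "unknown"
    retention_time: Optional[float] = None
    mz = intensity = None
    for cv in element.iter(f"{{{_MZML_NS}}}cvParam", "cvParam"):
        accession = cv.get("accession", "")
        if accession == "MS:1000511":
            ms_level = int(cv.get("value", "1"))
        elif accession == "MS:1000130":
            polarity = "positive"
        elif accession == "MS:1000129":
            polarity = "negative"
        elif accession == "MS:1000016":
            scale = _SCAN_TIME_UNITS.get(cv.get("unitAccession", ""), 60.0)
            retention_time = float(cv.get("value")) * scale
    for array_element in element.iter(
        f"{{{_MZML_NS}}}binaryDataArray", "binaryDataArray"
    ):
        kind, values = _decode_binary_array(array_element)
        if kind == "mz":
            mz = values
        elif kind == "intensity":
            intensity = values
    if mz is None or intensity is None:
        raise FormatError(
            f"spectrum {element.get('id')!r}: missing m/z or intensity array"
        )
    return Spectrum(
        scan_id=str(element.get("id", element.get("index", ""))),
        mz=mz,
        intensity=intensity,
        ms_level=ms_level,
        retention_time=retention_time,
        polarity=polarity,
    )


def _iter_mzml(path: Path) -> Iterator[Spectrum]:
    # stream with lxml; namespace-tolerant (plain or default-namespace tags)
    for _event, element in etree.iterparse(
        str(path), events=("end",), tag=(f"{{{_MZML_NS}}}spectrum", "spectrum")
    ):
        yield _parse_mzml_spectrum(element)
        element.clear(keep_tail=True)


def _iter_mzxml(path: Path) -> Iterator[Spectrum]:
    with _mzxml_reader.read(str(path)) as reader:
        for entry in reader:
            pol = {"+": "positive", "-": "negative"}.get(entry.get("polarity"), "unknown")
            yield Spectrum(
                scan_id=str(entry.get("num", "")),
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                ms_level=int(entry.get("msLevel", 1)),
                retention_time=_rt_seconds(entry.get("retentionTime")),
                polarity=pol,
            )


def read_profile_spectra(
    path, ms_level_filter: Optional[int] = None
) -> list[Spectrum]:
    """Read all profile spectra from an mzML or mzXML file, in file order.

    Parameters
    ----------
    path
        Path to an mzML 1.1 or mzXML 3.x file; the dialect is auto-detected
        from the root element.
    ms_level_filter
        If given, only spectra with this MS level are returned.

    Returns
    -------
    list of :class:`Spectrum`. A spectrum containing *no* zero-intensity
    point at all is probably already centroided; it triggers a warning but
    is still returned unchanged.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such spectrum file: {path}")
    dialect = _detect_dialect(path)
    iterator = _iter_mzml(path) if dialect == "mzml" else _iter_mzxml(path)
    spectra: list[Spectrum] = []
    for spectrum in iterator:
        if ms_level_filter is not None and spectrum.ms_level != ms_level_filter:
            continue
        if len(spectrum) and not np.any(spectrum.intensity == 0):
            message = (
                f"scan {spectrum.scan_id!r} contains no zero intensities; "
                "it looks already centroided"
            )
            logger.warning(message)
            warnings.warn(message, UserWarning, stacklevel=2)
        spectra.append(spectrum)
    return spectra


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return format(value, ".12g")  # >= 10 significant digits
    return str(value)


def write_centroid_table(records: Sequence[CentroidRecord], path) -> None:
    """Write records as RFC-4180 CSV with the fixed 13-column schema.

    Rows are sorted by (scan order of first appearance, mz_centroid); floats
    carry 12 significant digits so a write/read round trip is lossless to
    well past 10 digits. Missing retention time becomes an empty field.
    """
    scan_order: dict[str, int] = {}
    for record in records:
        scan_order.setdefault(record.scan_id, len(scan_order))
    ordered = sorted(records, key=lambda r: (scan_order[r.scan_id], r.mz_centroid))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CENTROID_COLUMNS)
        for record in ordered:
            writer.writerow([_fmt(getattr(record, col)) for col in CENTROID_COLUMNS])


def read_centroid_table(path) -> list[CentroidRecord]:
    """Parse a centroid CSV back into records (inverse of the writer)."""
    records: list[CentroidRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                CentroidRecord(
                    scan_id=row["scan_id"],
                    retention_time=(
                        float(row["retention_time"]) if row["retention_time"] else None
                    ),
                    ms_level=int(row["ms_level"]),
                    mz_centroid=float(row["mz_centroid"]),
                    height=float(row["height"]),
                    area=float(row["area"]),
                    sigma=float(row["sigma"]),
                    fwhm=float(row["fwhm"]),
                    dqs=float(row["dqs"]),
                    category=row["category"],
                    n_points=int(row["n_points"]),
                    nrmse=float(row["nrmse"]),
                    apex_inside=row["apex_inside"] == "True",
                )
            )
    return records


# ---------------------------------------------------------------------------
# Minimal mzML writer (profile mode, uncompressed 64-bit arrays).
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"
_POLARITY_CV = {
    "positive": ("MS:1000130", "positive scan"),
    "negative": ("MS:1000129", "negative scan"),
}


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    etree.SubElement(
        parent,
        f"{{{_MZML_NS}}}cvParam",
        cvRef="MS" if accession.startswith("MS") else "UO",
        accession=accession,
        name=name,
        value=value,
        **attrs,
    )


def _binary_array(parent, values: np.ndarray, kind: str) -> None:
    payload = base64.b64encode(
        struct.pack(f"<{values.size}d", *np.asarray(values, dtype=float))
    ).decode("ascii")
    array = etree.SubElement(
        parent, f"{{{_MZML_NS}}}binaryDataArray", encodedLength=str(len(payload))
    )
    _cv(array, "MS:1000523", "64-bit float")
    _cv(array, "MS:1000576", "no compression")
    if kind == "mz":
        _cv(array, "MS:1000514", "m/z array", unitCvRef="MS",
            unitAccession="MS:1000040", unitName="m/z")
    else:
        _cv(array, "MS:1000515", "intensity array", unitCvRef="MS",
            unitAccession="MS:1000131", unitName="number of detector counts")
    etree.SubElement(array, f"{{{_MZML_NS}}}binary").text = payload


def write_mzml(spectra: Sequence[Spectrum], path) -> None:
    """Serialize spectra to a minimal, standard-conforming profile mzML file.

    Emits exactly the elements a profile-spectrum consumer needs (spectrum
    list, 64-bit uncompressed m/z and intensity arrays, MS level, polarity
    and scan start time); the output reads back with pyteomics and with
    :func:`read_profile_spectra`.
    """
    root = etree.Element(
        f"{{{_MZML_NS}}}mzML", nsmap={None: _MZML_NS}, version="1.1.0"
    )
    cv_list = etree.SubElement(root, f"{{{_MZML_NS}}}cvList", count="2")
    etree.SubElement(
        cv_list, f"{{{_MZML_NS}}}cv", id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cv_list, f"{{{_MZML_NS}}}cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    run = etree.SubElement(root, f"{{{_MZML_NS}}}run", id="run1")
    spectrum_list = etree.SubElement(
        run, f"{{{_MZML_NS}}}spectrumList", count=str(len(spectra))
    )
    for index, spectrum in enumerate(spectra):
        element = etree.SubElement(
            spectrum_list,
            f"{{{_MZML_NS}}}spectrum",
            index=str(index),
            id=spectrum.scan_id,
            defaultArrayLength=str(len(spectrum)),
        )
        _cv(element, "MS:1000511", "ms level", str(spectrum.ms_level))
        _cv(element, "MS:1000128", "profile spectrum")
        if spectrum.polarity in _POLARITY_CV:
            _cv(element, *_POLARITY_CV[spectrum.polarity])
        scan_list = etree.SubElement(
            element, f"{{{_MZML_NS}}}scanList", count="1"
        )
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, f"{{{_MZML_NS}}}scan")
        if spectrum.retention_time is not None:
            _cv(scan, "MS:1000016", "scan start time",
                format(spectrum.retention_time, ".12g"),
                unitCvRef="UO", unitAccession="UO:0000010", unitName="second")
        arrays = etree.SubElement(
            element, f"{{{_MZML_NS}}}binaryDataArrayList", count="2"
        )
        _binary_array(arrays, spectrum.mz, "mz")
        _binary_array(arrays, spectrum.intensity, "intensity")
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )
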