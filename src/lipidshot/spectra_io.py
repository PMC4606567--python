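"""Segmented direct-infusion acquisitions: data model, TSV and mzML I/O,
scan averaging, and lock-mass recalibration.

An acquisition is a fixed sequence of segments executed while the sample is
infused: a narrow positive MS1 window dedicated to the ammoniated sterol ion,
wide positive and negative MS1 windows with lock-mass correction, and two
data-independent MS/MS sweeps driven by inclusion lists on a 1 Da grid with
1.0 Da isolation width.  The default template reproduces that scheme exactly
(windows, lock masses, inclusion lists); see :func:`default_method_template`.

The canonical on-disk format is a plain TSV peak list (one peak per row,
6-decimal m/z) chosen for bit-exact fixtures; mzML is supported through a
read adapter (and a minimal writer) built on pyteomics.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Peak",
    "Ms1Spectrum",
    "MsmsScan",
    "SegmentDef",
    "MethodTemplate",
    "AcquisitionRun",
    "default_method_template",
    "read_run",
    "write_run",
    "read_run_mzml",
    "write_run_mzml",
    "average_scans",
    "lockmass_recalibrate",
]

POSITIVE = "positive"
NEGATIVE = "negative"

LOCK_APPLIED = "applied"
LOCK_UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity}")


@dataclass
class Ms1Spectrum:
    polarity: str
    window: Tuple[float, float]
    peaks: List[Peak]
    lockmass_status: str = LOCK_UNAVAILABLE
    scan_index: int = 0
    segment: str = ""

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


@dataclass
class MsmsScan:
    polarity: str
    precursor_window_center: float
    isolation_width: float = 1.0
    normalized_collision_energy: float = 0.0
    peaks: List[Peak] = field(default_factory=list)
    segment: str = ""
    scan_index: int = 0

    def __post_init__(self):
        if self.isolation_width <= 0:
            raise ValueError("isolation width must be positive")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def contains_precursor(self, mz: float) -> bool:
        """Half-open isolation interval [center - w/2, center + w/2)."""
        half = self.isolation_width / 2.0
        return (
            self.precursor_window_center - half
            <= mz
            < self.precursor_window_center + half
        )


@dataclass(frozen=True)
class SegmentDef:
    """One acquisition segment of the method template."""

    name: str
    polarity: str
    scan_type: str  # "MS1" | "MSMS-DIA"
    window: Optional[Tuple[float, float]] = None  # MS1 scan window
    inclusion: Optional[Tuple[float, float, float]] = None  # (start, stop, step)
    lock_mz: Optional[float] = None
    duration_s: float = 0.0
    resolution: float = 0.0
    nce: float = 0.0
    metadata: Tuple[Tuple[str, str], ...] = ()  # opaque instrument settings

    def inclusion_centers(self) -> np.ndarray:
        if self.inclusion is None:
            return np.array([])
        start, stop, step = self.inclusion
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)


@dataclass(frozen=True)
class MethodTemplate:
    segments: Tuple[SegmentDef, ...]

    def __getitem__(self, name: str) -> SegmentDef:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def ms1_segments(self) -> List[SegmentDef]:
        return [s for s in self.segments if s.scan_type == "MS1"]

    def dia_segment(self, polarity: str) -> Optional[SegmentDef]:
        for s in self.segments:
            if s.scan_type == "MSMS-DIA" and s.polarity == polarity:
                return s
        return None


def default_method_template() -> MethodTemplate:
    """The default 6-segment method: sterol window, wide MS1 windows with
    lock masses in both polarities, and the two DIA inclusion-list sweeps."""
    agc = lambda v, it: (("AGC", v), ("IT_ms", it))
    return MethodTemplate(
        (
            SegmentDef("pos_sterol", POSITIVE, "MS1", window=(402.0, 412.0),
                       duration_s=12, resolution=140000, metadata=agc("5e5", "200")),
            SegmentDef("pos_wide", POSITIVE, "MS1", window=(550.0, 1000.0),
                       lock_mz=680.48022, duration_s=18, resolution=140000,
                       metadata=agc("1e6", "50")),
            SegmentDef("pos_dia", POSITIVE, "MSMS-DIA",
                       inclusion=(500.5, 999.75, 1.0), duration_s=105,
                       resolution=17500, nce=20, metadata=agc("1e5", "64")),
            SegmentDef("neg_lyso", NEGATIVE, "MS1", window=(400.0, 650.0),
                       lock_mz=529.46262, duration_s=15, resolution=140000,
                       metadata=agc("1e6", "50")),
            SegmentDef("neg_wide", NEGATIVE, "MS1", window=(520.0, 940.0),
                       lock_mz=529.46262, duration_s=15, resolution=140000,
                       metadata=agc("1e6", "50")),
            SegmentDef("neg_dia", NEGATIVE, "MSMS-DIA",
                       inclusion=(590.5, 939.5, 1.0), duration_s=90,
                       resolution=17500, nce=35, metadata=agc("1e5", "64")),
        )
    )


@dataclass
class AcquisitionRun:
    method: MethodTemplate
    ms1: Dict[str, List[Ms1Spectrum]] = field(default_factory=dict)
    msms: Dict[str, List[MsmsScan]] = field(default_factory=dict)
    sample_id: str = "sample"
    plasma_ul: float = 1.0
    anticoagulant: str = "edta"

    def add_ms1(self, spectrum: Ms1Spectrum) -> None:
        self.method[spectrum.segment]  # KeyError if unknown
        self.ms1.setdefault(spectrum.segment, []).append(spectrum)

    def add_msms(self, scan: MsmsScan) -> None:
        self.method[scan.segment]
        self.msms.setdefault(scan.segment, []).append(scan)

    def all_msms(self, polarity: Optional[str] = None) -> List[MsmsScan]:
        out: List[MsmsScan] = []
        for scans in self.msms.values():
            for s in scans:
                if polarity is None or s.polarity == polarity:
                    out.append(s)
        return out


# ---------------------------------------------------------------------------
# TSV dialect

_TSV_HEADER = "segment\tscan\tpolarity\twindow_lo\twindow_hi\tprecursor_mz\tmz\tintensity"


def write_run(run: AcquisitionRun, path) -> None:
    """Write the TSV peak-list dialect: UTF-8, one peak per row, m/z with six
    decimals, intensity with one."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample={run.sample_id} plasma_ul={run.plasma_ul:g} "
                 f"anticoagulant={run.anticoagulant}\n")
        fh.write(_TSV_HEADER + "\n")
        for seg in run.method.segments:
            for sp in run.ms1.get(seg.name, []):
                lo, hi = sp.window
                for p in sp.peaks:
                    fh.write(
                        f"{seg.name}\t{sp.scan_index}\t{_pol_code(sp.polarity)}"
                        f"\t{lo:.6f}\t{hi:.6f}\t\t{p.mz:.6f}\t{p.intensity:.1f}\n"
                    )
            for sc in self_sorted(run.msms.get(seg.name, [])):
                half = sc.isolation_width / 2
                lo, hi = sc.precursor_window_center - half, sc.precursor_window_center + half
                for p in sc.peaks:
                    fh.write(
                        f"{seg.name}\t{sc.scan_index}\t{_pol_code(sc.polarity)}"
                        f"\t{lo:.6f}\t{hi:.6f}\t{sc.precursor_window_center:.6f}"
                        f"\t{p.mz:.6f}\t{p.intensity:.1f}\n"
                    )


def self_sorted(scans: List[MsmsScan]) -> List[MsmsScan]:
    return sorted(scans, key=lambda s: (s.precursor_window_center, s.scan_index))


def _pol_code(polarity: str) -> str:
    return "pos" if polarity == POSITIVE else "neg"


def _pol_from_code(code: str, line_no: int) -> str:
    if code == "pos":
        return POSITIVE
    if code == "neg":
        return NEGATIVE
    raise ValueError(f"line {line_no}: unknown polarity code {code!r}")


def read_run(path, method: Optional[MethodTemplate] = None) -> AcquisitionRun:
    """Read the TSV dialect back into an :class:`AcquisitionRun`.

    Round-trips :func:`write_run` losslessly up to the printed float
    precision.  Raises ``ValueError`` with the offending line number on
    negative intensities or malformed rows; unsorted peak rows are accepted
    (spectra sort on construction) with a warning.
    """
    if method is None:
        method = default_method_template()
    run = AcquisitionRun(method)
    # key -> (segment, scan, polarity, window, precursor) ; value -> peaks
    groups: Dict[tuple, List[Peak]] = {}
    order: List[tuple] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("# sample="):
                    for tok in line[2:].split():
                        k, _, v = tok.partition("=")
                        if k == "sample":
                            run.sample_id = v
                        elif k == "plasma_ul":
                            run.plasma_ul = float(v)
                        elif k == "anticoagulant":
                            run.anticoagulant = v
                continue
            if line == _TSV_HEADER:
                continue
            cols = line.split("\t")
            if len(cols) != 8:
                raise ValueError(f"line {line_no}: expected 8 columns, got {len(cols)}")
            seg, scan, pol, lo, hi, prec, mz, inten = cols
            intensity = float(inten)
            if intensity < 0:
                raise ValueError(f"line {line_no}: negative intensity {inten}")
            key = (seg, int(scan), _pol_from_code(pol, line_no), float(lo),
                   float(hi), float(prec) if prec else None)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(Peak(float(mz), intensity))
    for key in order:
        seg, scan, pol, lo, hi, prec = key
        peaks = groups[key]
        if any(peaks[i].mz > peaks[i + 1].mz for i in range(len(peaks) - 1)):
            warnings.warn(f"segment {seg} scan {scan}: peaks not sorted; sorting")
        if prec is None:
            run.add_ms1(Ms1Spectrum(pol, (lo, hi), peaks, scan_index=scan,
                                    segment=seg))
        else:
            run.add_msms(MsmsScan(pol, prec, isolation_width=hi - lo,
                                  peaks=peaks, segment=seg, scan_index=scan))
    return run


# ---------------------------------------------------------------------------
# mzML adapter (read via pyteomics; minimal writer for round-trips)

def _assign_segment(method: MethodTemplate, polarity: str,
                    window: Optional[Tuple[float, float]],
                    precursor: Optional[float]) -> str:
    """Map an mzML scan onto a method segment by polarity, scan window and
    precursor presence."""
    if precursor is not None:
        seg = method.dia_segment(polarity)
        if seg is None:
            raise ValueError(f"no DIA segment for polarity {polarity}")
        return seg.name
    candidates = [
        s for s in method.ms1_segments() if s.polarity == polarity
    ]
    if window is not None:
        for s in candidates:
            if abs(s.window[0] - window[0]) < 1.0 and abs(s.window[1] - window[1]) < 1.0:
                return s.name
    if len(candidates) == 1:
        return candidates[0].name
    raise ValueError(
        f"cannot map MS1 scan (polarity={polarity}, window={window}) to a segment"
    )


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_params(elem) -> Dict[str, str]:
    out = {}
    for cv in elem.findall(f"{_MZML_NS}cvParam"):
        out[cv.get("name")] = cv.get("value", "")
    return out


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    raw = base64.b64decode(bda.findtext(f"{_MZML_NS}binary") or "")
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f8" if "64-bit float" in params else "<f4"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_run_mzml(path, method: Optional[MethodTemplate] = None) -> AcquisitionRun:
    """Read centroided spectra from mzML, assigning scans to method segments
    by polarity + scan window (MS1) or precursor isolation target (DIA).

    A self-contained reader over lxml handling the common single-run layout
    (64-bit/32-bit float arrays, optional zlib compression); profile data,
    chromatograms and indexed wrappers are out of scope.
    """
    from lxml import etree

    if method is None:
        method = default_method_template()
    run = AcquisitionRun(method)
    tree = etree.parse(str(path))
    for i, sp in enumerate(tree.iter(f"{_MZML_NS}spectrum")):
        params = _cv_params(sp)
        polarity = POSITIVE if "positive scan" in params else NEGATIVE
        arrays: Dict[str, np.ndarray] = {}
        for bda in sp.iter(f"{_MZML_NS}binaryDataArray"):
            p = _cv_params(bda)
            kind = "mz" if "m/z array" in p else (
                "intensity" if "intensity array" in p else None)
            if kind:
                arrays[kind] = _decode_binary_array(bda)
        mzs = arrays.get("mz", np.array([]))
        ints = arrays.get("intensity", np.array([]))
        peaks = [Peak(float(m), float(x)) for m, x in zip(mzs, ints)]
        window = None
        for w in sp.iter(f"{_MZML_NS}scanWindow"):
            p = _cv_params(w)
            try:
                window = (float(p["scan window lower limit"]),
                          float(p["scan window upper limit"]))
            except KeyError:
                pass
            break
        precursor = None
        width = 1.0
        if int(params.get("ms level", "1") or 1) == 2:
            for iso in sp.iter(f"{_MZML_NS}isolationWindow"):
                p = _cv_params(iso)
                precursor = float(p["isolation window target m/z"])
                lo = float(p.get("isolation window lower offset", 0.5))
                hi = float(p.get("isolation window upper offset", 0.5))
                width = lo + hi
                break
        seg = _assign_segment(method, polarity, window, precursor)
        if precursor is None:
            win = window or method[seg].window
            run.add_ms1(Ms1Spectrum(polarity, win, peaks, scan_index=i,
                                    segment=seg))
        else:
            run.add_msms(MsmsScan(polarity, precursor, isolation_width=width,
                                  peaks=peaks, segment=seg, scan_index=i))
    return run


def _b64_floats(values: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def write_run_mzml(run: AcquisitionRun, path) -> None:
    """Write a minimal, uncompressed 64-bit mzML file readable by pyteomics.

    Intended for fixtures and interchange smoke tests, not archival."""
    spectra_xml: List[str] = []
    idx = 0

    def cv(acc: str, name: str, value: str = "") -> str:
        return (f'<cvParam cvRef="MS" accession="{acc}" name="{name}"'
                + (f' value="{value}"' if value != "" else ' value=""') + "/>")

    def binary(arr_name_acc: str, arr_name: str, values: Sequence[float]) -> str:
        b64 = _b64_floats(values)
        return (
            f'<binaryDataArray encodedLength="{len(b64)}">'
            + cv("MS:1000523", "64-bit float")
            + cv("MS:1000576", "no compression")
            + cv(arr_name_acc, arr_name)
            + f"<binary>{b64}</binary></binaryDataArray>"
        )

    def spectrum_xml(peaks: List[Peak], polarity: str, ms_level: int,
                     window: Optional[Tuple[float, float]],
                     precursor: Optional[float], width: float) -> str:
        nonlocal idx
        mzs = [p.mz for p in peaks]
        ints = [p.intensity for p in peaks]
        parts = [
            f'<spectrum index="{idx}" id="scan={idx}" defaultArrayLength="{len(peaks)}">',
            cv("MS:1000511", "ms level", str(ms_level)),
            cv("MS:1000127", "centroid spectrum"),
            cv("MS:1000130" if polarity == POSITIVE else "MS:1000129",
               "positive scan" if polarity == POSITIVE else "negative scan"),
        ]
        if window is not None:
            parts.append(
                '<scanList count="1"><scan><scanWindowList count="1"><scanWindow>'
                + cv("MS:1000501", "scan window lower limit", f"{window[0]:.6f}")
                + cv("MS:1000500", "scan window upper limit", f"{window[1]:.6f}")
                + "</scanWindow></scanWindowList></scan></scanList>"
            )
        if precursor is not None:
            half = width / 2
            parts.append(
                '<precursorList count="1"><precursor><isolationWindow>'
                + cv("MS:1000827", "isolation window target m/z", f"{precursor:.6f}")
                + cv("MS:1000828", "isolation window lower offset", f"{half:.6f}")
                + cv("MS:1000829", "isolation window upper offset", f"{half:.6f}")
                + "</isolationWindow></precursor></precursorList>"
            )
        parts.append(
            '<binaryDataArrayList count="2">'
            + binary("MS:1000514", "m/z array", mzs)
            + binary("MS:1000515", "intensity array", ints)
            + "</binaryDataArrayList></spectrum>"
        )
        idx += 1
        return "".join(parts)

    for seg in run.method.segments:
        for sp in run.ms1.get(seg.name, []):
            spectra_xml.append(
                spectrum_xml(sp.peaks, sp.polarity, 1, sp.window, None, 1.0)
            )
        for sc in self_sorted(run.msms.get(seg.name, [])):
            spectra_xml.append(
                spectrum_xml(sc.peaks, sc.polarity, 2, None,
                             sc.precursor_window_center, sc.isolation_width)
            )

    doc = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="1"><cv id="MS" fullName="PSI-MS" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>'
        '<run id="run1">'
        f'<spectrumList count="{len(spectra_xml)}">'
        + "".join(spectra_xml)
        + "</spectrumList></run></mzML>"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)


# ---------------------------------------------------------------------------
# Scan averaging and lock-mass recalibration

def average_scans(spectra: Sequence[Ms1Spectrum], cluster_tol_ppm: float = 5.0
                  ) -> Ms1Spectrum:
    """Average repeat scans of one segment into a consensus spectrum.

    Peaks from all scans are pooled, sorted, and clustered greedily in
    ascending m/z: a peak opens a new cluster when it lies more than
    ``cluster_tol_ppm`` above the cluster's running intensity-weighted mean.
    Cluster m/z is the intensity-weighted mean; cluster intensity is the sum
    over scans divided by the number of scans (a peak absent from a scan
    counts as zero, so averaging is linear in total ion current).
    """
    if not spectra:
        raise ValueError("no spectra to average")
    pol = spectra[0].polarity
    seg = spectra[0].segment
    if any(s.polarity != pol for s in spectra):
        raise ValueError("mixed polarity in average_scans")
    n = len(spectra)
    pooled = sorted(
        (p for s in spectra for p in s.peaks), key=lambda p: p.mz
    )
    out: List[Peak] = []
    cur_wsum = cur_int = 0.0
    for p in pooled:
        if cur_int > 0:
            mean = cur_wsum / cur_int
            if (p.mz - mean) / mean * 1e6 <= cluster_tol_ppm:
                cur_wsum += p.mz * p.intensity
                cur_int += p.intensity
                continue
            out.append(Peak(mean, cur_int / n))
        cur_wsum = p.mz * p.intensity
        cur_int = p.intensity
    if cur_int > 0:
        out.append(Peak(cur_wsum / cur_int, cur_int / n))
    status = spectra[0].lockmass_status
    if any(s.lockmass_status != status for s in spectra):
        status = LOCK_UNAVAILABLE
    return Ms1Spectrum(pol, spectra[0].window, out, lockmass_status=status,
                       scan_index=0, segment=seg)


def lockmass_recalibrate(s: Ms1Spectrum, reference_mz: float,
                         search_tol_ppm: float = 10.0) -> Ms1Spectrum:
    """Single-point multiplicative recalibration against a background ion.

    If a peak lies within ``search_tol_ppm`` of ``reference_mz`` (the most
    intense such candidate wins), every m/z is scaled by reference/found and
    the spectrum is marked lock-applied.  Orbitrap calibration error is close
    to multiplicative (constant ppm), so a single reference ion per polarity
    suffices.  Absence of the reference is a status, not an error: the
    spectrum is returned unchanged and downstream matching widens its
    tolerance tier.
    """
    lo, hi = s.window
    if not (lo <= reference_mz <= hi):
        raise ValueError(
            f"reference m/z {reference_mz} outside window [{lo}, {hi}]"
        )
    tol = reference_mz * search_tol_ppm * 1e-6
    candidates = [p for p in s.peaks if abs(p.mz - reference_mz) <= tol]
    if not candidates:
        return replace_status(s, LOCK_UNAVAILABLE)
    found = max(candidates, key=lambda p: p.intensity).mz
    factor = reference_mz / found
    peaks = [Peak(p.mz * factor, p.intensity) for p in s.peaks]
    return Ms1Spectrum(s.polarity, s.window, peaks, lockmass_status=LOCK_APPLIED,
                       scan_index=s.scan_index, segment=s.segment)


def replace_status(s: Ms1Spectrum, status: str) -> Ms1Spectrum:
    return Ms1Spectrum(s.polarity, s.window, list(s.peaks),
                       lockmass_status=status, scan_index=s.scan_index,
                       segment=s.segment)
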