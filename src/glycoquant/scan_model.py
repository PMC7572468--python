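"""Domain model and I/O for spectra and the MS2<->MS3 scan hierarchy.

Spectra are held centroided, sorted ascending by m/z, with exact-duplicate
m/z values summed on construction.  MS3 scans are linked to their parent MS2
scans through an explicit table, mirroring the link table produced by raw-file
metadata extractors.

The MGF dialect written/read here extends standard MGF with::

    MSLEVEL=<1|2|3>
    PARENTSCAN=<scan number of the fragmented spectrum>
    ISOLATIONWIDTH=<Th>
    SPSMZ=<comma separated notch m/z values>      (MS3 only)
    MERGED=<0|1>                                  (pseudo-spectra only)
    SOURCEMS3=<comma separated scan numbers>      (pseudo-spectra only)
    ISOTOPEOFFSET=<int>                           (pseudo-spectra only)

because plain MGF carries no MS3 linkage.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple
from xml.etree import ElementTree

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, LinkageError, ParseError

__all__ = [
    "Peak",
    "SpectrumHeader",
    "Spectrum",
    "ScanHierarchy",
    "read_run",
    "read_mgf",
    "read_mzml",
    "write_mgf",
    "build_scan_link_table",
    "write_link_table",
    "tic_normalize",
]


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class SpectrumHeader:
    """Per-scan metadata. ``parent_scan`` points at the fragmented spectrum
    (MS3 -> its MS2, MS2 -> its MS1 survey scan when known)."""

    scan_number: int
    ms_level: int
    retention_time: float = 0.0
    precursor_mz: float | None = None
    precursor_charge: int = 0  # 0 == unknown, resolved by precursor correction
    isolation_width: float = 1.6
    parent_scan: int | None = None
    sps_mz_list: tuple[float, ...] = ()

    def __post_init__(self):
        if self.scan_number < 1:
            raise ValueError(f"scan_number must be >= 1, got {self.scan_number}")
        if self.ms_level not in (1, 2, 3):
            raise ValueError(f"ms_level must be 1, 2 or 3, got {self.ms_level}")
        if self.parent_scan is not None and self.parent_scan >= self.scan_number:
            raise ValueError(
                f"parent_scan {self.parent_scan} must precede scan {self.scan_number}"
            )


class Spectrum:
    """A centroided spectrum: sorted m/z array + intensity array.

    Construction canonicalizes the peak list: peaks are sorted ascending by
    m/z and ties at identical m/z are summed, so two spectra with the same
    peak content compare equal regardless of input order.
    """

    __slots__ = ("header", "mz", "intensity")

    def __init__(self, header: SpectrumHeader, mz: Iterable[float], intensity: Iterable[float]):
        mz_arr = np.asarray(list(mz) if not isinstance(mz, np.ndarray) else mz, dtype=np.float64)
        int_arr = np.asarray(
            list(intensity) if not isinstance(intensity, np.ndarray) else intensity,
            dtype=np.float64,
        )
        if mz_arr.shape != int_arr.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(~np.isfinite(mz_arr)) or np.any(~np.isfinite(int_arr)):
            raise ValueError(f"NaN/inf in spectrum (scan {header.scan_number})")
        if np.any(mz_arr <= 0):
            raise ValueError(f"non-positive m/z in spectrum (scan {header.scan_number})")
        if np.any(int_arr < 0):
            raise ValueError(f"negative intensity in spectrum (scan {header.scan_number})")
        order = np.argsort(mz_arr, kind="stable")
        mz_arr = mz_arr[order]
        int_arr = int_arr[order]
        if mz_arr.size > 1:
            # sum intensities of peaks at exactly identical m/z
            uniq, inverse = np.unique(mz_arr, return_inverse=True)
            if uniq.size != mz_arr.size:
                summed = np.zeros(uniq.size)
                np.add.at(summed, inverse, int_arr)
                mz_arr, int_arr = uniq, summed
        self.header = header
        self.mz = mz_arr
        self.intensity = int_arr

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return int(self.mz.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.header == other.header
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )

    def __repr__(self) -> str:
        return (
            f"Spectrum(scan={self.header.scan_number}, ms{self.header.ms_level}, "
            f"{len(self)} peaks)"
        )


@dataclass
class ScanHierarchy:
    """All spectra of a run plus the MS3 -> parent-MS2 link table."""

    spectra: dict[int, Spectrum] = field(default_factory=dict)
    ms3_parent: dict[int, int] = field(default_factory=dict)

    def validate(self) -> None:
        bad: list[int] = []
        for ms3, ms2 in self.ms3_parent.items():
            if ms3 not in self.spectra or self.spectra[ms3].header.ms_level != 3:
                bad.append(ms3)
            elif ms2 not in self.spectra or self.spectra[ms2].header.ms_level != 2:
                bad.append(ms3)
        if bad:
            raise LinkageError(
                f"MS3 scans with unresolvable parent MS2: {sorted(bad)}", sorted(bad)
            )

    def scans_at_level(self, level: int) -> list[int]:
        return sorted(s for s, sp in self.spectra.items() if sp.header.ms_level == level)

    def ms3_children(self, ms2_scan: int) -> list[int]:
        return sorted(s3 for s3, s2 in self.ms3_parent.items() if s2 == ms2_scan)

    def ms1_before(self, scan: int) -> Spectrum | None:
        """Nearest preceding MS1 survey scan, or None."""
        best = None
        for s, sp in self.spectra.items():
            if sp.header.ms_level == 1 and s < scan and (best is None or s > best):
                best = s
        return self.spectra[best] if best is not None else None

    def add(self, spectrum: Spectrum) -> None:
        self.spectra[spectrum.header.scan_number] = spectrum
        h = spectrum.header
        if h.ms_level == 3 and h.parent_scan is not None:
            self.ms3_parent[h.scan_number] = h.parent_scan


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def tic_normalize(spec: Spectrum) -> Spectrum:
    """Return a copy with intensities divided by the total ion current."""
    total = spec.tic
    if total <= 0:
        raise DegenerateInputError(
            f"cannot TIC-normalize all-zero spectrum (scan {spec.header.scan_number})"
        )
    return Spectrum(spec.header, spec.mz, spec.intensity / total)


def build_scan_link_table(run: ScanHierarchy) -> pd.DataFrame:
    """One (ms3_scan, ms2_scan) row per MS3 scan, ascending by ms3_scan."""
    rows = sorted(run.ms3_parent.items())
    return pd.DataFrame(rows, columns=["ms3_scan", "ms2_scan"], dtype=np.int64)


def write_link_table(run: ScanHierarchy, path: str | Path) -> None:
    build_scan_link_table(run).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

_MZ_FMT = "{:.5f}"
_INT_FMT = "{:.6g}"


def _iter_mgf_blocks(path: Path) -> Iterator[list[str]]:
    block: list[str] | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                block = []
            elif line == "END IONS":
                if block is None:
                    raise ParseError(f"{path}: END IONS without BEGIN IONS")
                yield block
                block = None
            elif block is not None:
                block.append(line)
    if block is not None:
        raise ParseError(f"{path}: unterminated BEGIN IONS block")


def _parse_mgf_block(block: list[str], path: Path) -> tuple[Spectrum, dict[str, str]]:
    fields: dict[str, str] = {}
    mzs: list[float] = []
    ints: list[float] = []
    for line in block:
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            fields[key.upper()] = value.strip()
        else:
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: malformed peak line {line!r}")
            mzs.append(float(parts[0]))
            ints.append(float(parts[1]))
    try:
        scan = int(fields["SCANS"])
    except KeyError:
        raise ParseError(f"{path}: block missing SCANS header") from None
    try:
        ms_level = int(fields.get("MSLEVEL", "2"))
        rt = float(fields.get("RTINSECONDS", "0"))
        prec_mz = None
        prec_int = 0.0
        if "PEPMASS" in fields:
            pm = fields["PEPMASS"].split()
            prec_mz = float(pm[0])
            if len(pm) > 1:
                prec_int = float(pm[1])
        charge = 0
        if "CHARGE" in fields and fields["CHARGE"]:
            charge = int(fields["CHARGE"].rstrip("+-") or 0)
        parent = int(fields["PARENTSCAN"]) if "PARENTSCAN" in fields else None
        iso = float(fields.get("ISOLATIONWIDTH", "1.6"))
        sps: tuple[float, ...] = ()
        if fields.get("SPSMZ"):
            sps = tuple(float(x) for x in fields["SPSMZ"].split(","))
        header = SpectrumHeader(
            scan_number=scan,
            ms_level=ms_level,
            retention_time=rt,
            precursor_mz=prec_mz,
            precursor_charge=charge,
            isolation_width=iso,
            parent_scan=parent,
            sps_mz_list=sps,
        )
        del prec_int
        return Spectrum(header, mzs, ints), fields
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed header in scan {scan}: {exc}") from exc


def read_mgf(path: str | Path) -> ScanHierarchy:
    path = Path(path)
    run = ScanHierarchy()
    for block in _iter_mgf_blocks(path):
        spectrum, _ = _parse_mgf_block(block, path)
        run.add(spectrum)
    _link_ms3(run)
    return run


def _link_ms3(run: ScanHierarchy) -> None:
    bad = []
    for scan in run.scans_at_level(3):
        h = run.spectra[scan].header
        parent = h.parent_scan
        if parent is None or parent not in run.spectra or run.spectra[parent].header.ms_level != 2:
            bad.append(scan)
        else:
            run.ms3_parent[scan] = parent
    if bad:
        raise LinkageError(f"MS3 scans with unresolvable parent MS2: {sorted(bad)}", sorted(bad))
    run.validate()


def _format_mgf_block(spec: Spectrum, extra: dict[str, str] | None = None) -> str:
    h = spec.header
    lines = ["BEGIN IONS", f"TITLE=scan={h.scan_number}", f"SCANS={h.scan_number}"]
    lines.append(f"RTINSECONDS={h.retention_time:.4f}")
    lines.append(f"MSLEVEL={h.ms_level}")
    if h.precursor_mz is not None:
        lines.append(f"PEPMASS={h.precursor_mz:.6f}")
    if h.precursor_charge:
        lines.append(f"CHARGE={h.precursor_charge}+")
    if h.parent_scan is not None:
        lines.append(f"PARENTSCAN={h.parent_scan}")
    lines.append(f"ISOLATIONWIDTH={h.isolation_width:.4f}")
    if h.sps_mz_list:
        lines.append("SPSMZ=" + ",".join(f"{x:.5f}" for x in h.sps_mz_list))
    for key, value in (extra or {}).items():
        lines.append(f"{key}={value}")
    for m, i in zip(spec.mz, spec.intensity):
        lines.append(f"{_MZ_FMT.format(m)} {_INT_FMT.format(i)}")
    lines.append("END IONS")
    return "\n".join(lines)


def write_mgf(run, path: str | Path) -> None:
    """Write a ScanHierarchy or a list of pseudo-spectra in the package MGF dialect."""
    path = Path(path)
    blocks: list[str] = []
    if isinstance(run, ScanHierarchy):
        for scan in sorted(run.spectra):
            blocks.append(_format_mgf_block(run.spectra[scan]))
    else:  # iterable of PseudoSpectrum
        for ps in run:
            blocks.append(ps.to_mgf_block())
    path.write_text("\n".join(blocks) + ("\n" if blocks else ""))


# ---------------------------------------------------------------------------
# mzML (minimal reader; centroided spectra, standard CV terms)
# ---------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"

_CV_MS_LEVEL = "MS:1000511"
_CV_SCAN_START = "MS:1000016"
_CV_SELECTED_MZ = "MS:1000744"
_CV_CHARGE = "MS:1000041"
_CV_ISO_TARGET = "MS:1000827"
_CV_ISO_LOWER = "MS:1000828"
_CV_ISO_UPPER = "MS:1000829"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_64BIT = "MS:1000523"
_CV_32BIT = "MS:1000521"
_CV_ZLIB = "MS:1000574"


def _scan_number_from_id(spectrum_id: str) -> int | None:
    for token in spectrum_id.split():
        if token.startswith("scan="):
            return int(token.split("=", 1)[1])
    return None


def _cv_value(elem, accession: str) -> str | None:
    for cv in elem.iter(_NS + "cvParam"):
        if cv.get("accession") == accession:
            return cv.get("value", "")
    return None


def _decode_binary(binary_elem) -> np.ndarray:
    accessions = {cv.get("accession") for cv in binary_elem.iter(_NS + "cvParam")}
    node = binary_elem.find(_NS + "binary")
    raw = base64.b64decode((node.text or "").strip()) if node is not None else b""
    if _CV_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = np.float64 if _CV_64BIT in accessions or _CV_32BIT not in accessions else np.float32
    count = len(raw) // struct.calcsize("d" if dtype is np.float64 else "f")
    return np.frombuffer(raw, dtype=dtype, count=count).astype(np.float64)


def read_mzml(path: str | Path) -> ScanHierarchy:
    path = Path(path)
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise ParseError(f"{path}: not valid mzML: {exc}") from exc
    run = ScanHierarchy()
    for spec_elem in tree.iter(_NS + "spectrum"):
        sid = spec_elem.get("id", "")
        scan = _scan_number_from_id(sid)
        if scan is None:
            raise ParseError(f"{path}: spectrum id {sid!r} carries no scan number")
        level_str = _cv_value(spec_elem, _CV_MS_LEVEL)
        if level_str is None:
            raise ParseError(f"{path}: scan {scan} lacks an ms level")
        ms_level = int(level_str)
        rt = 0.0
        scan_elem = spec_elem.find(f"{_NS}scanList/{_NS}scan")
        if scan_elem is not None:
            for cv in scan_elem.iter(_NS + "cvParam"):
                if cv.get("accession") == _CV_SCAN_START:
                    rt = float(cv.get("value", "0"))
                    if cv.get("unitName", "") == "minute":
                        rt *= 60.0
        prec_mz = None
        charge = 0
        parent = None
        sps: list[float] = []
        iso_width = 1.6
        for prec in spec_elem.iter(_NS + "precursor"):
            ref = prec.get("spectrumRef", "")
            pscan = _scan_number_from_id(ref) if ref else None
            if pscan is not None:
                parent = pscan
            iso = prec.find(_NS + "isolationWindow")
            target = None
            if iso is not None:
                tval = _cv_value(iso, _CV_ISO_TARGET)
                target = float(tval) if tval else None
                lo = _cv_value(iso, _CV_ISO_LOWER)
                hi = _cv_value(iso, _CV_ISO_UPPER)
                if lo and hi:
                    iso_width = float(lo) + float(hi)
            sel = prec.find(f"{_NS}selectedIonList/{_NS}selectedIon")
            if sel is not None:
                mz_val = _cv_value(sel, _CV_SELECTED_MZ)
                if mz_val:
                    if prec_mz is None:
                        prec_mz = float(mz_val)
                cv_charge = _cv_value(sel, _CV_CHARGE)
                if cv_charge and not charge:
                    charge = int(cv_charge)
            if ms_level == 3 and target is not None:
                sps.append(target)
            elif prec_mz is None and target is not None:
                prec_mz = target
        mz_arr = np.empty(0)
        int_arr = np.empty(0)
        for arr_elem in spec_elem.iter(_NS + "binaryDataArray"):
            accs = {cv.get("accession") for cv in arr_elem.iter(_NS + "cvParam")}
            data = _decode_binary(arr_elem)
            if _CV_MZ_ARRAY in accs:
                mz_arr = data
            elif _CV_INT_ARRAY in accs:
                int_arr = data
        header = SpectrumHeader(
            scan_number=scan,
            ms_level=ms_level,
            retention_time=rt,
            precursor_mz=prec_mz,
            precursor_charge=charge,
            isolation_width=iso_width,
            parent_scan=parent,
            sps_mz_list=tuple(sps),
        )
        run.add(Spectrum(header, mz_arr, int_arr))
    _link_ms3(run)
    return run


def read_run(path: str | Path, format: str | None = None) -> ScanHierarchy:
    """Read a run from mzML or MGF; format inferred from the suffix if omitted."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "mzml" if suffix == ".mzml" else "mgf"
    format = format.lower()
    if format == "mgf":
        return read_mgf(path)
    if format == "mzml":
        return read_mzml(path)
    raise ValueError(f"unsupported format {format!r} (expected 'mzml' or 'mgf')")
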