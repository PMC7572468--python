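"""Merge MS2 and MS3 fragments of one precursor into pseudo-spectra and
re-assign monoisotopic precursors from the surrounding MS1 context."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LinkageError
from .scan_model import ScanHierarchy, Spectrum

log = logging.getLogger(__name__)

__all__ = [
    "MergeConfig",
    "PseudoSpectrum",
    "merge_fragments",
    "correct_precursor",
    "build_pseudo_spectra",
    "merge_report",
    "REPORTER_REGION_MZ",
    "ISOTOPE_SPACING",
]

#: peaks below this m/z are reporter-region signals: kept in the pseudo-spectrum
#: for quantification but excluded from identification scoring.
REPORTER_REGION_MZ = 135.0

#: mass difference between consecutive 13C isotopologues (Da)
ISOTOPE_SPACING = 1.0033548


@dataclass(frozen=True)
class MergeConfig:
    merge_tol_ppm: float = 1.0
    combine_rule: str = "sum"  # or "max"
    isotope_search_range: tuple[int, int] = (-2, 2)  # inclusive offsets
    envelope_tol_ppm: float = 10.0  # MS1 peak lookup tolerance

    def __post_init__(self):
        if self.merge_tol_ppm <= 0:
            raise ValueError("merge_tol_ppm must be > 0")
        if self.combine_rule not in ("sum", "max"):
            raise ValueError(f"combine_rule must be 'sum' or 'max', got {self.combine_rule!r}")


@dataclass
class PseudoSpectrum:
    """Merged MS2+MS3 fragment list with corrected precursor."""

    precursor_mz: float
    precursor_charge: int
    source_ms2: int
    source_ms3: tuple[int, ...]
    mz: np.ndarray
    intensity: np.ndarray
    merged_flag: bool
    isotope_offset_applied: int = 0
    retention_time: float = 0.0

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return int(self.mz.size)

    def to_mgf_block(self) -> str:
        lines = [
            "BEGIN IONS",
            f"TITLE=scan={self.source_ms2}",
            f"SCANS={self.source_ms2}",
            f"RTINSECONDS={self.retention_time:.4f}",
            "MSLEVEL=2",
            f"PEPMASS={self.precursor_mz:.6f}",
        ]
        if self.precursor_charge:
            lines.append(f"CHARGE={self.precursor_charge}+")
        lines.append(f"MERGED={1 if self.merged_flag else 0}")
        if self.source_ms3:
            lines.append("SOURCEMS3=" + ",".join(str(s) for s in self.source_ms3))
        lines.append(f"ISOTOPEOFFSET={self.isotope_offset_applied}")
        for m, i in zip(self.mz, self.intensity):
            lines.append(f"{m:.5f} {i:.6g}")
        lines.append("END IONS")
        return "\n".join(lines)


def _cluster_peaks(
    mz: np.ndarray, intensity: np.ndarray, tol_ppm: float, combine_rule: str
) -> tuple[np.ndarray, np.ndarray]:
    """Single-linkage 1-D clustering: adjacent sorted peaks closer than
    tol_ppm are chained into one cluster, emitted as a single combined peak
    (m/z = intensity-weighted mean)."""
    if mz.size == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz = mz[order]
    intensity = intensity[order]
    gaps_ppm = np.diff(mz) / mz[:-1] * 1e6
    boundaries = np.flatnonzero(gaps_ppm > tol_ppm) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [mz.size]))
    out_mz = np.empty(starts.size)
    out_int = np.empty(starts.size)
    for idx, (a, b) in enumerate(zip(starts, ends)):
        seg_int = intensity[a:b]
        seg_mz = mz[a:b]
        total = seg_int.sum()
        if total > 0:
            out_mz[idx] = float(np.dot(seg_mz, seg_int) / total)
        else:
            out_mz[idx] = float(seg_mz.mean())
        out_int[idx] = total if combine_rule == "sum" else float(seg_int.max())
    return out_mz, out_int


def merge_fragments(
    ms2: Spectrum, ms3_list: list[Spectrum], cfg: MergeConfig | None = None
) -> PseudoSpectrum:
    """Combine the MS2 peaks and all linked MS3 peaks of one precursor.

    Peaks within ``merge_tol_ppm`` of each other collapse into one peak at the
    intensity-weighted mean m/z; the combined intensity follows
    ``cfg.combine_rule``.  Order of ``ms3_list`` does not affect the result.
    """
    cfg = cfg or MergeConfig()
    for ms3 in ms3_list:
        if ms3.header.parent_scan != ms2.header.scan_number:
            raise LinkageError(
                f"MS3 scan {ms3.header.scan_number} has parent "
                f"{ms3.header.parent_scan}, expected {ms2.header.scan_number}",
                [ms3.header.scan_number],
            )
    all_mz = np.concatenate([ms2.mz] + [s.mz for s in ms3_list]) if ms3_list else ms2.mz.copy()
    all_int = (
        np.concatenate([ms2.intensity] + [s.intensity for s in ms3_list])
        if ms3_list
        else ms2.intensity.copy()
    )
    out_mz, out_int = _cluster_peaks(all_mz, all_int, cfg.merge_tol_ppm, cfg.combine_rule)
    h = ms2.header
    return PseudoSpectrum(
        precursor_mz=float(h.precursor_mz) if h.precursor_mz is not None else 0.0,
        precursor_charge=h.precursor_charge,
        source_ms2=h.scan_number,
        source_ms3=tuple(sorted(s.header.scan_number for s in ms3_list)),
        mz=out_mz,
        intensity=out_int,
        merged_flag=bool(ms3_list),
        retention_time=h.retention_time,
    )


def _envelope_lookup(ms1: Spectrum, mz: float, tol_ppm: float) -> float | None:
    """Intensity of the most intense MS1 peak within tol of mz, or None."""
    if len(ms1) == 0:
        return None
    tol = mz * tol_ppm * 1e-6
    lo = np.searchsorted(ms1.mz, mz - tol, side="left")
    hi = np.searchsorted(ms1.mz, mz + tol, side="right")
    if hi <= lo:
        return None
    return float(ms1.intensity[lo:hi].max())


def _infer_charge(ms1: Spectrum, prec_mz: float, cfg: MergeConfig, zmax: int = 6) -> int:
    """Infer charge from isotope spacing around the precursor in MS1.

    Picks the charge whose spacing explains the most envelope peaks;
    ties break toward lower charge. Returns 0 when nothing matches."""
    best_z, best_hits = 0, 1  # require at least 2 envelope peaks
    for z in range(1, zmax + 1):
        spacing = ISOTOPE_SPACING / z
        hits = 0
        for k in range(-1, 4):
            if _envelope_lookup(ms1, prec_mz + k * spacing, cfg.envelope_tol_ppm) is not None:
                hits += 1
        if hits > best_hits:
            best_z, best_hits = z, hits
    return best_z


def correct_precursor(
    pseudo: PseudoSpectrum, ms1_context: Spectrum | None, cfg: MergeConfig | None = None
) -> PseudoSpectrum:
    """Shift the reported precursor onto the monoisotopic envelope peak.

    Walks integer isotope offsets within ``cfg.isotope_search_range``; the
    monoisotope is the left edge of a contiguous envelope (a peak with a
    right neighbour one spacing up and no peak one spacing down).  If no
    envelope is found the precursor is left unchanged with offset 0.
    """
    cfg = cfg or MergeConfig()
    if ms1_context is None or len(ms1_context) == 0 or pseudo.precursor_mz <= 0:
        log.warning(
            "no MS1 context for MS2 scan %d; precursor left unchanged", pseudo.source_ms2
        )
        return pseudo
    z = pseudo.precursor_charge
    if z < 1:
        z = _infer_charge(ms1_context, pseudo.precursor_mz, cfg)
        if z < 1:
            log.warning(
                "could not infer charge for MS2 scan %d; precursor left unchanged",
                pseudo.source_ms2,
            )
            return pseudo
        pseudo.precursor_charge = z
    spacing = ISOTOPE_SPACING / z
    lo, hi = cfg.isotope_search_range
    present: dict[int, float] = {}
    for k in range(lo - 1, hi + 2):
        val = _envelope_lookup(ms1_context, pseudo.precursor_mz + k * spacing, cfg.envelope_tol_ppm)
        if val is not None:
            present[k] = val
    offset = None
    for k in range(lo, hi + 1):
        if k in present and (k - 1) not in present and (k + 1) in present:
            offset = k
            break
    if offset is None:
        log.warning(
            "no isotopic envelope near precursor of MS2 scan %d; left unchanged",
            pseudo.source_ms2,
        )
        return pseudo
    if offset != 0:
        pseudo.precursor_mz = pseudo.precursor_mz + offset * spacing
        pseudo.isotope_offset_applied = offset
    return pseudo


def build_pseudo_spectra(run: ScanHierarchy, cfg: MergeConfig | None = None) -> list[PseudoSpectrum]:
    """One pseudo-spectrum per MS2 scan, consuming all linked MS3 scans,
    ordered by source MS2 scan number."""
    cfg = cfg or MergeConfig()
    run.validate()
    out: list[PseudoSpectrum] = []
    for ms2_scan in run.scans_at_level(2):
        ms2 = run.spectra[ms2_scan]
        children = [run.spectra[s] for s in run.ms3_children(ms2_scan)]
        pseudo = merge_fragments(ms2, children, cfg)
        ms1 = run.ms1_before(ms2_scan)
        pseudo = correct_precursor(pseudo, ms1, cfg)
        out.append(pseudo)
    return out


def merge_report(run: ScanHierarchy, pseudo_list: list[PseudoSpectrum]) -> pd.DataFrame:
    """Per-MS2 summary: scans merged, peak counts in/out, isotope offset."""
    rows = []
    for ps in pseudo_list:
        peaks_in = len(run.spectra[ps.source_ms2])
        peaks_in += sum(len(run.spectra[s]) for s in ps.source_ms3)
        rows.append(
            {
                "ms2_scan": ps.source_ms2,
                "n_ms3": len(ps.source_ms3),
                "peaks_in": peaks_in,
                "peaks_out": len(ps),
                "isotope_offset": ps.isotope_offset_applied,
            }
        )
    return pd.DataFrame(rows, columns=["ms2_scan", "n_ms3", "peaks_in", "peaks_out", "isotope_offset"])
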