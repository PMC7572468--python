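"""Reporter-ion extraction and propagation of quantification from GPSMs to
glycoform, glycosite, and glycan tables, with proteome-median normalization
and Z-score regulation calls."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scan_model import ScanHierarchy, Spectrum
from .search_engine import GPSM

log = logging.getLogger(__name__)

__all__ = [
    "TMT6_CHANNELS",
    "ReporterSet",
    "extract_reporters",
    "attach_quant",
    "propagate",
    "propagate_table",
    "compute_ratios",
    "normalize_ratios",
    "call_regulation",
]

#: standard 6-plex reporter-ion m/z values; editable for other plexes
TMT6_CHANNELS: dict[str, float] = {
    "126": 126.12773,
    "127": 127.13108,
    "128": 128.13444,
    "129": 129.13779,
    "130": 130.14114,
    "131": 131.14450,
}


@dataclass(frozen=True)
class ReporterSet:
    channels: tuple[str, ...]
    expected_mz: tuple[float, ...]
    intensities: tuple[float, ...]
    tolerance: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.channels, self.intensities))


def extract_reporters(
    ms3: Spectrum, channels: dict[str, float] | None = None, tol: float = 0.003
) -> ReporterSet:
    """Per channel, the most intense peak within ``tol`` Th of the channel
    m/z; 0 when no peak falls in the window."""
    channels = channels or TMT6_CHANNELS
    labels = tuple(channels)
    mzs = tuple(channels[c] for c in labels)
    centers = sorted(mzs)
    for a, b in zip(centers, centers[1:]):
        if b - a < 2 * tol:
            raise ConfigurationError(
                f"reporter windows overlap: channels at {a} and {b} with tol {tol}"
            )
    out = []
    for mz in mzs:
        lo = int(np.searchsorted(ms3.mz, mz - tol, side="left"))
        hi = int(np.searchsorted(ms3.mz, mz + tol, side="right"))
        out.append(float(ms3.intensity[lo:hi].max()) if hi > lo else 0.0)
    return ReporterSet(labels, mzs, tuple(out), tol)


def attach_quant(
    gpsms: list[GPSM],
    run: ScanHierarchy,
    channels: dict[str, float] | None = None,
    tol: float = 0.003,
) -> list[GPSM]:
    """Fill each GPSM's reporter intensities from its linked MS3 scan(s),
    summing channel-wise over multiple MS3; falls back to the MS2 scan itself
    when no MS3 is linked (plain-MS2 acquisitions)."""
    channels = channels or TMT6_CHANNELS
    labels = tuple(channels)
    for g in gpsms:
        total = np.zeros(len(labels))
        sources = list(g.source_ms3) or [g.source_ms2]
        for scan in sources:
            rep = extract_reporters(run.spectra[scan], channels, tol)
            total += np.array(rep.intensities)
        g.reporters = tuple(float(x) for x in total)
        g.reporter_channels = labels
    return gpsms


def propagate(gpsms: list[GPSM]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sum GPSM reporter intensities up the hierarchy.

    Glycoform key = (protein, site, glycan); glycosites sum their glycoforms;
    each glycan composition sums every glycoform bearing it.  Channel-wise
    totals are conserved exactly at each level.  Decoy GPSMs are excluded.
    """
    rows = []
    for g in gpsms:
        if not g.is_target:
            continue
        if not g.reporter_channels:
            raise ConfigurationError("GPSM without attached reporters; run attach_quant first")
        row = {
            "protein": g.candidate.peptide.protein_accession,
            "site": g.candidate.site_in_protein,
            "glycan": g.candidate.glycan.to_string(),
            "fucosylated": g.candidate.glycan.fuc > 0,
            "all_zero": all(v == 0 for v in g.reporters),
        }
        for ch, val in zip(g.reporter_channels, g.reporters):
            row[f"intensity_{ch}"] = val
        rows.append(row)
    if not rows:
        empty = pd.DataFrame()
        return empty, empty.copy(), empty.copy()
    return propagate_table(pd.DataFrame(rows))


def propagate_table(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Table-level propagation: input needs protein/site/glycan keys and
    intensity_<channel> columns (one row per GPSM)."""
    df = df.copy()
    if "fucosylated" not in df.columns:
        df["fucosylated"] = df["glycan"].str.contains(r"Fuc\([1-9]")
    intensity_cols = [c for c in df.columns if c.startswith("intensity_")]
    if "all_zero" not in df.columns:
        df["all_zero"] = (df[intensity_cols] == 0).all(axis=1)
    sums = {c: (c, "sum") for c in intensity_cols}
    glycoform = (
        df.groupby(["protein", "site", "glycan", "fucosylated"], as_index=False)
        .agg(n_gpsms=("glycan", "size"), n_zero_gpsms=("all_zero", "sum"), **sums)
        .sort_values(["protein", "site", "glycan"], ignore_index=True)
    )
    glycosite = (
        glycoform.groupby(["protein", "site"], as_index=False)
        .agg(n_glycoforms=("glycan", "size"), **sums)
        .sort_values(["protein", "site"], ignore_index=True)
    )
    glycan = (
        glycoform.groupby(["glycan"], as_index=False)
        .agg(n_glycoforms=("protein", "size"), **sums)
        .sort_values(["glycan"], ignore_index=True)
    )
    return glycoform, glycosite, glycan


def _ratio_columns(table: pd.DataFrame, reference: str) -> tuple[list[str], str]:
    intensity_cols = [c for c in table.columns if c.startswith("intensity_")]
    ref_col = f"intensity_{reference}"
    if ref_col not in intensity_cols:
        raise ConfigurationError(f"reference channel {reference!r} not in table")
    return intensity_cols, ref_col


def compute_ratios(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Add ratio_<channel> columns = intensity_<channel> / intensity_<ref>."""
    table = table.copy()
    intensity_cols, ref_col = _ratio_columns(table, reference)
    ref = table[ref_col].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for col in intensity_cols:
            ch = col.removeprefix("intensity_")
            table[f"ratio_{ch}"] = np.where(ref > 0, table[col] / ref, np.nan)
    return table


def normalize_ratios(
    glyco: pd.DataFrame, proteome_ratios: pd.DataFrame, reference: str
) -> pd.DataFrame:
    """Divide each raw channel ratio by the median proteome ratio of that
    channel.  ``proteome_ratios`` must carry one column per channel (named by
    channel label) holding reference-relative ratios."""
    table = compute_ratios(glyco, reference) if not any(
        c.startswith("ratio_") for c in glyco.columns
    ) else glyco.copy()
    ratio_cols = [c for c in table.columns if c.startswith("ratio_")]
    for col in ratio_cols:
        ch = col.removeprefix("ratio_")
        if ch not in proteome_ratios.columns:
            raise ConfigurationError(f"proteome ratio table has no column for channel {ch}")
        med = float(proteome_ratios[ch].median())
        if not np.isfinite(med) or med == 0:
            raise ConfigurationError(f"zero/absent proteome median for channel {ch}")
        table[f"norm_ratio_{ch}"] = table[col] / med
    return table


def call_regulation(
    normalized: pd.DataFrame,
    condition_channels: list[str],
    z_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Per condition channel, Z-score of log2 normalized ratio across entries;
    regulated when |z| > cutoff.  Needs >= 3 entries and a non-zero spread,
    otherwise the channel is flagged and z left undefined."""
    out = normalized.copy()
    for ch in condition_channels:
        col = f"norm_ratio_{ch}"
        if col not in out.columns:
            raise ConfigurationError(f"normalized table has no column {col}")
        vals = out[col].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logr = np.log2(vals)
        finite = np.isfinite(logr)
        zcol, rcol, fcol = f"z_{ch}", f"regulated_{ch}", f"flag_{ch}"
        if finite.sum() < 3:
            out[zcol] = np.nan
            out[rcol] = False
            out[fcol] = "insufficient"
            log.warning("channel %s: fewer than 3 usable entries for Z-scores", ch)
            continue
        mean = logr[finite].mean()
        sd = logr[finite].std(ddof=1)
        if sd == 0:
            out[zcol] = np.nan
            out[rcol] = False
            out[fcol] = "zero_sd"
            log.warning("channel %s: zero spread, Z undefined", ch)
            continue
        z = (logr - mean) / sd
        out[zcol] = z
        out[rcol] = np.where(np.isfinite(z), np.abs(z) > z_cutoff, False)
        out[fcol] = "ok"
    return out
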