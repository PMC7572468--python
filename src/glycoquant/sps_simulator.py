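"""Synthetic multi-notch MS3 acquisition runs with ground truth.

Emulates the scan structure of the acquisition method (one low-energy MS2
producing glycan Y ions, one linked MS3 of the co-selected notches producing
peptide b/y ions plus isobaric reporter ions) and the co-isolation
interference mixture experiment: a glyco analyte with a designed six-channel
mixing vector contaminated by a background analyte labeled in the first
three channels only.

Reporter model per channel c:  I_c = A*r_c + f*alpha*B*s_c
with A/B the total analyte/contaminant signal, r/s the normalized channel
designs, f the co-isolated fraction, and alpha the contaminant carry-through
into MS3 (1 = MS2-like, 0 = perfect purification).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .glyco_space import (
    GlycanComposition,
    GlycopeptideCandidate,
    MASSES,
    PeptideEntry,
    Protein,
    enumerate_by_ions,
    enumerate_y_ions,
    peptide_mass,
    tryptic_digest,
)
from .pseudo_merge import ISOTOPE_SPACING, REPORTER_REGION_MZ
from .quant_engine import TMT6_CHANNELS
from .scan_model import ScanHierarchy, Spectrum, SpectrumHeader

__all__ = [
    "SimConfig",
    "simulate_run",
    "select_sps",
    "simulate_interference_mixture",
    "InterferenceSim",
    "export_ground_truth",
    "read_ground_truth",
    "generate_proteins",
    "default_sim_glycans",
    "IGM_YEAST_DESIGN",
    "YEAST_CONTAMINANT_DESIGN",
]

#: six-channel analyte pooling design of the interference experiment
IGM_YEAST_DESIGN = (10.0, 4.0, 1.0, 1.0, 4.0, 10.0)
#: background labeled only in the first three channels, mixed equally
YEAST_CONTAMINANT_DESIGN = (1.0, 1.0, 1.0, 0.0, 0.0, 0.0)

_ENVELOPE_SHAPE = (0.6, 1.0, 0.75, 0.4)  # rises from the monoisotope, then falls
_IMPOSTOR_GLYCAN_SHIFT = 3.5  # Da; deliberately different from the decoy offset


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_glycopeptides: int = 50
    n_impostors: int = 0
    n_proteins: int = 5
    blocks_per_protein: int = 20
    proteins: tuple[Protein, ...] | None = None
    glycans: tuple[GlycanComposition, ...] | None = None
    channel_design: tuple[float, ...] = (1.0,) * 6
    contaminant_design: tuple[float, ...] = YEAST_CONTAMINANT_DESIGN
    interference_fraction: float = 0.0
    sps_attenuation: float = 0.2
    noise_cv: float = 0.0
    noise_floor: float = 0.0
    n_sps_notches: int = 10
    sps_window: tuple[float, float] = (700.0, 2000.0)
    reporter_mode: str = "ms3"  # "ms3" | "ms2"
    label: str = "TMT6"
    base_intensity: float = 1.0e6
    contaminant_intensity: float | None = None  # defaults to base_intensity (1:1)
    precursor_offset_prob: float = 0.3
    charges: tuple[int, ...] = (2, 3)

    def __post_init__(self):
        if min(self.channel_design) < 0 or min(self.contaminant_design) < 0:
            raise ValueError("channel designs must be non-negative")
        if not 0.0 <= self.interference_fraction <= 1.0:
            raise ValueError("interference_fraction must lie in [0, 1]")
        if not 0.0 <= self.sps_attenuation <= 1.0:
            raise ValueError("sps_attenuation must lie in [0, 1]")
        if self.reporter_mode not in ("ms3", "ms2"):
            raise ValueError("reporter_mode must be 'ms3' or 'ms2'")


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------

_FILLER = "ADEFGHILQSTVWY"  # no K/R/P (cleavage control), no C/M/N (mod/sequon control)


def _random_block(rng: np.random.Generator) -> str:
    """A tryptic block: filler residues with one embedded N-X-S/T sequon,
    terminated by K or R."""
    length = int(rng.integers(8, 14))
    letters = [str(rng.choice(list(_FILLER))) for _ in range(length)]
    pos = int(rng.integers(1, length - 3))
    letters[pos] = "N"
    if letters[pos + 1] == "P":
        letters[pos + 1] = "A"
    letters[pos + 2] = "S" if rng.random() < 0.5 else "T"
    letters.append("K" if rng.random() < 0.5 else "R")
    return "".join(letters)


def generate_proteins(
    rng: np.random.Generator, n_proteins: int, blocks_per_protein: int = 20
) -> list[Protein]:
    """Random proteins whose tryptic peptides each carry one sequon."""
    return [
        Protein(
            f"SIM{p + 1:03d}",
            "".join(_random_block(rng) for _ in range(blocks_per_protein)),
        )
        for p in range(n_proteins)
    ]


def default_sim_glycans() -> list[GlycanComposition]:
    """A compact pool of common-sized compositions for desk-scale runs."""
    return [
        GlycanComposition(3, 2, 0, 0),
        GlycanComposition(4, 2, 0, 0),
        GlycanComposition(5, 2, 0, 0),
        GlycanComposition(5, 2, 0, 1),
        GlycanComposition(3, 2, 1, 0),
        GlycanComposition(4, 3, 0, 0),
        GlycanComposition(4, 3, 1, 1),
        GlycanComposition(5, 4, 0, 0),
    ]


# ---------------------------------------------------------------------------
# acquisition logic
# ---------------------------------------------------------------------------


def select_sps(ms2: Spectrum, cfg: SimConfig | None = None) -> list[float]:
    """Notch selection: the most intense in-window MS2 peaks, up to the notch
    limit, returned in descending intensity.  Reporter-region peaks are never
    selected regardless of the configured window."""
    cfg = cfg or SimConfig()
    lo, hi = cfg.sps_window
    mask = (ms2.mz >= max(lo, REPORTER_REGION_MZ)) & (ms2.mz <= hi)
    mzs = ms2.mz[mask]
    ints = ms2.intensity[mask]
    if mzs.size == 0:
        return []
    order = np.argsort(-ints, kind="stable")[: cfg.n_sps_notches]
    return [float(m) for m in mzs[order]]


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------


@dataclass
class _Analyte:
    peptide: PeptideEntry
    site: int
    glycan: GlycanComposition
    charge: int
    candidate: GlycopeptideCandidate
    is_true: bool


def _sample_analytes(cfg: SimConfig, rng: np.random.Generator) -> tuple[
    list[_Analyte], list[Protein], list[GlycanComposition]
]:
    proteins = (
        list(cfg.proteins)
        if cfg.proteins is not None
        else generate_proteins(rng, cfg.n_proteins, cfg.blocks_per_protein)
    )
    glycans = list(cfg.glycans) if cfg.glycans is not None else default_sim_glycans()
    if not proteins or not glycans:
        raise ConfigurationError("empty protein or glycan pool")
    pairs: list[tuple[PeptideEntry, int]] = []
    for prot in proteins:
        for pep in tryptic_digest(prot, max_missed=0, min_len=6):
            if 6 <= len(pep.sequence) <= 26:
                for site in pep.sequon_positions:
                    pairs.append((pep, site))
    if not pairs:
        raise ConfigurationError("protein pool yields no sequon-bearing peptides")
    analytes: list[_Analyte] = []
    seen: set[tuple[str, int, str]] = set()
    attempts = 0
    while len(analytes) < cfg.n_glycopeptides and attempts < cfg.n_glycopeptides * 50:
        attempts += 1
        pep, site = pairs[int(rng.integers(len(pairs)))]
        glycan = glycans[int(rng.integers(len(glycans)))]
        key = (pep.sequence, site, glycan.to_string())
        if key in seen:
            continue
        seen.add(key)
        charge = int(rng.choice(cfg.charges))
        cand = GlycopeptideCandidate(
            peptide=pep,
            site=site,
            glycan=glycan,
            label=cfg.label,
            neutral_mass=peptide_mass(pep, MASSES, cfg.label) + glycan.mass(MASSES),
        )
        analytes.append(_Analyte(pep, site, glycan, charge, cand, True))
    # impostors: shuffled sequences + mass-shifted glycans, absent from any database
    target_seqs = {p.sequence for p, _ in pairs}
    made = 0
    while made < cfg.n_impostors:
        pep, site = pairs[int(rng.integers(len(pairs)))]
        glycan = glycans[int(rng.integers(len(glycans)))]
        interior = list(pep.sequence[:-1])
        rng.shuffle(interior)
        shuffled = "".join(interior) + pep.sequence[-1]
        if shuffled == pep.sequence or shuffled in target_seqs:
            continue
        fake = dataclasses.replace(
            pep,
            sequence=shuffled,
            protein_accession=f"IMPOSTOR{made + 1:04d}",
            sequon_positions=(1,),
            fixed_mods=tuple(
                (i + 1, MASSES.carbamidomethyl)
                for i, aa in enumerate(shuffled)
                if aa == "C"
            ),
        )
        cand = GlycopeptideCandidate(
            peptide=fake,
            site=1,
            glycan=glycan,
            is_glycan_decoy=True,  # reuse the shift machinery for the fake glycan mass
            glycan_mass_shift=_IMPOSTOR_GLYCAN_SHIFT,
            label=cfg.label,
            neutral_mass=peptide_mass(fake, MASSES, cfg.label)
            + glycan.mass(MASSES)
            + _IMPOSTOR_GLYCAN_SHIFT,
        )
        charge = int(rng.choice(cfg.charges))
        analytes.append(_Analyte(fake, 1, glycan, charge, cand, False))
        made += 1
    return analytes, proteins, glycans


def _noisy(values: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    out = values.astype(float)
    if cfg.noise_cv > 0:
        out = out * np.exp(rng.normal(0.0, cfg.noise_cv, size=out.shape))
    if cfg.noise_floor > 0:
        out = out + rng.exponential(cfg.noise_floor, size=out.shape)
    return out


def _best_fragment_mz(neutral: float, zmax: int, window: tuple[float, float]) -> float:
    """m/z of the fragment at the charge placing it closest to the window centre."""
    proton = MASSES.proton
    center = 0.5 * (window[0] + window[1])
    options = [(neutral + z * proton) / z for z in range(1, max(zmax, 1) + 1)]
    return min(options, key=lambda m: abs(m - center))


def _reporter_vector(cfg: SimConfig, carry: float) -> np.ndarray:
    r = np.asarray(cfg.channel_design, dtype=float)
    r = r / r.sum()
    s = np.asarray(cfg.contaminant_design, dtype=float)
    s_sum = s.sum()
    s = s / s_sum if s_sum > 0 else s
    a_total = cfg.base_intensity
    b_total = (
        cfg.contaminant_intensity if cfg.contaminant_intensity is not None else a_total
    )
    return a_total * r + cfg.interference_fraction * carry * b_total * s


def simulate_run(cfg: SimConfig) -> tuple[ScanHierarchy, pd.DataFrame]:
    """Generate a full run (MS1 context, MS2, linked MS3) plus ground truth.

    Deterministic under a fixed seed: the emitted MGF is byte-identical
    across repeated calls with the same config.
    """
    rng = np.random.default_rng(cfg.seed)
    analytes, proteins, glycans = _sample_analytes(cfg, rng)
    run = ScanHierarchy()
    truth_rows = []
    channels = TMT6_CHANNELS
    n_channels = len(cfg.channel_design)
    if n_channels != len(channels):
        raise ConfigurationError(
            f"channel design length {n_channels} != {len(channels)} reporter channels"
        )
    scan = 0
    rt = 0.0
    for analyte in analytes:
        rt += 3.0
        z = analyte.charge
        mono_neutral = analyte.candidate.neutral_mass
        mono_mz = mono_neutral / z + MASSES.proton
        spacing = ISOTOPE_SPACING / z

        # --- MS1 survey with isotope envelope
        scan += 1
        ms1_scan = scan
        env_mz = [mono_mz + k * spacing for k in range(len(_ENVELOPE_SHAPE))]
        env_int = [cfg.base_intensity * w for w in _ENVELOPE_SHAPE]
        run.add(
            Spectrum(
                SpectrumHeader(ms1_scan, 1, retention_time=rt),
                env_mz,
                env_int,
            )
        )
        off_by_one = rng.random() < cfg.precursor_offset_prob
        reported_mz = mono_mz + (spacing if off_by_one else 0.0)

        # --- MS2: glycan Y-series (low-energy profile), dominant small cores
        y_ions = enumerate_y_ions(analyte.candidate, MASSES)
        mz_list: list[float] = []
        int_list: list[float] = []
        frag_base = cfg.base_intensity * 0.1
        for label, neutral in y_ions:
            frag_mz = _best_fragment_mz(neutral, z, cfg.sps_window)
            n_residues = 0 if label == "Y0" else sum(
                int(x) for x in label.split("+")[1].split(".")
            )
            core_bias = 1.0 / (1.0 + 0.5 * n_residues)
            w = core_bias * float(np.exp(rng.normal(0.0, 0.5)))
            mz_list.append(frag_mz)
            int_list.append(frag_base * w)
        f = cfg.interference_fraction
        if f > 0:
            n_cont = 15
            cont_mz = rng.uniform(300.0, 1800.0, size=n_cont)
            cont_int = (
                f
                * (cfg.contaminant_intensity or cfg.base_intensity)
                * 0.05
                * np.exp(rng.normal(0.0, 0.5, size=n_cont))
            )
            mz_list.extend(float(m) for m in cont_mz)
            int_list.extend(float(i) for i in cont_int)

        by_ions = enumerate_by_ions(analyte.peptide, MASSES, cfg.label)
        reporter_truth = _reporter_vector(
            cfg, carry=1.0 if cfg.reporter_mode == "ms2" else cfg.sps_attenuation
        )
        if f == 0:
            r = np.asarray(cfg.channel_design, dtype=float)
            reporter_truth = cfg.base_intensity * r / r.sum()

        if cfg.reporter_mode == "ms2":
            # plain-MS2 acquisition: b/y ions land in the MS2 scan too
            for label, neutral in by_ions:
                mz_list.append(neutral + MASSES.proton)
                int_list.append(
                    cfg.base_intensity * 0.05 * float(np.exp(rng.normal(0.0, 0.5)))
                )

        frag_int = _noisy(np.asarray(int_list), cfg, rng)
        if cfg.reporter_mode == "ms2":
            # reporters read from MS2 experience the full interference (no alpha)
            reporters = _noisy(reporter_truth.copy(), cfg, rng)
            mz_list = mz_list + list(channels.values())
            frag_int = np.concatenate([frag_int, reporters])
        scan += 1
        ms2_scan = scan
        ms2_spec = Spectrum(
            SpectrumHeader(
                ms2_scan,
                2,
                retention_time=rt + 0.5,
                precursor_mz=reported_mz,
                precursor_charge=z,
                parent_scan=ms1_scan,
            ),
            mz_list,
            frag_int,
        )
        run.add(ms2_spec)

        if cfg.reporter_mode == "ms3":
            notches = select_sps(ms2_spec, cfg)
            keep = rng.random(len(by_ions)) < 0.75
            min_keep = int(np.ceil(0.6 * len(by_ions)))
            if keep.sum() < min_keep:
                for idx in np.flatnonzero(~keep):
                    keep[idx] = True
                    if keep.sum() >= min_keep:
                        break
            ms3_mz: list[float] = []
            ms3_int: list[float] = []
            for (label, neutral), used in zip(by_ions, keep):
                if not used:
                    continue
                ms3_mz.append(neutral + MASSES.proton)
                ms3_int.append(
                    cfg.base_intensity * 0.05 * float(np.exp(rng.normal(0.0, 0.5)))
                )
            reporters = _noisy(reporter_truth.copy(), cfg, rng)
            ms3_mz.extend(channels.values())
            ms3_int.extend(float(v) for v in reporters)
            scan += 1
            run.add(
                Spectrum(
                    SpectrumHeader(
                        scan,
                        3,
                        retention_time=rt + 1.0,
                        precursor_mz=reported_mz,
                        precursor_charge=z,
                        parent_scan=ms2_scan,
                        sps_mz_list=tuple(notches) or (reported_mz,),
                    ),
                    ms3_mz,
                    ms3_int,
                )
            )

        row = {
            "ms2_scan": ms2_scan,
            "protein": analyte.peptide.protein_accession,
            "peptide": analyte.peptide.sequence,
            "site": analyte.peptide.start_pos + analyte.site - 1,
            "glycan": analyte.glycan.to_string(),
            "charge": z,
            "is_true": analyte.is_true,
            "contaminated": f > 0,
            "isotope_offset": 1 if off_by_one else 0,
        }
        for ch, val in zip(channels, reporter_truth):
            row[f"true_{ch}"] = float(val)
        truth_rows.append(row)
    run.validate()
    truth = pd.DataFrame(truth_rows)
    return run, truth


@dataclass
class InterferenceSim:
    """Paired emission of the interference mixture: the SPS-MS3 run (reporter
    carry-through attenuated by alpha) and the plain-MS2 run (full
    interference), sharing one analyte sample and ground-truth design."""

    sps_run: ScanHierarchy
    ms2_run: ScanHierarchy
    truth_sps: pd.DataFrame
    truth_ms2: pd.DataFrame
    proteins: tuple[Protein, ...]
    glycans: tuple[GlycanComposition, ...]
    config: SimConfig


def simulate_interference_mixture(
    seed: int = 0,
    n_glycopeptides: int = 40,
    interference_fraction: float = 0.5,
    sps_attenuation: float = 0.2,
    noise_cv: float = 0.0,
    n_proteins: int = 2,
) -> InterferenceSim:
    """The six-channel interference mixture: glyco analytes pooled
    10:4:1:1:4:10 across channels 126..131, a background labeled 1:1:1 in
    channels 126-128 only, spiked 1:1 by total amount.  Channels 129-131 are
    interference-free by design in both acquisition modes."""
    pool_rng = np.random.default_rng(seed)
    proteins = tuple(generate_proteins(pool_rng, n_proteins, blocks_per_protein=25))
    glycans = tuple(default_sim_glycans())
    base = SimConfig(
        seed=seed + 1,
        n_glycopeptides=n_glycopeptides,
        proteins=proteins,
        glycans=glycans,
        channel_design=IGM_YEAST_DESIGN,
        contaminant_design=YEAST_CONTAMINANT_DESIGN,
        interference_fraction=interference_fraction,
        sps_attenuation=sps_attenuation,
        noise_cv=noise_cv,
        reporter_mode="ms3",
    )
    sps_run, truth_sps = simulate_run(base)
    ms2_cfg = dataclasses.replace(base, reporter_mode="ms2")
    ms2_run, truth_ms2 = simulate_run(ms2_cfg)
    return InterferenceSim(
        sps_run=sps_run,
        ms2_run=ms2_run,
        truth_sps=truth_sps,
        truth_ms2=truth_ms2,
        proteins=proteins,
        glycans=glycans,
        config=base,
    )


def export_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
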