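"""Glycopeptide search space: tryptic digestion, sequon detection, masses,
glycan library, theoretical fragment series, decoys, and the precursor index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlphabetError, ConfigurationError, LocationError

__all__ = [
    "Protein",
    "PeptideEntry",
    "GlycanComposition",
    "GlycanEntry",
    "GlycopeptideCandidate",
    "MassTable",
    "MASSES",
    "read_fasta",
    "write_fasta",
    "tryptic_digest",
    "find_sequons",
    "peptide_mass",
    "enumerate_y_ions",
    "enumerate_by_ions",
    "build_candidate_index",
    "CandidateIndex",
    "generate_candidates",
    "make_peptide_decoys",
    "make_glycan_decoys",
    "default_glycan_library",
    "read_glycan_library",
    "write_glycan_library",
    "oxidation_variants",
    "GLYCAN_DECOY_SHIFT",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: fixed neutral-mass offset applied to glycan-bearing ions of glycan decoys
GLYCAN_DECOY_SHIFT = 17.00274


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic masses (Da) used across the package."""

    residues: dict[str, float] = field(
        default_factory=lambda: {
            "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
            "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
            "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
            "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
            "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
        }
    )
    water: float = 18.01056
    proton: float = 1.00728
    monosaccharides: dict[str, float] = field(
        default_factory=lambda: {
            "hex": 162.05282,
            "hexnac": 203.07937,
            "neuac": 291.09542,
            "fuc": 146.05791,
        }
    )
    carbamidomethyl: float = 57.02146
    oxidation: float = 15.99492
    labels: dict[str, float] = field(
        default_factory=lambda: {"TMT6": 229.16293, "TMT0": 224.15248, "none": 0.0}
    )


MASSES = MassTable()


@dataclass(frozen=True)
class Protein:
    accession: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise AlphabetError(
                f"protein {self.accession} contains unsupported residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class PeptideEntry:
    """One digestion product located within its parent protein.

    ``fixed_mods``/``variable_mods`` map 1-based residue positions to mass
    additions in Da; position 0 is reserved for N-terminal modifications.
    """

    sequence: str
    protein_accession: str
    start_pos: int  # 1-based residue index in protein
    missed_cleavages: int
    sequon_positions: tuple[int, ...] = ()
    fixed_mods: tuple[tuple[int, float], ...] = ()
    variable_mods: tuple[tuple[int, float], ...] = ()
    is_decoy: bool = False

    def mods_at(self) -> dict[int, float]:
        mods: dict[int, float] = {}
        for pos, mass in self.fixed_mods:
            mods[pos] = mods.get(pos, 0.0) + mass
        for pos, mass in self.variable_mods:
            mods[pos] = mods.get(pos, 0.0) + mass
        return mods


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of the four monosaccharide classes defining a composition."""

    hex: int = 0
    hexnac: int = 0
    neuac: int = 0
    fuc: int = 0

    def __post_init__(self):
        if min(self.hex, self.hexnac, self.neuac, self.fuc) < 0:
            raise ValueError("monosaccharide counts must be >= 0")

    @property
    def total(self) -> int:
        return self.hex + self.hexnac + self.neuac + self.fuc

    def mass(self, masses: MassTable = MASSES) -> float:
        ms = masses.monosaccharides
        return (
            self.hex * ms["hex"]
            + self.hexnac * ms["hexnac"]
            + self.neuac * ms["neuac"]
            + self.fuc * ms["fuc"]
        )

    def to_string(self) -> str:
        return f"Hex({self.hex})HexNAc({self.hexnac})NeuAc({self.neuac})Fuc({self.fuc})"

    @classmethod
    def from_string(cls, s: str) -> "GlycanComposition":
        import re

        m = re.fullmatch(r"Hex\((\d+)\)HexNAc\((\d+)\)NeuAc\((\d+)\)Fuc\((\d+)\)", s)
        if not m:
            raise ValueError(f"cannot parse glycan string {s!r}")
        return cls(int(m.group(1)), int(m.group(2)), int(m.group(3)), int(m.group(4)))


@dataclass(frozen=True)
class GlycanEntry:
    """A glycan library entry; decoys carry a fixed mass shift on every
    glycan-containing ion (the bare-peptide Y0 ion is never shifted)."""

    composition: GlycanComposition
    is_decoy: bool = False
    mass_shift: float = 0.0

    def mass(self, masses: MassTable = MASSES) -> float:
        return self.composition.mass(masses) + self.mass_shift


@dataclass(frozen=True)
class GlycopeptideCandidate:
    peptide: PeptideEntry
    site: int  # 1-based position within peptide
    glycan: GlycanComposition
    is_peptide_decoy: bool = False
    is_glycan_decoy: bool = False
    glycan_mass_shift: float = 0.0
    label: str = "TMT6"
    neutral_mass: float = 0.0

    @property
    def decoy_class(self) -> str:
        if self.is_peptide_decoy and self.is_glycan_decoy:
            return "both"
        if self.is_peptide_decoy:
            return "pep_decoy"
        if self.is_glycan_decoy:
            return "gly_decoy"
        return "target"

    @property
    def candidate_id(self) -> str:
        mods = ";".join(f"{p}:{m:.5f}" for p, m in sorted(self.peptide.variable_mods))
        return (
            f"{self.peptide.protein_accession}|{self.peptide.sequence}|{self.site}|"
            f"{self.glycan.to_string()}|{self.decoy_class}|{mods}"
        )

    @property
    def site_in_protein(self) -> int:
        return self.peptide.start_pos + self.site - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[Protein]:
    """Accession = first whitespace-delimited token after '>'."""
    proteins: list[Protein] = []
    acc: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if acc is not None:
                    proteins.append(Protein(acc, "".join(chunks)))
                acc = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if acc is not None:
        proteins.append(Protein(acc, "".join(chunks)))
    return proteins


def write_fasta(proteins: Iterable[Protein], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.accession}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# digestion and sequons
# ---------------------------------------------------------------------------


def _cleavage_sites(sequence: str) -> list[int]:
    """0-based positions after which trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    protein: Protein,
    max_missed: int = 2,
    min_len: int = 4,
    masses: MassTable = MASSES,
    carbamidomethyl: bool = True,
) -> list[PeptideEntry]:
    """Fully-specific tryptic peptides with up to ``max_missed`` missed
    cleavages, ordered by start position then length.  Cysteines carry the
    fixed carbamidomethyl mass."""
    seq = protein.sequence
    sites = _cleavage_sites(seq)
    boundaries = [0] + [s + 1 for s in sites] + [len(seq)]
    out: list[PeptideEntry] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            pep = seq[start:end]
            if len(pep) < min_len:
                continue
            fixed = tuple(
                (k + 1, masses.carbamidomethyl)
                for k, aa in enumerate(pep)
                if aa == "C" and carbamidomethyl
            )
            entry = PeptideEntry(
                sequence=pep,
                protein_accession=protein.accession,
                start_pos=start + 1,
                missed_cleavages=j - i - 1,
                fixed_mods=fixed,
            )
            entry = replace(entry, sequon_positions=tuple(find_sequons(entry, protein)))
            out.append(entry)
    return out


def find_sequons(pep: PeptideEntry, protein: Protein | None = None) -> list[int]:
    """1-based peptide positions matching N-X-S/T (X != P), looking across the
    peptide C-terminus into the protein when context is available."""
    seq = pep.sequence
    if protein is not None:
        start = pep.start_pos - 1
        if protein.sequence[start : start + len(seq)] != seq:
            raise LocationError(
                f"peptide {seq} not found at position {pep.start_pos} of "
                f"{protein.accession}"
            )
        context = protein.sequence
        offset = start
    else:
        context = seq
        offset = 0
    positions = []
    for i, aa in enumerate(seq):
        if aa != "N":
            continue
        gi = offset + i
        if gi + 2 >= len(context):
            continue
        x, st = context[gi + 1], context[gi + 2]
        if x != "P" and st in "ST":
            positions.append(i + 1)
    return positions


# ---------------------------------------------------------------------------
# masses and fragment series
# ---------------------------------------------------------------------------


def peptide_mass(
    pep: PeptideEntry, masses: MassTable = MASSES, label: str = "TMT6"
) -> float:
    """Neutral monoisotopic peptide mass including fixed/variable mods and
    one label per N-terminus plus one per lysine."""
    try:
        total = sum(masses.residues[aa] for aa in pep.sequence)
    except KeyError as exc:
        raise AlphabetError(f"unknown residue {exc.args[0]!r} in {pep.sequence}") from exc
    total += masses.water
    total += sum(m for _, m in pep.fixed_mods)
    total += sum(m for _, m in pep.variable_mods)
    label_mass = masses.labels[label]
    total += label_mass * (1 + pep.sequence.count("K"))
    return total


def oxidation_variants(
    pep: PeptideEntry, masses: MassTable = MASSES, max_ox: int = 3
) -> list[PeptideEntry]:
    """The peptide plus every variant with up to ``max_ox`` oxidized methionines."""
    met_positions = [i + 1 for i, aa in enumerate(pep.sequence) if aa == "M"]
    out = [pep]
    for n in range(1, min(max_ox, len(met_positions)) + 1):
        for combo in itertools.combinations(met_positions, n):
            out.append(
                replace(
                    pep,
                    variable_mods=tuple((p, masses.oxidation) for p in combo),
                )
            )
    return out


def _sub_compositions(glycan: GlycanComposition) -> list[GlycanComposition]:
    """Every sub-composition g' <= glycan satisfying attachment rules:
    any non-empty g' needs hexnac >= 1; sialic acid requires a hexose."""
    subs = []
    for h, n, s, f in itertools.product(
        range(glycan.hex + 1),
        range(glycan.hexnac + 1),
        range(glycan.neuac + 1),
        range(glycan.fuc + 1),
    ):
        if h + n + s + f == 0:
            continue
        if n < 1:
            continue
        if s > 0 and h < 1:
            continue
        subs.append(GlycanComposition(h, n, s, f))
    return subs


def enumerate_y_ions(
    candidate: GlycopeptideCandidate, masses: MassTable = MASSES
) -> list[tuple[str, float]]:
    """Glycan Y-ion series: the bare peptide (Y0) plus the peptide carrying
    every rule-satisfying sub-composition of the glycan, deduplicated by
    neutral mass and sorted ascending.  For glycan decoys, every
    glycan-containing ion is shifted by the decoy offset; Y0 is not."""
    pep_mass = peptide_mass(candidate.peptide, masses, candidate.label)
    shift = candidate.glycan_mass_shift if candidate.is_glycan_decoy else 0.0
    ions = [("Y0", pep_mass)]
    for sub in _sub_compositions(candidate.glycan):
        label = f"Y+{sub.hex}.{sub.hexnac}.{sub.neuac}.{sub.fuc}"
        ions.append((label, pep_mass + sub.mass(masses) + shift))
    seen: dict[float, str] = {}
    for label, mass in ions:
        key = round(mass, 6)
        if key not in seen:
            seen[key] = label
    return sorted(((lbl, m) for m, lbl in seen.items()), key=lambda t: t[1])


def enumerate_by_ions(
    pep: PeptideEntry, masses: MassTable = MASSES, label: str = "TMT6"
) -> list[tuple[str, float]]:
    """All b_k and y_k neutral fragment masses for k = 1..len-1.

    Convention: b_k = sum of the first k residues (+ N-terminal label + mods
    on 1..k); y_k = sum of the last k residues + water (+ mods and K labels
    in that range); hence b_k + y_{n-k} equals the neutral peptide mass.
    """
    seq = pep.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("peptide must have length >= 2 for b/y ions")
    mods = pep.mods_at()
    label_mass = masses.labels[label]
    res = [masses.residues[aa] for aa in seq]
    prefix = np.cumsum(res)
    mod_prefix = np.cumsum([mods.get(i + 1, 0.0) for i in range(n)])
    k_label_prefix = np.cumsum([label_mass if aa == "K" else 0.0 for aa in seq])
    total_mods = mod_prefix[-1]
    total_klabel = k_label_prefix[-1]
    out: list[tuple[str, float]] = []
    for k in range(1, n):
        b = prefix[k - 1] + mod_prefix[k - 1] + k_label_prefix[k - 1] + label_mass
        out.append((f"b{k}", float(b)))
    for k in range(1, n):
        # last k residues: indices n-k .. n-1
        y = (
            (prefix[-1] - prefix[n - k - 1])
            + (total_mods - mod_prefix[n - k - 1])
            + (total_klabel - k_label_prefix[n - k - 1])
            + masses.water
        )
        out.append((f"y{k}", float(y)))
    return out


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------


def make_peptide_decoys(peptides: Sequence[PeptideEntry]) -> list[PeptideEntry]:
    """Reverse each target keeping a C-terminal K/R fixed; recompute sequons
    within the decoy sequence; drop decoys colliding with any target."""
    target_seqs = {p.sequence for p in peptides}
    decoys = []
    for pep in peptides:
        seq = pep.sequence
        if seq[-1] in "KR":
            rev = seq[:-1][::-1] + seq[-1]
        else:
            rev = seq[::-1]
        if rev in target_seqs:
            continue
        fixed = tuple(
            (i + 1, MASSES.carbamidomethyl) for i, aa in enumerate(rev) if aa == "C"
        )
        decoy = PeptideEntry(
            sequence=rev,
            protein_accession="DECOY_" + pep.protein_accession,
            start_pos=pep.start_pos,
            missed_cleavages=pep.missed_cleavages,
            fixed_mods=fixed,
            is_decoy=True,
        )
        decoys.append(replace(decoy, sequon_positions=tuple(find_sequons(decoy, None))))
    return decoys


def make_glycan_decoys(
    glycans: Sequence[GlycanComposition], shift: float = GLYCAN_DECOY_SHIFT
) -> list[GlycanEntry]:
    """One decoy per glycan, shifted by a fixed neutral-mass offset."""
    return [GlycanEntry(g, is_decoy=True, mass_shift=shift) for g in glycans]


# ---------------------------------------------------------------------------
# glycan library
# ---------------------------------------------------------------------------


def default_glycan_library(max_total: int = 18) -> list[GlycanComposition]:
    """All compositions with hex 3-12, hexnac 2-7, neuac 0-4, fuc 0-3 whose
    total residue count does not exceed ``max_total``."""
    lib = []
    for h, n, s, f in itertools.product(
        range(3, 13), range(2, 8), range(0, 5), range(0, 4)
    ):
        if h + n + s + f <= max_total:
            lib.append(GlycanComposition(h, n, s, f))
    return sorted(lib)


def read_glycan_library(path: str | Path) -> list[GlycanComposition]:
    df = pd.read_csv(path, sep="\t")
    required = {"hex", "hexnac", "neuac", "fuc"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"glycan library must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return [
        GlycanComposition(int(r.hex), int(r.hexnac), int(r.neuac), int(r.fuc))
        for r in df.itertuples()
    ]


def write_glycan_library(glycans: Iterable[GlycanComposition], path: str | Path) -> None:
    pd.DataFrame(
        [(g.hex, g.hexnac, g.neuac, g.fuc) for g in glycans],
        columns=["hex", "hexnac", "neuac", "fuc"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# candidate generation and the precursor index
# ---------------------------------------------------------------------------


def generate_candidates(
    peptides: Sequence[PeptideEntry],
    glycans: Sequence[GlycanEntry | GlycanComposition],
    masses: MassTable = MASSES,
    label: str = "TMT6",
) -> list[GlycopeptideCandidate]:
    """Cross every sequon-bearing peptide with every glycan entry; one
    candidate per (peptide, site, glycan)."""
    entries = [
        g if isinstance(g, GlycanEntry) else GlycanEntry(g) for g in glycans
    ]
    out: list[GlycopeptideCandidate] = []
    for pep in peptides:
        if not pep.sequon_positions:
            continue
        pmass = peptide_mass(pep, masses, label)
        for site in pep.sequon_positions:
            for entry in entries:
                out.append(
                    GlycopeptideCandidate(
                        peptide=pep,
                        site=site,
                        glycan=entry.composition,
                        is_peptide_decoy=pep.is_decoy,
                        is_glycan_decoy=entry.is_decoy,
                        glycan_mass_shift=entry.mass_shift,
                        label=label,
                        neutral_mass=pmass + entry.mass(masses),
                    )
                )
    return out


class CandidateIndex:
    """Sorted-array precursor-mass index; queries are exact-equivalent to a
    linear scan at the same ppm tolerance."""

    def __init__(self, candidates: Sequence[GlycopeptideCandidate]):
        if not candidates:
            raise ConfigurationError("cannot build an index over zero candidates")
        self.candidates = sorted(candidates, key=lambda c: (c.neutral_mass, c.candidate_id))
        self.masses = np.array([c.neutral_mass for c in self.candidates])

    def __len__(self) -> int:
        return len(self.candidates)

    def query(self, neutral_mass: float, tol_ppm: float) -> list[GlycopeptideCandidate]:
        tol = neutral_mass * tol_ppm * 1e-6
        lo = int(np.searchsorted(self.masses, neutral_mass - tol, side="left"))
        hi = int(np.searchsorted(self.masses, neutral_mass + tol, side="right"))
        return self.candidates[lo:hi]


def build_candidate_index(
    peptides: Sequence[PeptideEntry],
    glycans: Sequence[GlycanEntry | GlycanComposition],
    masses: MassTable = MASSES,
    label: str = "TMT6",
) -> CandidateIndex:
    return CandidateIndex(generate_candidates(peptides, glycans, masses, label))
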