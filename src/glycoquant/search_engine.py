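"""Match pseudo-spectra to glycopeptide candidates, score, control FDR at
peptide and glycan levels, and run the two-step database search.

Scores are binomial surprisals: with n theoretical ions, k matched, and a
chance match probability p-hat estimated from the summed tolerance windows
over the spectrum span, score = -log10 P(Binomial(n, p-hat) >= k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import ConfigurationError
from .glyco_space import (
    CandidateIndex,
    GlycanEntry,
    GlycopeptideCandidate,
    MASSES,
    MassTable,
    Protein,
    enumerate_by_ions,
    enumerate_y_ions,
    generate_candidates,
    make_glycan_decoys,
    make_peptide_decoys,
    oxidation_variants,
    tryptic_digest,
)
from .pseudo_merge import PseudoSpectrum, REPORTER_REGION_MZ

log = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "ScoreSet",
    "GPSM",
    "SearchResult",
    "PRESETS",
    "match_spectrum",
    "pep_score",
    "gly_score",
    "total_score",
    "score_candidate",
    "search_run",
    "estimate_fdr",
    "two_step_search",
    "build_search_space",
    "gpsm_table",
]

_MIN_PHAT = 1e-6
_MAX_SCORE = 300.0


@dataclass(frozen=True)
class SearchConfig:
    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 20.0
    total_fdr: float = 0.02
    w_pep: float = 1.0
    w_gly: float = 1.0
    min_pep_score: float | None = None
    min_gly_score: float | None = None
    charge_range: tuple[int, int] = (2, 6)
    max_oxidation: int = 1

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 < self.total_fdr < 1:
            raise ValueError("total_fdr must lie in (0, 1)")


#: named analysis regimes: score-cutoff filtering vs plain 2% total FDR
PRESETS: dict[str, SearchConfig] = {
    "igm": SearchConfig(min_pep_score=7.0, min_gly_score=8.0),
    "dg75": SearchConfig(total_fdr=0.02),
}


@dataclass(frozen=True)
class ScoreSet:
    pep_score: float
    gly_score: float
    total_score: float
    pep_ion_ratio: float
    gly_ion_ratio: float
    n_matched_by: int
    n_matched_y: int


@dataclass
class GPSM:
    source_ms2: int
    source_ms3: tuple[int, ...]
    candidate: GlycopeptideCandidate
    scores: ScoreSet
    precursor_mz: float
    precursor_charge: int
    mass_delta_ppm: float
    q_value: float = 1.0
    reporters: tuple[float, ...] = ()
    reporter_channels: tuple[str, ...] = ()

    @property
    def decoy_class(self) -> str:
        return self.candidate.decoy_class

    @property
    def is_target(self) -> bool:
        return self.decoy_class == "target"


@dataclass
class SearchResult:
    gpsms: list[GPSM]
    accepted: list[GPSM]
    db_round: int = 1
    round1_accepted: list[GPSM] = field(default_factory=list)
    gained_keys: set = field(default_factory=set)
    lost_keys: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# matching and scoring
# ---------------------------------------------------------------------------


def match_spectrum(
    pseudo: PseudoSpectrum,
    theoretical: Sequence[tuple[str, float]],
    cfg: SearchConfig,
    charges: Sequence[int] = (1,),
) -> dict[str, tuple[int, float]]:
    """Match each theoretical neutral-mass ion (at any of ``charges``) to the
    nearest peak within fragment_tol_ppm.  Reporter-region peaks are never
    used as identification evidence.  Returns {ion label: (peak index, ppm)}.
    """
    mz = pseudo.mz
    lo_idx = int(np.searchsorted(mz, REPORTER_REGION_MZ, side="left"))
    mz = mz[lo_idx:]
    matches: dict[str, tuple[int, float]] = {}
    if mz.size == 0 or not theoretical:
        return matches
    proton = MASSES.proton
    for label, neutral in theoretical:
        best: tuple[int, float] | None = None
        for z in charges:
            target = (neutral + z * proton) / z
            pos = int(np.searchsorted(mz, target))
            for idx in (pos - 1, pos):
                if 0 <= idx < mz.size:
                    ppm = abs(mz[idx] - target) / target * 1e6
                    if ppm <= cfg.fragment_tol_ppm and (best is None or ppm < best[1]):
                        best = (idx + lo_idx, float(ppm))
        if best is not None:
            matches[label] = best
    return matches


def _chance_probability(
    theoretical_mz: np.ndarray, span: float, tol_ppm: float
) -> float:
    """Per-ion chance match probability: summed 2*tol windows over the span."""
    if span <= 0 or theoretical_mz.size == 0:
        return _MIN_PHAT
    total_window = float(np.sum(2.0 * theoretical_mz * tol_ppm * 1e-6))
    p = total_window / span / max(theoretical_mz.size, 1)
    return float(min(max(p, _MIN_PHAT), 0.5))


def _binomial_surprisal(k: int, n: int, p_hat: float) -> float:
    if k <= 0 or n <= 0:
        return 0.0
    tail = float(binom.sf(k - 1, n, p_hat))
    if tail <= 0.0:
        return _MAX_SCORE
    return float(min(-np.log10(tail), _MAX_SCORE))


def pep_score(n_matched: int, n_theoretical: int, p_hat: float) -> float:
    """-log10 binomial tail of matching >= k of n b/y ions by chance."""
    return _binomial_surprisal(n_matched, n_theoretical, p_hat)


def gly_score(n_matched: int, n_theoretical: int, p_hat: float) -> float:
    """Same functional form as pep_score, applied to the Y-ion series."""
    return _binomial_surprisal(n_matched, n_theoretical, p_hat)


def total_score(pep: float, gly: float, cfg: SearchConfig) -> float:
    return cfg.w_pep * pep + cfg.w_gly * gly


def score_candidate(
    pseudo: PseudoSpectrum,
    candidate: GlycopeptideCandidate,
    cfg: SearchConfig,
    masses: MassTable = MASSES,
    ion_cache: dict | None = None,
) -> ScoreSet:
    """Score one candidate against one pseudo-spectrum.

    b/y ions are considered at charges 1..min(z, 2); Y ions (large,
    glycan-bearing) at charges 1..z.
    """
    cid = candidate.candidate_id
    if ion_cache is not None and cid in ion_cache:
        by_ions, y_ions = ion_cache[cid]
    else:
        by_ions = enumerate_by_ions(candidate.peptide, masses, candidate.label)
        y_ions = enumerate_y_ions(candidate, masses)
        if ion_cache is not None:
            ion_cache[cid] = (by_ions, y_ions)
    z = max(candidate_charge := pseudo.precursor_charge, 1)
    by_charges = tuple(range(1, min(z, 2) + 1))
    y_charges = tuple(range(1, z + 1))
    by_matches = match_spectrum(pseudo, by_ions, cfg, by_charges)
    y_matches = match_spectrum(pseudo, y_ions, cfg, y_charges)
    usable = pseudo.mz[pseudo.mz >= REPORTER_REGION_MZ]
    span = float(usable.max() - usable.min()) if usable.size > 1 else 0.0
    proton = masses.proton
    by_mz = np.array([(m + proton) for _, m in by_ions])
    y_mz = np.array([(m + proton) for _, m in y_ions])
    p_by = _chance_probability(by_mz, span, cfg.fragment_tol_ppm) * len(by_charges)
    p_y = _chance_probability(y_mz, span, cfg.fragment_tol_ppm) * len(y_charges)
    p_by = min(p_by, 0.5)
    p_y = min(p_y, 0.5)
    k_by, n_by = len(by_matches), len(by_ions)
    k_y, n_y = len(y_matches), len(y_ions)
    ps = pep_score(k_by, n_by, p_by)
    gs = gly_score(k_y, n_y, p_y)
    return ScoreSet(
        pep_score=ps,
        gly_score=gs,
        total_score=total_score(ps, gs, cfg),
        pep_ion_ratio=k_by / n_by if n_by else 0.0,
        gly_ion_ratio=k_y / n_y if n_y else 0.0,
        n_matched_by=k_by,
        n_matched_y=k_y,
    )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def estimate_fdr(gpsms: list[GPSM]) -> list[GPSM]:
    """Assign q-values from two-level target-decoy counts.

    At each score threshold s: FDR_p = #pep-decoys>=s / #targets>=s,
    FDR_g analogous for glycan decoys ('both' counts toward each), and
    total FDR = FDR_p + FDR_g - FDR_p*FDR_g.  q = reverse running minimum
    over descending score, hence non-increasing in score.
    """
    if not gpsms:
        return gpsms
    order = sorted(
        range(len(gpsms)),
        key=lambda i: (-gpsms[i].scores.total_score, gpsms[i].candidate.candidate_id),
    )
    n = len(order)
    is_pep = np.array(
        [gpsms[i].decoy_class in ("pep_decoy", "both") for i in order], dtype=np.int64
    )
    is_gly = np.array(
        [gpsms[i].decoy_class in ("gly_decoy", "both") for i in order], dtype=np.int64
    )
    is_tgt = np.array([gpsms[i].is_target for i in order], dtype=np.int64)
    cum_pep = np.cumsum(is_pep)
    cum_gly = np.cumsum(is_gly)
    cum_tgt = np.maximum(np.cumsum(is_tgt), 1)
    scores = np.array([gpsms[i].scores.total_score for i in order])
    # ties share the loosest (largest-index) cumulative counts
    fdr = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[j + 1] == scores[i]:
            j += 1
        fp = cum_pep[j] / cum_tgt[j]
        fg = cum_gly[j] / cum_tgt[j]
        fdr[i : j + 1] = fp + fg - fp * fg
        i = j + 1
    qvals = np.minimum.accumulate(fdr[::-1])[::-1]
    for rank, idx in enumerate(order):
        gpsms[idx].q_value = float(min(qvals[rank], 1.0))
    return gpsms


def _passes_cutoffs(g: GPSM, cfg: SearchConfig) -> bool:
    if cfg.min_pep_score is not None and g.scores.pep_score <= cfg.min_pep_score:
        return False
    if cfg.min_gly_score is not None and g.scores.gly_score <= cfg.min_gly_score:
        return False
    return True


def search_run(
    pseudo_list: Sequence[PseudoSpectrum],
    index: CandidateIndex,
    cfg: SearchConfig | None = None,
    masses: MassTable = MASSES,
    db_round: int = 1,
) -> SearchResult:
    """Rank-1 search of every pseudo-spectrum against the candidate index.

    Ties at equal total score break toward smaller precursor mass error,
    then lexicographic candidate id, so results are order-independent.
    """
    cfg = cfg or SearchConfig()
    if len(index) == 0:
        raise ConfigurationError("empty candidate index")
    proton = masses.proton
    ion_cache: dict = {}
    gpsms: list[GPSM] = []
    for pseudo in pseudo_list:
        if pseudo.precursor_mz <= 0:
            continue
        charges = (
            [pseudo.precursor_charge]
            if pseudo.precursor_charge >= 1
            else list(range(cfg.charge_range[0], cfg.charge_range[1] + 1))
        )
        best: tuple[float, float, str, GlycopeptideCandidate, ScoreSet, int] | None = None
        for z in charges:
            neutral = (pseudo.precursor_mz - proton) * z
            for cand in index.query(neutral, cfg.precursor_tol_ppm):
                delta_ppm = abs(neutral - cand.neutral_mass) / cand.neutral_mass * 1e6
                trial = replace(pseudo, precursor_charge=z) if z != pseudo.precursor_charge else pseudo
                scores = score_candidate(trial, cand, cfg, masses, ion_cache)
                key = (-scores.total_score, delta_ppm, cand.candidate_id)
                if best is None or key < (-best[0], best[1], best[2]):
                    best = (scores.total_score, delta_ppm, cand.candidate_id, cand, scores, z)
        if best is None:
            continue
        _, delta_ppm, _, cand, scores, z = best
        gpsms.append(
            GPSM(
                source_ms2=pseudo.source_ms2,
                source_ms3=pseudo.source_ms3,
                candidate=cand,
                scores=scores,
                precursor_mz=pseudo.precursor_mz,
                precursor_charge=z,
                mass_delta_ppm=delta_ppm,
            )
        )
    estimate_fdr(gpsms)
    accepted = [
        g
        for g in gpsms
        if g.is_target and g.q_value <= cfg.total_fdr and _passes_cutoffs(g, cfg)
    ]
    return SearchResult(gpsms=gpsms, accepted=accepted, db_round=db_round)


# ---------------------------------------------------------------------------
# search-space assembly and the two-step search
# ---------------------------------------------------------------------------


def build_search_space(
    proteins: Sequence[Protein],
    glycans: Sequence,
    cfg: SearchConfig,
    masses: MassTable = MASSES,
    label: str = "TMT6",
    max_missed: int = 2,
) -> CandidateIndex:
    """Digest, expand oxidation variants, add both decoy classes, and index
    the four decoy-class combinations (target/decoy peptide x glycan)."""
    peptides: list = []
    for prot in proteins:
        peptides.extend(tryptic_digest(prot, max_missed=max_missed, masses=masses))
    peptides = [p for p in peptides if p.sequon_positions]
    expanded: list = []
    for p in peptides:
        expanded.extend(oxidation_variants(p, masses, cfg.max_oxidation))
    pep_decoys_base = make_peptide_decoys(peptides)
    pep_decoys: list = []
    for p in pep_decoys_base:
        pep_decoys.extend(oxidation_variants(p, masses, cfg.max_oxidation))
    target_glycans = [GlycanEntry(g) if not isinstance(g, GlycanEntry) else g for g in glycans]
    gly_decoys = make_glycan_decoys([g.composition for g in target_glycans])
    candidates = []
    candidates.extend(generate_candidates(expanded, target_glycans, masses, label))
    candidates.extend(generate_candidates(expanded, gly_decoys, masses, label))
    candidates.extend(generate_candidates(pep_decoys, target_glycans, masses, label))
    candidates.extend(generate_candidates(pep_decoys, gly_decoys, masses, label))
    return CandidateIndex(candidates)


def _glycoform_key(g: GPSM) -> tuple[str, int, str]:
    return (
        g.candidate.peptide.protein_accession,
        g.candidate.site_in_protein,
        g.candidate.glycan.to_string(),
    )


def two_step_search(
    pseudo_list: Sequence[PseudoSpectrum],
    proteins: Sequence[Protein],
    glycans: Sequence,
    cfg: SearchConfig | None = None,
    masses: MassTable = MASSES,
    label: str = "TMT6",
) -> SearchResult:
    """Round 1 against the full database; round 2 re-searches every spectrum
    against only the proteins carrying at least one accepted round-1 GPSM.
    The final accepted set is the round-2 set (db_round=2) with a gained/lost
    glycoform report relative to round 1."""
    cfg = cfg or SearchConfig()
    if not proteins:
        raise ConfigurationError("empty protein database")
    index1 = build_search_space(proteins, glycans, cfg, masses, label)
    round1 = search_run(pseudo_list, index1, cfg, masses, db_round=1)
    hit_accessions = {g.candidate.peptide.protein_accession for g in round1.accepted}
    if not hit_accessions:
        log.warning("two-step search: round 1 accepted nothing; final result empty")
        return SearchResult(
            gpsms=round1.gpsms, accepted=[], db_round=2, round1_accepted=round1.accepted
        )
    reduced = [p for p in proteins if p.accession in hit_accessions]
    index2 = build_search_space(reduced, glycans, cfg, masses, label)
    round2 = search_run(pseudo_list, index2, cfg, masses, db_round=2)
    keys1 = {_glycoform_key(g) for g in round1.accepted}
    keys2 = {_glycoform_key(g) for g in round2.accepted}
    round2.round1_accepted = round1.accepted
    round2.gained_keys = keys2 - keys1
    round2.lost_keys = keys1 - keys2
    return round2


def gpsm_table(gpsms: Sequence[GPSM]) -> pd.DataFrame:
    """Flat table of GPSMs; reporter columns appear once quant is attached."""
    rows = []
    for g in gpsms:
        row = {
            "scan": g.source_ms2,
            "peptide": g.candidate.peptide.sequence,
            "protein": g.candidate.peptide.protein_accession,
            "site": g.candidate.site_in_protein,
            "glycan": g.candidate.glycan.to_string(),
            "charge": g.precursor_charge,
            "pep_score": g.scores.pep_score,
            "gly_score": g.scores.gly_score,
            "total_score": g.scores.total_score,
            "pep_ion_ratio": g.scores.pep_ion_ratio,
            "gly_ion_ratio": g.scores.gly_ion_ratio,
            "mass_delta_ppm": g.mass_delta_ppm,
            "q_value": g.q_value,
            "decoy_class": g.decoy_class,
        }
        for ch, val in zip(g.reporter_channels, g.reporters):
            row[f"reporter_{ch}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
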