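"""Oracle-backed tests for the search-space module.

Oracles are deliberately independent implementations: brute-force cleavage
enumeration, naive mass summation, exhaustive sub-composition search, and a
linear index scan.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoquant.errors import AlphabetError, LocationError
from glycoquant.glyco_space import (
    GLYCAN_DECOY_SHIFT,
    CandidateIndex,
    GlycanComposition,
    GlycanEntry,
    MASSES,
    PeptideEntry,
    Protein,
    build_candidate_index,
    default_glycan_library,
    enumerate_by_ions,
    enumerate_y_ions,
    find_sequons,
    generate_candidates,
    make_glycan_decoys,
    make_peptide_decoys,
    oxidation_variants,
    peptide_mass,
    read_fasta,
    read_glycan_library,
    tryptic_digest,
    write_fasta,
    write_glycan_library,
)

from conftest import make_candidate

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_digest(sequence: str, max_missed: int, min_len: int) -> set[str]:
    """Enumerate peptides from all cleavage-site subsets (independent of the
    production implementation)."""
    sites = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    cuts = [0] + sites + [len(sequence)]
    out = set()
    for a_idx in range(len(cuts) - 1):
        for b_idx in range(a_idx + 1, len(cuts)):
            missed = b_idx - a_idx - 1
            pep = sequence[cuts[a_idx] : cuts[b_idx]]
            if missed <= max_missed and len(pep) >= min_len:
                out.add(pep)
    return out


def naive_mass(sequence: str, n_label: int, cam_count: int, ox_count: int = 0) -> float:
    total = sum(MASSES.residues[a] for a in sequence) + MASSES.water
    total += MASSES.labels["TMT6"] * n_label
    total += MASSES.carbamidomethyl * cam_count
    total += MASSES.oxidation * ox_count
    return total


def exhaustive_y_subcompositions(g: GlycanComposition) -> set[tuple[int, int, int, int]]:
    out = set()
    for h, n, s, f in itertools.product(
        range(g.hex + 1), range(g.hexnac + 1), range(g.neuac + 1), range(g.fuc + 1)
    ):
        if h + n + s + f == 0:
            continue
        if n < 1:
            continue
        if s > 0 and h < 1:
            continue
        out.add((h, n, s, f))
    return out


def random_protein(rng, length: int) -> Protein:
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    return Protein("RND", seq)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


class TestDigest:
    def test_worked_example(self):
        peps = tryptic_digest(Protein("P", "MKANSTRPK"), max_missed=1, min_len=2)
        assert {p.sequence for p in peps} == {"MK", "ANSTRPK", "MKANSTRPK"}

    def test_no_cleavage_sites(self):
        peps = tryptic_digest(Protein("P", "AAAAGGGG"), max_missed=2, min_len=4)
        assert [p.sequence for p in peps] == ["AAAAGGGG"]
        assert peps[0].missed_cleavages == 0

    def test_zero_missed_concatenation_reconstructs_protein(self):
        rng = np.random.default_rng(1)
        prot = random_protein(rng, 200)
        peps = [
            p for p in tryptic_digest(prot, max_missed=2, min_len=1) if p.missed_cleavages == 0
        ]
        peps.sort(key=lambda p: p.start_pos)
        assert "".join(p.sequence for p in peps) == prot.sequence

    def test_matches_brute_force_on_50_random_proteins(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            prot = random_protein(rng, int(rng.integers(20, 120)))
            got = {p.sequence for p in tryptic_digest(prot, max_missed=2, min_len=4)}
            assert got == brute_force_digest(prot.sequence, 2, 4)

    def test_start_positions_locate_peptides(self):
        rng = np.random.default_rng(5)
        prot = random_protein(rng, 150)
        for pep in tryptic_digest(prot, max_missed=2, min_len=4):
            start = pep.start_pos - 1
            assert prot.sequence[start : start + len(pep.sequence)] == pep.sequence


class TestSequons:
    def _entry(self, seq, start=1, acc="P"):
        return PeptideEntry(seq, acc, start, 0)

    def test_basic_motif(self):
        assert find_sequons(self._entry("ANSTRPK")) == [2]

    def test_proline_blocks(self):
        assert find_sequons(self._entry("ANPTK")) == []

    def test_boundary_sequon_via_protein_context(self):
        prot = Protein("P", "AAANGTKLLL")
        # peptide "AAAN" ends at the N; S/T only visible in the protein
        pep = PeptideEntry("AAAN", "P", 1, 0)
        assert find_sequons(pep, prot) == [4]

    def test_peptide_not_in_protein_raises(self):
        prot = Protein("P", "AAANGTKLLL")
        with pytest.raises(LocationError):
            find_sequons(PeptideEntry("WWWW", "P", 1, 0), prot)

    def test_nxs_and_nxt_both_match(self):
        assert find_sequons(self._entry("ANGSAANGTA")) == [2, 7]


# ---------------------------------------------------------------------------
# masses
# ---------------------------------------------------------------------------


class TestPeptideMass:
    def test_ack_tmt6_example(self):
        pep = PeptideEntry(
            "ACK", "P", 1, 0, fixed_mods=((2, MASSES.carbamidomethyl),)
        )
        # oracle: 71.03711 + 160.03065 + 128.09496 + 18.01056 + 2*229.16293
        assert peptide_mass(pep, MASSES, "TMT6") == pytest.approx(835.49914, abs=1e-6)
        assert peptide_mass(pep, MASSES, "TMT6") == pytest.approx(
            naive_mass("ACK", 2, 1), abs=1e-9
        )

    def test_single_glycine_no_label(self):
        pep = PeptideEntry("G", "P", 1, 0)
        assert peptide_mass(pep, MASSES, "none") == pytest.approx(75.03202, abs=1e-6)

    def test_oxidation_shift(self):
        pep = PeptideEntry("AMK", "P", 1, 0)
        ox = PeptideEntry("AMK", "P", 1, 0, variable_mods=((2, MASSES.oxidation),))
        delta = peptide_mass(ox, MASSES, "TMT6") - peptide_mass(pep, MASSES, "TMT6")
        assert delta == pytest.approx(15.99492, abs=1e-9)

    def test_unknown_residue(self):
        with pytest.raises(AlphabetError):
            peptide_mass(PeptideEntry("AXK", "P", 1, 0), MASSES, "none")

    @settings(max_examples=30, deadline=None)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25))
    def test_matches_summation_oracle(self, seq):
        cam = seq.count("C")
        pep = PeptideEntry(
            seq, "P", 1, 0,
            fixed_mods=tuple((i + 1, MASSES.carbamidomethyl) for i, a in enumerate(seq) if a == "C"),
        )
        assert peptide_mass(pep, MASSES, "TMT6") == pytest.approx(
            naive_mass(seq, 1 + seq.count("K"), cam), abs=1e-6
        )

    def test_oxidation_variants_counts(self):
        pep = PeptideEntry("AMGMK", "P", 1, 0)
        variants = oxidation_variants(pep, MASSES, max_ox=2)
        # unmodified + 2 singles + 1 double
        assert len(variants) == 4


# ---------------------------------------------------------------------------
# fragment series
# ---------------------------------------------------------------------------


class TestYIons:
    def test_single_hexnac(self):
        cand = make_candidate(glycan=GlycanComposition(0, 1, 0, 0))
        ions = enumerate_y_ions(cand)
        assert len(ions) == 2  # Y0 and Y0+HexNAc
        pep = peptide_mass(cand.peptide, MASSES, cand.label)
        assert ions[0][1] == pytest.approx(pep)
        assert ions[1][1] == pytest.approx(pep + MASSES.monosaccharides["hexnac"])

    def test_count_matches_exhaustive_enumeration(self):
        g = GlycanComposition(1, 2, 0, 1)
        cand = make_candidate(glycan=g)
        ions = enumerate_y_ions(cand)
        assert len(ions) == len(exhaustive_y_subcompositions(g)) + 1

    def test_masses_match_sum_oracle(self):
        g = GlycanComposition(2, 2, 1, 1)
        cand = make_candidate(glycan=g)
        pep = peptide_mass(cand.peptide, MASSES, cand.label)
        expected = {round(pep, 6)}
        for h, n, s, f in exhaustive_y_subcompositions(g):
            expected.add(round(pep + GlycanComposition(h, n, s, f).mass(MASSES), 6))
        got = {round(m, 6) for _, m in enumerate_y_ions(cand)}
        assert got == expected

    def test_sorted_by_mass(self):
        cand = make_candidate(glycan=GlycanComposition(3, 2, 1, 1))
        masses = [m for _, m in enumerate_y_ions(cand)]
        assert masses == sorted(masses)


class TestBYIons:
    def test_two_residues(self):
        pep = PeptideEntry("AG", "P", 1, 0)
        ions = enumerate_by_ions(pep, MASSES, "none")
        assert len(ions) == 2
        labels = {l for l, _ in ions}
        assert labels == {"b1", "y1"}

    def test_additivity_on_random_peptides(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(2, 20))))
            pep = PeptideEntry(
                seq, "P", 1, 0,
                fixed_mods=tuple((i + 1, MASSES.carbamidomethyl) for i, a in enumerate(seq) if a == "C"),
            )
            total = peptide_mass(pep, MASSES, "TMT6")
            ions = dict(enumerate_by_ions(pep, MASSES, "TMT6"))
            n = len(seq)
            for k in range(1, n):
                assert ions[f"b{k}"] + ions[f"y{n-k}"] == pytest.approx(total, abs=1e-6)

    def test_label_position_on_lysine_y1(self):
        pep = PeptideEntry("ACK", "P", 1, 0, fixed_mods=((2, MASSES.carbamidomethyl),))
        ions = dict(enumerate_by_ions(pep, MASSES, "TMT6"))
        # y1 = K + water + one TMT label
        assert ions["y1"] == pytest.approx(
            MASSES.residues["K"] + MASSES.water + MASSES.labels["TMT6"], abs=1e-9
        )
        # b1 = A + N-terminal label
        assert ions["b1"] == pytest.approx(
            MASSES.residues["A"] + MASSES.labels["TMT6"], abs=1e-9
        )


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------


class TestDecoys:
    def test_reversal_keeps_cterm(self):
        pep = PeptideEntry("ANSTK", "P", 1, 0, sequon_positions=(2,))
        decoys = make_peptide_decoys([pep])
        assert decoys[0].sequence == "TSNAK"
        assert decoys[0].is_decoy

    def test_palindrome_dropped(self):
        pep = PeptideEntry("AGA", "P", 1, 0)
        assert make_peptide_decoys([pep]) == []

    def test_decoy_mass_equals_target(self):
        pep = PeptideEntry("ANSTGLK", "P", 1, 0, sequon_positions=(2,))
        decoy = make_peptide_decoys([pep])[0]
        assert peptide_mass(decoy, MASSES, "TMT6") == pytest.approx(
            peptide_mass(pep, MASSES, "TMT6"), abs=1e-9
        )

    def test_glycan_decoy_shift(self):
        glycans = [GlycanComposition(3, 2, 0, 0), GlycanComposition(5, 2, 1, 0)]
        decoys = make_glycan_decoys(glycans)
        for g, d in zip(glycans, decoys):
            assert d.mass() - g.mass() == pytest.approx(GLYCAN_DECOY_SHIFT)
            assert d.is_decoy

    def test_decoy_y0_not_shifted_and_counts_match(self):
        g = GlycanComposition(2, 2, 0, 1)
        target = make_candidate(glycan=g)
        from dataclasses import replace

        decoy = replace(target, is_glycan_decoy=True, glycan_mass_shift=GLYCAN_DECOY_SHIFT)
        t_ions = enumerate_y_ions(target)
        d_ions = enumerate_y_ions(decoy)
        assert len(t_ions) == len(d_ions)
        pep = peptide_mass(target.peptide, MASSES, target.label)
        assert d_ions[0][1] == pytest.approx(pep)  # Y0 unshifted
        for (_, tm), (_, dm) in zip(t_ions[1:], d_ions[1:]):
            assert dm - tm == pytest.approx(GLYCAN_DECOY_SHIFT, abs=1e-9)


# ---------------------------------------------------------------------------
# candidate index
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def index():
    rng = np.random.default_rng(33)
    prots = []
    for i in range(4):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        prots.append(Protein(f"P{i}", seq))
    peptides = []
    for prot in prots:
        peptides.extend(tryptic_digest(prot, max_missed=1, min_len=5))
    peptides = [p for p in peptides if p.sequon_positions]
    glycans = [GlycanComposition(3, 2, 0, 0), GlycanComposition(4, 2, 0, 1)]
    if not peptides:
        pytest.skip("random pool produced no sequon peptides")
    return build_candidate_index(peptides, glycans)


class TestCandidateIndex:

    def test_query_far_from_all_is_empty(self, index):
        assert index.query(1.0, 10.0) == []

    def test_query_at_candidate_mass_hits(self, index):
        cand = index.candidates[0]
        assert cand in index.query(cand.neutral_mass, 10.0)

    def test_equivalent_to_linear_scan(self, index):
        rng = np.random.default_rng(7)
        lo, hi = index.masses.min() * 0.99, index.masses.max() * 1.01
        for _ in range(1000):
            q = float(rng.uniform(lo, hi))
            tol = float(rng.choice([1.0, 10.0, 50.0]))
            got = {c.candidate_id for c in index.query(q, tol)}
            oracle = {
                c.candidate_id
                for c in index.candidates
                if abs(q - c.neutral_mass) / q <= tol * 1e-6
            }
            assert got == oracle

    def test_candidate_neutral_mass_consistency(self, index):
        for cand in index.candidates[:50]:
            expected = peptide_mass(cand.peptide, MASSES, cand.label) + cand.glycan.mass(
                MASSES
            ) + cand.glycan_mass_shift
            assert cand.neutral_mass == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# libraries and I/O
# ---------------------------------------------------------------------------


class TestLibraries:
    def test_default_library_bounds(self):
        lib = default_glycan_library()
        assert lib
        for g in lib:
            assert 3 <= g.hex <= 12 and 2 <= g.hexnac <= 7
            assert 0 <= g.neuac <= 4 and 0 <= g.fuc <= 3
            assert g.total <= 18

    def test_library_roundtrip(self, tmp_path):
        lib = default_glycan_library()[:25]
        path = tmp_path / "glycans.tsv"
        write_glycan_library(lib, path)
        assert read_glycan_library(path) == lib

    def test_fasta_roundtrip(self, tmp_path):
        prots = [Protein("sp|Q1|TEST", "MKANSTRPK" * 10), Protein("P2", "AAAGGGK")]
        path = tmp_path / "db.fasta"
        write_fasta(prots, path)
        back = read_fasta(path)
        assert back == prots

    def test_glycan_string_roundtrip(self):
        g = GlycanComposition(5, 4, 2, 1)
        assert GlycanComposition.from_string(g.to_string()) == g
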