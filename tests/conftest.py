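"""Shared fixtures and spectrum-construction helpers."""

from __future__ import annotations

import base64

import numpy as np
import pytest

from glycoquant.glyco_space import (
    GlycopeptideCandidate,
    MASSES,
    PeptideEntry,
    Protein,
    enumerate_by_ions,
    enumerate_y_ions,
    peptide_mass,
)
from glycoquant.pseudo_merge import PseudoSpectrum
from glycoquant.scan_model import ScanHierarchy, Spectrum, SpectrumHeader


def make_spectrum(
    scan: int,
    ms_level: int,
    mz,
    intensity,
    precursor_mz=None,
    charge=0,
    parent=None,
    sps=(),
    rt=0.0,
) -> Spectrum:
    return Spectrum(
        SpectrumHeader(
            scan_number=scan,
            ms_level=ms_level,
            retention_time=rt,
            precursor_mz=precursor_mz,
            precursor_charge=charge,
            parent_scan=parent,
            sps_mz_list=tuple(sps),
        ),
        mz,
        intensity,
    )


@pytest.fixture
def tiny_run() -> ScanHierarchy:
    """MS1(1) -> MS2(2) -> MS3(3,4); plus an orphan MS2(5)."""
    run = ScanHierarchy()
    run.add(make_spectrum(1, 1, [500.0, 500.5, 501.0], [80.0, 100.0, 60.0]))
    run.add(make_spectrum(2, 2, [300.0, 800.0], [10.0, 20.0], precursor_mz=500.0, charge=2, parent=1))
    run.add(make_spectrum(3, 3, [126.12773, 400.0], [5.0, 7.0], precursor_mz=500.0, charge=2, parent=2, sps=[800.0]))
    run.add(make_spectrum(4, 3, [200.0], [3.0], precursor_mz=500.0, charge=2, parent=2, sps=[800.0]))
    run.add(make_spectrum(5, 2, [350.0], [4.0], precursor_mz=600.0, charge=2, parent=1))
    run.validate()
    return run


def make_candidate(
    sequence: str = "AANGSVLK",
    site: int = 3,
    glycan=None,
    label: str = "TMT6",
    accession: str = "PROT1",
    start_pos: int = 1,
) -> GlycopeptideCandidate:
    from glycoquant.glyco_space import GlycanComposition

    glycan = glycan or GlycanComposition(3, 2, 0, 0)
    pep = PeptideEntry(
        sequence=sequence,
        protein_accession=accession,
        start_pos=start_pos,
        missed_cleavages=0,
        sequon_positions=(site,),
        fixed_mods=tuple(
            (i + 1, MASSES.carbamidomethyl) for i, aa in enumerate(sequence) if aa == "C"
        ),
    )
    return GlycopeptideCandidate(
        peptide=pep,
        site=site,
        glycan=glycan,
        label=label,
        neutral_mass=peptide_mass(pep, MASSES, label) + glycan.mass(MASSES),
    )


def spectrum_from_candidate(
    candidate: GlycopeptideCandidate,
    scan: int = 10,
    charge: int = 2,
    y_fraction: float = 1.0,
    by_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
    noise_peaks: int = 0,
) -> PseudoSpectrum:
    """Noise-free pseudo-spectrum containing a deterministic subset of the
    candidate's theoretical fragments at exact m/z."""
    rng = rng or np.random.default_rng(0)
    proton = MASSES.proton
    y_ions = enumerate_y_ions(candidate, MASSES)
    by_ions = enumerate_by_ions(candidate.peptide, MASSES, candidate.label)
    mzs, ints = [], []
    n_y = max(1, int(round(y_fraction * len(y_ions))))
    n_by = int(round(by_fraction * len(by_ions)))
    for label, neutral in y_ions[:n_y]:
        mzs.append((neutral + proton))
        ints.append(1000.0)
    for label, neutral in by_ions[:n_by]:
        mzs.append(neutral + proton)
        ints.append(500.0)
    for _ in range(noise_peaks):
        mzs.append(float(rng.uniform(200, 1900)))
        ints.append(float(rng.uniform(10, 100)))
    order = np.argsort(mzs)
    mz_arr = np.asarray(mzs, dtype=float)[order]
    int_arr = np.asarray(ints, dtype=float)[order]
    return PseudoSpectrum(
        precursor_mz=candidate.neutral_mass / charge + proton,
        precursor_charge=charge,
        source_ms2=scan,
        source_ms3=(scan + 1,),
        mz=mz_arr,
        intensity=int_arr,
        merged_flag=True,
    )


# ---------------------------------------------------------------------------
# minimal mzML fixture content
# ---------------------------------------------------------------------------


def _b64(arr) -> str:
    return base64.b64encode(np.asarray(arr, dtype=np.float64).tobytes()).decode()


def _binary_block(mz, intensity) -> str:
    return f"""
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="0">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
          <binary>{_b64(mz)}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="0">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
          <binary>{_b64(intensity)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>"""


def make_mzml_text() -> str:
    """Three-scan mzML: MS1(1), MS2(2, prec 500 z2), MS3(3, two notches)."""
    ms1 = _binary_block([499.0, 500.0, 501.0], [50.0, 100.0, 30.0])
    ms2 = _binary_block([300.0, 800.0, 900.0], [10.0, 40.0, 20.0])
    ms3 = _binary_block([126.12773, 250.0], [500.0, 60.0])
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r1">
    <spectrumList count="3">
      <spectrum index="0" id="controllerType=0 controllerNumber=1 scan=1" defaultArrayLength="3">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="0.5" unitName="minute"/>
        </scan></scanList>{ms1}
      </spectrum>
      <spectrum index="1" id="controllerType=0 controllerNumber=1 scan=2" defaultArrayLength="3">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="31.0" unitName="second"/>
        </scan></scanList>
        <precursorList count="1">
          <precursor spectrumRef="controllerType=0 controllerNumber=1 scan=1">
            <isolationWindow>
              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="500.0"/>
              <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="0.8"/>
              <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="0.8"/>
            </isolationWindow>
            <selectedIonList count="1"><selectedIon>
              <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="500.0"/>
              <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="2"/>
            </selectedIon></selectedIonList>
          </precursor>
        </precursorList>{ms2}
      </spectrum>
      <spectrum index="2" id="controllerType=0 controllerNumber=1 scan=3" defaultArrayLength="2">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="3"/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="31.5" unitName="second"/>
        </scan></scanList>
        <precursorList count="2">
          <precursor spectrumRef="controllerType=0 controllerNumber=1 scan=2">
            <isolationWindow>
              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="800.0"/>
            </isolationWindow>
          </precursor>
          <precursor spectrumRef="controllerType=0 controllerNumber=1 scan=2">
            <isolationWindow>
              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="900.0"/>
            </isolationWindow>
          </precursor>
        </precursorList>{ms3}
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""
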