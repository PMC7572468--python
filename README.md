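# glycoquant

Identification and multiplexed isobaric-tag (TMT) quantification of intact
N-glycopeptides from multi-notch MS3 acquisitions, plus a synthetic
acquisition simulator that makes every stage testable at desk scale.

The pipeline merges the MS2 and MS3 fragment ions recorded for one precursor
into a single pseudo-spectrum (1 ppm default tolerance), re-assigns the
monoisotopic precursor from the MS1 isotope envelope, searches the merged
spectra against a glycopeptide space (tryptic peptides x glycan composition
library) with target-decoy FDR control at both the peptide and the glycan
level (2% total FDR default, combined as `FDRp + FDRg - FDRp*FDRg`), runs an
optional two-step database search (round 2 restricted to round-1
glycoproteins), extracts 6-plex reporter intensities from the linked MS3
scans, and propagates quantification from glycopeptide-spectrum matches
(GPSMs) to unique glycoforms (protein-site-glycan), glycosites, and glycan
compositions, with proteome-median ratio normalization and |Z| > 2
regulation calls.

## Layout

| module | role |
| --- | --- |
| `glycoquant.scan_model` | spectra, MS2/MS3 scan hierarchy, MGF dialect + minimal mzML reader, link table, TIC normalization |
| `glycoquant.pseudo_merge` | MS2+MS3 merging into pseudo-spectra, monoisotopic precursor correction |
| `glycoquant.glyco_space` | digestion, sequons, masses, glycan library, b/y and Y ion series, decoys, precursor index |
| `glycoquant.search_engine` | matching, binomial-surprisal scores, two-level FDR, two-step search |
| `glycoquant.quant_engine` | reporter extraction, glycoform/glycosite/glycan propagation, normalization, Z-scores |
| `glycoquant.sps_simulator` | synthetic runs with ground truth, notch selection, co-isolation interference mixture |
| `glycoquant.cli` / `glycoquant.pipeline` | `glycoquant` command-line tool and YAML-configured orchestration |

## CLI

```bash
# synthetic run (or --preset igm_yeast for the interference mixture)
glycoquant simulate --seed 1 --n-glycopeptides 50 --out sim/

# stage by stage
glycoquant merge  --input sim/simulated_run.mgf --out pseudo.mgf --merge-tol-ppm 1
glycoquant search --input sim/simulated_run.mgf --fasta db.fasta --fdr 0.02 --out gpsms.tsv
glycoquant quant  --run sim/simulated_run.mgf --gpsms gpsms.tsv --out-prefix quant
glycoquant report --glycoforms quant.glycoforms.tsv --proteome-ratios proteome.tsv \
                  --condition-channels 130,131 --out report.tsv

# or everything from a YAML config (presets: igm = score cutoffs, dg75 = 2% FDR)
glycoquant run --config pipeline.yaml --seed 1
```

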