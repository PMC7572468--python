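"""Pipeline orchestration: validated YAML configuration and the staged run
(read -> merge -> correct -> search -> quant -> propagate -> normalize ->
regulate), each stage writing its TSV artifact plus a run log."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError
from .glyco_space import default_glycan_library, read_fasta, read_glycan_library
from .pseudo_merge import MergeConfig, build_pseudo_spectra, merge_report
from .quant_engine import (
    TMT6_CHANNELS,
    attach_quant,
    call_regulation,
    compute_ratios,
    normalize_ratios,
    propagate,
)
from .scan_model import read_run, write_link_table, write_mgf
from .search_engine import PRESETS, SearchConfig, gpsm_table, search_run, two_step_search
from .search_engine import build_search_space
from .sps_simulator import SimConfig, export_ground_truth, simulate_run

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_MERGE_KEYS = {"merge_tol_ppm", "combine_rule", "isotope_search_range", "envelope_tol_ppm"}
_SEARCH_KEYS = {
    "precursor_tol_ppm",
    "fragment_tol_ppm",
    "total_fdr",
    "w_pep",
    "w_gly",
    "min_pep_score",
    "min_gly_score",
    "charge_range",
    "max_oxidation",
}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_TOP_KEYS = {
    "preset",
    "seed",
    "input",
    "fasta",
    "glycan_library",
    "output_dir",
    "reference_channel",
    "condition_channels",
    "proteome_ratios",
    "two_step",
    "reporter_tol",
    "merge",
    "search",
    "quant",
    "simulate",
}


@dataclass
class PipelineConfig:
    output_dir: str = "glycoquant_out"
    input: str | None = None  # mzML/MGF path; None -> simulate
    fasta: str | None = None
    glycan_library: str | None = None
    preset: str | None = None
    seed: int = 0
    reference_channel: str = "129"
    condition_channels: list[str] = field(default_factory=list)
    proteome_ratios: str | None = None
    two_step: bool = True
    reporter_tol: float = 0.003
    merge: MergeConfig = field(default_factory=MergeConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    simulate: SimConfig | None = None


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {where} config keys: {sorted(unknown)}")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Parse a YAML pipeline config, rejecting unknown keys; keyword
    overrides (e.g. total_fdr, merge_tol_ppm, seed) win over the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top-level")
    merge_raw = dict(raw.get("merge") or {})
    _check_keys(merge_raw, _MERGE_KEYS, "merge")
    if "isotope_search_range" in merge_raw:
        merge_raw["isotope_search_range"] = tuple(merge_raw["isotope_search_range"])
    search_raw = dict(raw.get("search") or {})
    _check_keys(search_raw, _SEARCH_KEYS, "search")
    if "charge_range" in search_raw:
        search_raw["charge_range"] = tuple(search_raw["charge_range"])
    preset = raw.get("preset")
    base_search = PRESETS[preset] if preset in PRESETS else SearchConfig()
    search_cfg = dataclasses.replace(base_search, **search_raw)
    sim_raw = raw.get("simulate")
    sim_cfg = None
    if sim_raw is not None:
        sim_raw = dict(sim_raw)
        _check_keys(sim_raw, _SIM_KEYS, "simulate")
        for key in ("channel_design", "contaminant_design", "charges", "sps_window"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim_cfg = SimConfig(**sim_raw)
    quant_raw = dict(raw.get("quant") or {})
    _check_keys(quant_raw, {"reporter_tol"}, "quant")
    cfg = PipelineConfig(
        output_dir=raw.get("output_dir", "glycoquant_out"),
        input=raw.get("input"),
        fasta=raw.get("fasta"),
        glycan_library=raw.get("glycan_library"),
        preset=preset,
        seed=int(raw.get("seed", 0)),
        reference_channel=str(raw.get("reference_channel", "129")),
        condition_channels=[str(c) for c in raw.get("condition_channels", [])],
        proteome_ratios=raw.get("proteome_ratios"),
        two_step=bool(raw.get("two_step", True)),
        reporter_tol=float(quant_raw.get("reporter_tol", raw.get("reporter_tol", 0.003))),
        merge=MergeConfig(**merge_raw),
        search=search_cfg,
        simulate=sim_cfg,
    )
    if "total_fdr" in overrides and overrides["total_fdr"] is not None:
        cfg.search = dataclasses.replace(cfg.search, total_fdr=overrides["total_fdr"])
    if "merge_tol_ppm" in overrides and overrides["merge_tol_ppm"] is not None:
        cfg.merge = dataclasses.replace(cfg.merge, merge_tol_ppm=overrides["merge_tol_ppm"])
    if overrides.get("seed") is not None:
        cfg.seed = int(overrides["seed"])
        if cfg.simulate is not None:
            cfg.simulate = dataclasses.replace(cfg.simulate, seed=cfg.seed)
    if overrides.get("preset"):
        name = overrides["preset"]
        if name not in PRESETS:
            raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        cfg.preset = name
        cfg.search = PRESETS[name]
    return cfg


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; every stage writes its artifact under output_dir.
    Returns the output directory.  Deterministic given config + seed."""
    out = Path(cfg.output_dir)
    # validate before writing anything
    if cfg.input is not None and not Path(cfg.input).exists():
        raise ConfigurationError(f"input file not found: {cfg.input}")
    if cfg.input is not None and cfg.fasta is None:
        raise ConfigurationError("a FASTA database is required when searching file input")
    if cfg.fasta is not None and not Path(cfg.fasta).exists():
        raise ConfigurationError(f"FASTA database not found: {cfg.fasta}")
    if cfg.glycan_library is not None and not Path(cfg.glycan_library).exists():
        raise ConfigurationError(f"glycan library not found: {cfg.glycan_library}")
    if cfg.proteome_ratios is not None and not Path(cfg.proteome_ratios).exists():
        raise ConfigurationError(f"proteome ratio table not found: {cfg.proteome_ratios}")
    if cfg.input is None and cfg.simulate is None:
        raise ConfigurationError("either an input file or a simulate block is required")

    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def _stage(name: str, start: float, **counts):
        stages.append({"stage": name, "seconds": round(time.perf_counter() - start, 3), **counts})

    # --- read / simulate
    t0 = time.perf_counter()
    sim_glycans = None
    if cfg.input is not None:
        run = read_run(cfg.input)
        proteins = read_fasta(cfg.fasta)
    else:
        sim = dataclasses.replace(cfg.simulate, seed=cfg.simulate.seed or cfg.seed)
        run, truth = simulate_run(sim)
        export_ground_truth(truth, out / "ground_truth.tsv")
        write_mgf(run, out / "simulated_run.mgf")
        from .sps_simulator import default_sim_glycans, generate_proteins  # noqa: F401
        import numpy as np

        if sim.proteins:
            proteins = list(sim.proteins)
        else:
            proteins = generate_proteins(
                np.random.default_rng(sim.seed), sim.n_proteins, sim.blocks_per_protein
            )
        sim_glycans = list(sim.glycans) if sim.glycans else default_sim_glycans()
    write_link_table(run, out / "scan_link_table.tsv")
    _stage("read", t0, n_spectra=len(run.spectra))

    # --- merge + precursor correction
    t0 = time.perf_counter()
    pseudo = build_pseudo_spectra(run, cfg.merge)
    write_mgf(pseudo, out / "pseudo_spectra.mgf")
    merge_report(run, pseudo).to_csv(out / "merge_report.tsv", sep="\t", index=False)
    _stage("merge", t0, n_pseudo=len(pseudo))

    # --- search
    t0 = time.perf_counter()
    if cfg.glycan_library is not None:
        glycans = read_glycan_library(cfg.glycan_library)
    elif sim_glycans is not None:
        glycans = sim_glycans
    else:
        glycans = default_glycan_library()
    if cfg.two_step:
        result = two_step_search(pseudo, proteins, glycans, cfg.search)
    else:
        index = build_search_space(proteins, glycans, cfg.search)
        result = search_run(pseudo, index, cfg.search)
    _stage("search", t0, n_gpsms=len(result.gpsms), n_accepted=len(result.accepted))

    # --- quantification
    t0 = time.perf_counter()
    attach_quant(result.accepted, run, TMT6_CHANNELS, cfg.reporter_tol)
    gpsm_table(result.accepted).to_csv(out / "gpsms.tsv", sep="\t", index=False)
    glycoform, glycosite, glycan = propagate(result.accepted)
    _stage("quant", t0, n_glycoforms=len(glycoform))

    # --- ratios, normalization, regulation
    t0 = time.perf_counter()
    if len(glycoform):
        glycoform = compute_ratios(glycoform, cfg.reference_channel)
        if cfg.proteome_ratios is not None:
            ref_table = pd.read_csv(cfg.proteome_ratios, sep="\t")
            glycoform = normalize_ratios(glycoform, ref_table, cfg.reference_channel)
            if cfg.condition_channels:
                glycoform = call_regulation(glycoform, cfg.condition_channels)
    glycoform.to_csv(out / "glycoforms.tsv", sep="\t", index=False)
    glycosite.to_csv(out / "glycosites.tsv", sep="\t", index=False)
    glycan.to_csv(out / "glycans.tsv", sep="\t", index=False)
    _stage("report", t0, n_glycosites=len(glycosite), n_glycans=len(glycan))

    log_payload = {
        "seed": cfg.seed,
        "preset": cfg.preset,
        "merge": dataclasses.asdict(cfg.merge),
        "search": dataclasses.asdict(cfg.search),
        "stages": stages,
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log_payload, sort_keys=False))
    return out
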