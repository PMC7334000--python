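"""Pipeline orchestration: fixed stage order with a reproducible manifest.

Stage order follows the analysis flow: digest -> count -> profile ->
interaction calling -> differential -> allelic.  All intermediates are
plain-text (BED/bedGraph/TSV/VCF) so every stage is diffable.  A run
manifest (config snapshot, input digests, version, per-stage timings,
output paths) is written atomically at the end of each run; deterministic
stages reproduce identical output digests on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import fields
from pathlib import Path

import yaml

from . import __version__
from .allelic import (read_allelic_counts_tsv, read_pedigree_yaml,
                      read_trio_vcf, region_bias_report, phase_snps,
                      select_informative, write_allelic_counts_tsv,
                      write_bias_report_tsv)
from .calling import (call_interactions, fit_distance_decay, segment_domains,
                      write_calls_bed, write_calls_tsv, write_domains_bed)
from .config import AnalysisConfig
from .counts import (CountMatrix, LibraryInfo, count_reads, filter_min_count,
                     read_counts_tsv, read_reads_tsv, replicate_correlation,
                     write_counts_tsv)
from .differential import (differential_fragments, write_differential_tsv,
                           write_regions_bed)
from .fragment_map import (digest, locate_viewpoint, read_fasta,
                           read_fragments_bed, write_fragments_bed)
from .profiles import (average_replicates, normalize_rpm, smooth_running_mean,
                       write_bedgraph)
from .simulate import (SimConfig, reads_from_counts, simulate_4c_counts,
                       simulate_allelic_counts, simulate_genome,
                       simulate_trio, write_fasta, write_reads_tsv,
                       write_trio_vcf, write_truth_tsv)

logger = logging.getLogger(__name__)

ALL_STAGES = ("digest", "count", "profile", "call", "diff", "allelic")


class ConfigError(ValueError):
    """Config schema violation; carries the offending field path."""

    def __init__(self, field_path: str, message: str):
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}")


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_run_config(cfg)
    return cfg


def validate_run_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("<root>", "config must be a mapping")
    known = {"analysis", "simulate", "inputs", "stages", "viewpoint",
             "conditions", "reference_condition"}
    for key in cfg:
        if key not in known:
            raise ConfigError(key, "unknown section")
    try:
        AnalysisConfig.from_dict(cfg.get("analysis", {}) or {})
    except (ValueError, TypeError) as e:
        raise ConfigError("analysis", str(e)) from e
    if "simulate" in cfg and cfg["simulate"] is not None:
        sim = cfg["simulate"]
        sim_fields = {f.name for f in fields(SimConfig)}
        for key in sim:
            if key not in sim_fields:
                raise ConfigError(f"simulate.{key}", "unknown field")
        try:
            SimConfig(**{k: v for k, v in sim.items()})
        except (ValueError, TypeError) as e:
            raise ConfigError("simulate", str(e)) from e
    stages = cfg.get("stages", list(ALL_STAGES))
    for s in stages:
        if s not in ALL_STAGES:
            raise ConfigError(f"stages.{s}", f"unknown stage (valid: {ALL_STAGES})")
    if "simulate" not in cfg:
        inputs = cfg.get("inputs")
        if not isinstance(inputs, dict):
            raise ConfigError("inputs", "required when 'simulate' is absent")
        if "viewpoint" not in cfg:
            raise ConfigError("viewpoint", "required (name, chrom, position)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Execute the requested stages and return the run manifest.

    Missing input files raise FileNotFoundError; config schema violations
    raise ConfigError (the CLI maps these to exit codes 3 and 2).
    """
    if not isinstance(config, dict):
        config = load_run_config(config)
    else:
        validate_run_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acfg = AnalysisConfig.from_dict(config.get("analysis", {}) or {})
    stages = list(config.get("stages", ALL_STAGES))
    manifest: dict = {"version": __version__, "config": config,
                      "stages": {}, "outputs": {}, "input_digests": {}}

    def stage_done(name: str, t0: float, outputs: dict[str, Path]) -> None:
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 4)}
        manifest["outputs"][name] = {k: str(v) for k, v in outputs.items()}

    # --- inputs: simulate or load -------------------------------------
    simulated = "simulate" in config and config["simulate"] is not None
    if simulated:
        sim_kwargs = dict(config["simulate"])
        if seed is not None:
            sim_kwargs["seed"] = seed
        sim = SimConfig(**sim_kwargs)
        t0 = time.perf_counter()
        genome = simulate_genome(sim)
        fasta = out / "genome.fa"
        write_fasta(genome, fasta)
        stage_done("simulate_genome", t0, {"fasta": fasta})
        vp_cfg = {"name": "vp", "chrom": sim.chrom, "position": sim.viewpoint_pos}
        conditions = config.get("conditions", ["A", "B"])
    else:
        inputs = config["inputs"]
        fasta = Path(inputs["fasta"])
        if not fasta.exists():
            raise FileNotFoundError(fasta)
        genome = read_fasta(fasta)[config["viewpoint"]["chrom"]]
        vp_cfg = config["viewpoint"]
        conditions = config.get("conditions", [])

    # --- digest --------------------------------------------------------
    t0 = time.perf_counter()
    primary = (config.get("simulate", {}) or {}).get("primary_motif", "GATC")
    secondary = (config.get("simulate", {}) or {}).get("secondary_motif", "CTAG")
    fragments = digest(genome, primary, secondary)
    viewpoint = locate_viewpoint(fragments, vp_cfg["name"], vp_cfg["chrom"],
                                 int(vp_cfg["position"]),
                                 exclusion_halfwidth=acfg.exclusion_halfwidth)
    frag_bed = out / "fragments.bed"
    write_fragments_bed(fragments, frag_bed)
    stage_done("digest", t0, {"fragments": frag_bed})

    # --- counts ----------------------------------------------------------
    t0 = time.perf_counter()
    if simulated:
        cms = {}
        truth_paths = {}
        for cond in conditions:
            cm_c, truth = simulate_4c_counts(fragments, viewpoint, sim, cond)
            cms[cond] = cm_c
            tp = out / f"truth_{cond}.tsv"
            truth.to_csv(tp, sep="\t", index=False)
            truth_paths[cond] = tp
        import pandas as pd
        all_counts = pd.concat([c.counts for c in cms.values()], axis=1)
        libraries = {}
        for c in cms.values():
            libraries.update(c.libraries)
        cm = CountMatrix(counts=all_counts, libraries=libraries,
                         fragments=list(fragments))
    else:
        reads_path = Path(config["inputs"]["reads"])
        if not reads_path.exists():
            raise FileNotFoundError(reads_path)
        manifest["input_digests"][str(reads_path)] = _sha256(reads_path)
        reads = read_reads_tsv(reads_path)
        libmap = config.get("conditions", {})
        libraries = None
        if isinstance(libmap, dict) and libmap:
            libraries = {lib: LibraryInfo(condition=cond, replicate=i + 1)
                         for i, (lib, cond) in enumerate(libmap.items())}
        cm = count_reads(reads, fragments, viewpoint, libraries)
    counts_tsv = out / "counts.tsv"
    write_counts_tsv(cm, counts_tsv)
    qc = replicate_correlation(cm, acfg)
    qc_tsv = out / "replicate_correlation.tsv"
    qc.to_csv(qc_tsv, sep="\t", index=False)
    stage_done("count", t0, {"counts": counts_tsv, "replicate_qc": qc_tsv})

    # --- profiles --------------------------------------------------------
    cond_profiles = {}
    if "profile" in stages:
        t0 = time.perf_counter()
        outputs = {}
        by_cond: dict[str, list] = {}
        for lib in cm.library_ids:
            prof = smooth_running_mean(normalize_rpm(cm, lib), acfg.smooth_window)
            path = out / f"profile_{lib}.bedgraph"
            write_bedgraph(prof, fragments, path)
            outputs[lib] = path
            by_cond.setdefault(cm.libraries[lib].condition, []).append(prof)
        for cond, profs in by_cond.items():
            avg = average_replicates(profs, label=cond)
            path = out / f"profile_{cond}_avg.bedgraph"
            write_bedgraph(avg, fragments, path,
                           track_name=f"{viewpoint.name}_{cond}")
            outputs[f"{cond}_avg"] = path
            cond_profiles[cond] = avg
        stage_done("profile", t0, outputs)

    # --- interaction calling ----------------------------------------------
    if "call" in stages:
        t0 = time.perf_counter()
        outputs = {}
        for cond in sorted({i.condition for i in cm.libraries.values()}):
            libs = cm.libraries_for(cond)
            avg_counts = cm.counts[libs].mean(axis=1)
            candidates = filter_min_count(cm, acfg, condition=cond)
            candidates -= {viewpoint.fragment_index}
            fit = fit_distance_decay(avg_counts, fragments, viewpoint, candidates)
            calls = call_interactions(fit, acfg)
            tsv = out / f"calls_{cond}.tsv"
            bed = out / f"calls_{cond}.bed"
            write_calls_tsv(calls, tsv)
            write_calls_bed(calls, fragments, bed)
            outputs[f"{cond}_tsv"], outputs[f"{cond}_bed"] = tsv, bed
            if cond in cond_profiles:
                segs = segment_domains(cond_profiles[cond].values, acfg)
                dom_bed = out / f"domains_{cond}.bed"
                write_domains_bed(segs, fragments, dom_bed)
                outputs[f"{cond}_domains"] = dom_bed
        stage_done("call", t0, outputs)

    # --- differential ------------------------------------------------------
    if "diff" in stages:
        conds = sorted({i.condition for i in cm.libraries.values()})
        if len(conds) >= 2:
            t0 = time.perf_counter()
            ref = config.get("reference_condition", conds[0])
            other = [c for c in conds if c != ref][0]
            res = differential_fragments(cm, ref, other, reference_label=ref,
                                         cfg=acfg)
            tsv = out / "differential.tsv"
            bed = out / "differential_regions.bed"
            write_differential_tsv(res, tsv)
            write_regions_bed(res, viewpoint.chrom, bed)
            stage_done("diff", t0, {"table": tsv, "regions": bed})

    # --- allelic -------------------------------------------------------------
    if "allelic" in stages:
        t0 = time.perf_counter()
        if simulated:
            trio, truth_map = simulate_trio(sim, viewpoint)
            vcf = out / "trio.vcf"
            write_trio_vcf(trio, vcf)
            write_truth_tsv(truth_map, out / "phase_truth.tsv")
            phased = phase_snps(trio)
            informative = select_informative(phased, viewpoint, acfg)
            records = simulate_allelic_counts([s.pos for s in informative], sim)
            ac_tsv = out / "allelic_counts.tsv"
            write_allelic_counts_tsv(records, ac_tsv)
            report = region_bias_report(
                {("sim", viewpoint.name): records}, acfg)
        else:
            inputs = config["inputs"]
            for key in ("vcf", "pedigree", "allelic_counts"):
                if key in inputs and not Path(inputs[key]).exists():
                    raise FileNotFoundError(inputs[key])
            ped = read_pedigree_yaml(inputs["pedigree"])
            trio = read_trio_vcf(inputs["vcf"], ped)
            phased = phase_snps(trio)
            informative = select_informative(phased, viewpoint, acfg)
            records = read_allelic_counts_tsv(inputs["allelic_counts"])
            keep = {s.pos for s in informative}
            records = [r for r in records if r.snp_pos in keep]
            report = region_bias_report(
                {(inputs.get("cell_line", "sample"), viewpoint.name): records},
                acfg)
        rep_tsv = out / "allelic_bias.tsv"
        write_bias_report_tsv(report, rep_tsv)
        stage_done("allelic", t0, {"report": rep_tsv})

    # atomic manifest write
    manifest_path = out / "manifest.json"
    tmp = out / ".manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    os.replace(tmp, manifest_path)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
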