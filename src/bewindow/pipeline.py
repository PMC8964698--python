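"""Run configuration and end-to-end orchestration of the analysis stages.

A run is described by a single YAML file: target definitions (inline
sequence or FASTA), a sample sheet (sample id, target, condition, replicate,
FASTQ paths), and thresholds.  The stage functions here are what the CLI
wraps; they are equally usable from Python.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from .alignment import AmpliconAligner, write_sam
from .alleles import call_alleles, perfect_edit_summary
from .quantify import (amplicon_qc_filter, build_conversion_matrix,
                       editing_profile, indel_frequency)
from .readprep import merge_pair, read_fastq_pairs
from .targets import AmpliconTarget, window_partition
from .windows import heatmap_table, inhibition_rate, window_comparison

logger = logging.getLogger("bewindow")

__all__ = ["RunConfig", "Thresholds", "SampleSheetEntry", "load_run_config",
           "quantify_sample", "run_quantify", "run_compare", "run_alleles",
           "run_simulate", "SampleQuant"]


@dataclass
class Thresholds:
    min_overlap: int = 11
    max_mismatch_frac: float = 0.1
    min_base_qual: int = 30
    min_identity: float = 0.7
    min_control_freq: float = 0.005
    min_reads: int = 0
    allele_region: tuple = (1, 20)
    min_allele_count: int = 1
    window_override: tuple = None


@dataclass
class SampleSheetEntry:
    sample_id: str
    target: str
    condition: str
    replicate: int
    r1: str
    r2: str


@dataclass
class RunConfig:
    targets: dict                 # name -> AmpliconTarget
    samples: list                 # [SampleSheetEntry]
    thresholds: Thresholds
    output_dir: str = "bewindow_out"
    seed: int = 0
    write_sam: bool = False

    def __post_init__(self):
        for s in self.samples:
            if s.target not in self.targets:
                raise ValueError(f"sample {s.sample_id} references unknown "
                                 f"target {s.target!r}")
            if s.condition not in ("control", "treated"):
                raise ValueError(f"sample {s.sample_id}: condition must be "
                                 "control or treated")


def _target_from_record(rec: dict, base_dir: Path) -> AmpliconTarget:
    if "fasta" in rec:
        path = base_dir / rec["fasta"]
        seqs = list(SeqIO.parse(str(path), "fasta"))
        contig = rec.get("contig")
        if contig is not None:
            matches = [s for s in seqs if s.id == contig]
            if not matches:
                raise ValueError(f"contig {contig!r} not found in {path}")
            amplicon = str(matches[0].seq)
        else:
            if len(seqs) != 1:
                raise ValueError(f"{path} has {len(seqs)} records; specify 'contig'")
            amplicon = str(seqs[0].seq)
    else:
        amplicon = rec["amplicon_seq"]
    intended = tuple(rec.get("intended_positions", ()))
    if "protospacer_seq" in rec:
        return AmpliconTarget.from_protospacer(
            rec["name"], amplicon, rec["protospacer_seq"], rec["editor"],
            intended, rec.get("min_flank", 10))
    return AmpliconTarget(rec["name"], amplicon, int(rec["protospacer_start"]),
                          rec.get("protospacer_strand", "+"), rec["editor"],
                          frozenset(intended), rec.get("min_flank", 10))


def load_run_config(path) -> RunConfig:
    """Parse a YAML run configuration."""
    path = Path(path)
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    base = path.parent
    targets = {}
    for rec in raw.get("targets", []):
        tgt = _target_from_record(rec, base)
        targets[tgt.name] = tgt
    samples = []
    for rec in raw.get("samples", []):
        samples.append(SampleSheetEntry(
            str(rec["id"]), rec["target"], rec["condition"],
            int(rec.get("replicate", 1)),
            str(base / rec["r1"]), str(base / rec["r2"])))
    thr_raw = dict(raw.get("thresholds", {}))
    if "allele_region" in thr_raw:
        thr_raw["allele_region"] = tuple(thr_raw["allele_region"])
    if "window_override" in thr_raw and thr_raw["window_override"] is not None:
        thr_raw["window_override"] = tuple(thr_raw["window_override"])
    thresholds = Thresholds(**thr_raw)
    return RunConfig(targets, samples, thresholds,
                     raw.get("output_dir", "bewindow_out"),
                     int(raw.get("seed", 0)), bool(raw.get("write_sam", False)))


@dataclass
class SampleQuant:
    """Everything quantified for one sample."""

    sample: SampleSheetEntry
    counts: dict                  # parsed/merged/aligned/accepted
    matrix: object
    profile: object
    indel_freq: object
    alignments: list


def quantify_sample(entry: SampleSheetEntry, target: AmpliconTarget,
                    thr: Thresholds, keep_alignments: bool = True):
    """FASTQ pair -> merge -> align -> conversion matrix for one sample."""
    aligner = AmpliconAligner(target, min_identity=thr.min_identity)
    counts = {"parsed": 0, "merged": 0, "aligned": 0, "accepted": 0}
    alignments = []
    for pair in read_fastq_pairs(entry.r1, entry.r2):
        counts["parsed"] += 1
        cons = merge_pair(pair, thr.min_overlap, thr.max_mismatch_frac)
        if cons is None:
            continue
        counts["merged"] += 1
        ar = aligner.align(cons.seq, cons.qual, cons.read_id)
        if ar is None:
            continue
        counts["aligned"] += 1
        counts["accepted"] += 1
        alignments.append(ar)
    matrix = build_conversion_matrix(alignments, target, thr.min_base_qual)
    profile = editing_profile(matrix, target, label=entry.sample_id,
                              replicate=entry.replicate)
    indel = indel_frequency(alignments, target)
    return SampleQuant(entry, counts, matrix, profile, indel,
                       alignments if keep_alignments else [])


def _quantify_all(config: RunConfig, keep_alignments: bool = True):
    """Quantify every sample, apply the read-count QC filter, log per stage."""
    results = {}
    skipped = []
    for entry in config.samples:
        target = config.targets[entry.target]
        try:
            sq = quantify_sample(entry, target, config.thresholds,
                                 keep_alignments)
        except (OSError, ValueError) as exc:
            logger.warning("sample %s skipped: %s", entry.sample_id, exc)
            skipped.append({"sample": entry.sample_id, "reason": str(exc)})
            continue
        logger.info("sample %s: %s", entry.sample_id, sq.counts)
        results[entry.sample_id] = sq
    retained, qc_report = amplicon_qc_filter(
        {sid: sq.counts["accepted"] for sid, sq in results.items()},
        config.thresholds.min_reads)
    for rec in qc_report:
        logger.warning("sample %s excluded by QC: %s", rec["sample"], rec["reason"])
    results = {sid: results[sid] for sid in retained}
    return results, skipped + qc_report


def run_quantify(config: RunConfig):
    """``quantify`` command: per-sample conversion matrix + profile TSVs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results, exclusions = _quantify_all(config, keep_alignments=config.write_sam)
    log = {"samples": {}, "exclusions": exclusions}
    for sid, sq in results.items():
        target = config.targets[sq.sample.target]
        sq.matrix.to_frame(target).to_csv(out / f"{sid}.conversion_matrix.tsv",
                                          sep="\t", index=False)
        log["samples"][sid] = {**sq.counts, "indel_frequency": sq.indel_freq}
        if config.write_sam:
            write_sam(sq.alignments, target, out / f"{sid}.sam")
    with open(out / "run_log.json", "w") as handle:
        json.dump(log, handle, indent=2, default=float)
    return results


def run_compare(config: RunConfig):
    """``compare`` command: inhibition table + window comparison per target."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results, _ = _quantify_all(config, keep_alignments=False)
    summaries = {}
    for tname, target in config.targets.items():
        controls = {sq.sample.replicate: sq for sq in results.values()
                    if sq.sample.target == tname and sq.sample.condition == "control"}
        treateds = {sq.sample.replicate: sq for sq in results.values()
                    if sq.sample.target == tname and sq.sample.condition == "treated"}
        shared = sorted(set(controls) & set(treateds))
        if not shared:
            if controls or treateds:
                raise ValueError(f"target {tname}: no matched control/treated "
                                 "replicate pairs")
            continue
        profiles = [
            inhibition_rate(controls[rep].profile, treateds[rep].profile,
                            config.thresholds.min_control_freq,
                            site=tname, replicate=rep)
            for rep in shared
        ]
        partition = window_partition(target.editor,
                                     config.thresholds.window_override)
        comp = window_comparison(profiles, partition)
        heatmap_table(profiles).to_csv(out / f"{tname}.inhibition.tsv",
                                       sep="\t", index=False)
        summary = {
            "target": tname,
            "on_target_positions": sorted(partition.on_target),
            "replicate_pairs": shared,
            "mean_ir_on_target": comp.mean_on,
            "mean_ir_out_of_window": comp.mean_out,
            "selectivity_fold": comp.selectivity_fold,
            "t_statistic": comp.t_statistic,
            "p_value": comp.p_value,
            "n_on": comp.n_on,
            "n_out": comp.n_out,
            "reason": comp.reason,
        }
        with open(out / f"{tname}.comparison.json", "w") as handle:
            json.dump(summary, handle, indent=2, default=float)
        summaries[tname] = summary
    return summaries


def run_alleles(config: RunConfig):
    """``alleles`` command: allele tables + perfect-edit summaries per target."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results, _ = _quantify_all(config, keep_alignments=True)
    tables = {}
    for sid, sq in results.items():
        target = config.targets[sq.sample.target]
        table = call_alleles(sq.alignments, target,
                             config.thresholds.allele_region,
                             config.thresholds.min_base_qual,
                             config.thresholds.min_allele_count)
        table.to_frame().to_csv(out / f"{sid}.alleles.tsv", sep="\t", index=False)
        tables[sid] = table
    summaries = {}
    for tname in config.targets:
        ctrl = [tables[sid] for sid, sq in results.items()
                if sq.sample.target == tname and sq.sample.condition == "control"
                and sid in tables]
        trt = [tables[sid] for sid, sq in results.items()
               if sq.sample.target == tname and sq.sample.condition == "treated"
               and sid in tables]
        per_sample = {
            sid: {
                "perfect_of_total": tables[sid].perfect_of_total,
                "perfect_of_edited": tables[sid].perfect_of_edited,
                "edited_of_total": tables[sid].edited_of_total,
            }
            for sid, sq in results.items()
            if sq.sample.target == tname and sid in tables
        }
        summary = {"target": tname, "samples": per_sample}
        if ctrl and trt:
            summary["comparison"] = perfect_edit_summary(ctrl[0], trt[0])
        if per_sample:
            with open(out / f"{tname}.perfect_edit.json", "w") as handle:
                json.dump(summary, handle, indent=2, default=float)
            summaries[tname] = summary
    return summaries


def simulate_and_quantify(sim_config, condition: str = "control",
                          thresholds: Thresholds = None, workdir=None):
    """Simulate one sample and push it through the full pipeline.

    Emits the pool as a paired FASTQ sample (in ``workdir`` or a temporary
    directory) and quantifies it exactly as real data would be; returns
    ``(pool, SampleQuant)`` so estimates can be compared with the truth.
    """
    import tempfile

    from .simulate import pool_to_fastq, simulate_allele_pool

    thresholds = thresholds or Thresholds()
    pool = simulate_allele_pool(sim_config, condition)

    def _run(directory):
        directory = Path(directory)
        r1 = directory / f"{condition}.R1.fastq"
        r2 = directory / f"{condition}.R2.fastq"
        pool_to_fastq(pool, sim_config, r1, r2)
        entry = SampleSheetEntry(f"sim-{condition}", sim_config.target.name,
                                 condition, 1, str(r1), str(r2))
        return quantify_sample(entry, sim_config.target, thresholds)

    if workdir is not None:
        return pool, _run(workdir)
    with tempfile.TemporaryDirectory() as tmp:
        return pool, _run(tmp)


def run_simulate(preset_name: str, out_dir, seed=None, condition="control",
                 coverage=None):
    """``simulate`` command: emit a preset's FASTQ pair plus its truth JSON."""
    import dataclasses as _dc

    from .simulate import pool_to_fastq, scenario_presets, simulate_allele_pool

    presets = scenario_presets()
    if preset_name not in presets:
        raise ValueError(f"unknown preset {preset_name!r}; "
                         f"choose from {sorted(presets)}")
    config = presets[preset_name]
    if seed is not None:
        config = _dc.replace(config, seed=int(seed))
    if coverage is not None:
        config = _dc.replace(config, coverage=int(coverage))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pool = simulate_allele_pool(config, condition)
    stem = f"{preset_name}.{condition}"
    r1 = out / f"{stem}.R1.fastq"
    r2 = out / f"{stem}.R2.fastq"
    pool_to_fastq(pool, config, r1, r2)
    with open(out / f"{stem}.truth.json", "w") as handle:
        handle.write(pool.truth_json())
    return config, pool, (r1, r2)
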