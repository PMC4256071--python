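"""End-to-end experiment orchestration.

Wires the generators, fragmenter, prediction emulator, clustering, classifier
and linker into two replayable experiments: a fragmentation sweep (gene count
and exons-per-gene versus contig number) and an RNA-seq correction experiment
(cumulative-dataset and support-threshold tables plus truth-based accuracy).
Every output is a text artifact readable by the corresponding module alone.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _dists, formats
from .fragmenter import apply_fragmentation, assembly_stats, nested_plans, plan_fragmentation
from .prediction_emulator import (emulate_boundary_invention, exons_per_gene,
                                  filter_complete, prediction_report,
                                  project_annotation)
from .rnaseq_linker import (build_connection_graph, correction_curves,
                            filter_alignments, merge_models, recovery_report)
from .synthetic_data import SyntheticGenome, make_genome, make_read_pairs, make_template_lengths

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything needed to replay an experiment byte-for-byte."""

    seed: int = 0
    n_genes: int = 200
    n_scaffolds: int = 4
    gc: float = 0.42
    mean_exons: float = 4.0
    template_n: int = 20000
    template_min_len: int = 200
    xs: tuple[int, ...] = (20, 200, 2000)
    p_invent: float = 1.0
    nested: bool = True
    cluster_method: str = "local-align"
    cluster_min_score: float = 40.0
    inflation: float = 2.0
    min_identity: float = 95.0
    min_overlap_frac: float = 0.80
    max_complement_overlap: float = 0.10
    min_mapq: int = 30
    require_unique: bool = True
    n_datasets: int = 3
    pairs_per_dataset: int = 2000
    read_length: int = 75
    k_max: int = 10

    def __post_init__(self) -> None:
        if not self.xs:
            raise ValueError("xs must be non-empty")
        if any(x < self.n_scaffolds for x in self.xs):
            raise ValueError("every x must be >= the scaffold count")

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any]) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        payload = dict(payload)
        if "xs" in payload:
            payload["xs"] = tuple(int(v) for v in payload["xs"])
        return cls(**payload)


def _build_inputs(config: ExperimentConfig):
    genome = make_genome(
        n_genes=config.n_genes,
        exons_per_gene=_dists.geometric(1.0 / config.mean_exons),
        gc=config.gc,
        n_scaffolds=config.n_scaffolds,
        seed=config.seed,
    )
    template = make_template_lengths(config.template_n, min_len=config.template_min_len,
                                     seed=config.seed + 1)
    return genome, template


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage %s failed: %s", stage, exc)
                return False
            log.info("stage %s done in %.2fs", stage, time.perf_counter() - self.t0)
            return False
    return _Timer()


def run_fragmentation_sweep(config: ExperimentConfig, outdir) -> pd.DataFrame:
    """Model counts and exon statistics at each fragmentation level.

    Writes the genome, truth annotation, per-x plans/contigs/models, per-x
    exon histograms and a sweep table; returns the sweep table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _timed("simulate"):
        genome, template = _build_inputs(config)
        formats.write_fasta(outdir / "genome.fa", genome.scaffolds)
        formats.write_genes_gff3(outdir / "truth.gff3", genome.genes)
        formats.write_template_lengths(outdir / "template_lengths.txt", template.lengths)
    with _timed("fragment"):
        if config.nested:
            plans = nested_plans(genome.scaffolds, template.lengths, config.xs, config.seed)
        else:
            plans = {x: plan_fragmentation(genome.scaffolds, template.lengths, x, config.seed)
                     for x in config.xs}
    rows = []
    hist_payload = {}
    for x in sorted(plans):
        plan = plans[x]
        formats.write_plan(outdir / f"plan_x{x}.json", plan)
        with _timed(f"predict-emulate x={x}"):
            contigs = apply_fragmentation(genome.scaffolds, plan)
            models = project_annotation(genome.genes, plan)
            models = emulate_boundary_invention(models, config.p_invent, config.seed + x)
            complete = filter_complete(models)
            formats.write_models_gff3(outdir / f"models_x{x}.gff3", models)
            stats = assembly_stats(contigs)
            hist, mean = exons_per_gene(models)
            hist_payload[str(x)] = {str(k): v for k, v in sorted(hist.items())}
            rows.append({
                "x": x,
                "contig_count": stats["count"],
                "n50": stats["n50"],
                "total_models": len(models),
                "complete_models": len(complete),
                "mean_exons_per_model": mean,
            })
    sweep = pd.DataFrame(rows)
    sweep.to_csv(outdir / "sweep.tsv", sep="\t", index=False, float_format="%.6g")
    formats.write_json(outdir / "exon_histograms.json", hist_payload)
    return sweep


def run_correction_experiment(config: ExperimentConfig, outdir) -> dict:
    """RNA-seq correction at the deepest fragmentation level of the sweep.

    Emits the cumulative-dataset table, the support-threshold table, the
    merged model groups and a provenance-based accuracy report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _timed("simulate"):
        genome, template = _build_inputs(config)
    x = max(config.xs)
    with _timed("fragment"):
        plan = plan_fragmentation(genome.scaffolds, template.lengths, x, config.seed)
    with _timed("predict-emulate"):
        models = project_annotation(genome.genes, plan)
        models = emulate_boundary_invention(models, config.p_invent, config.seed + x)
        models = filter_complete(models)
        formats.write_models_gff3(outdir / "models.gff3", models)
    with _timed("link-rnaseq"):
        datasets = [
            make_read_pairs(genome, plan, config.pairs_per_dataset,
                            read_length=config.read_length, seed=config.seed + 100 + i)
            for i in range(config.n_datasets)
        ]
        contig_lengths = {plan.contig_id(sid, i): e - s
                          for sid in plan.scaffold_lengths
                          for i, (s, e) in enumerate(plan.intervals(sid))}
        for i, ds in enumerate(datasets, start=1):
            formats.write_sam(outdir / f"reads_{i}.sam", ds, contig_lengths)
        cumulative, threshold = correction_curves(
            datasets, models, k_range=range(1, config.k_max + 1),
            min_mapq=config.min_mapq, require_unique=config.require_unique)
        cumulative.to_csv(outdir / "cumulative.tsv", sep="\t", index=False)
        threshold.to_csv(outdir / "threshold.tsv", sep="\t", index=False)
        pooled = filter_alignments([p for ds in datasets for p in ds],
                                   config.min_mapq, config.require_unique)
        graph = build_connection_graph(pooled, models)
        merge = merge_models(graph, models, k=1)
        provenance = {m.id: m.provenance for m in models}
        report = recovery_report(merge, provenance)
    payload = {
        "x": x,
        "original_models": merge.original_count,
        "revised_models": merge.revised_count,
        "reduction": merge.reduction,
        "recovery": report,
    }
    formats.write_json(outdir / "correction_report.json", payload)
    return payload
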