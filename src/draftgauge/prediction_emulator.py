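"""Emulate ab initio gene prediction on a fragmented assembly.

Instead of running an external predictor, the truth annotation is projected
onto the contigs of a fragmentation plan: every contig carrying at least one
exonic base of a gene yields one model, with exons clipped at contig edges.
Completeness flags record whether the transcription-order CDS termini survive
on the contig; :func:`emulate_boundary_invention` then models predictors that
report fragments as complete genes.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .fragmenter import FragmentationPlan

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import TrueGene

UNKNOWN_PROVENANCE = "unknown"


@dataclass(frozen=True)
class GeneModel:
    """A predicted gene on a single contig.

    Exon intervals are 0-based half-open in contig coordinates, disjoint and
    ascending. ``provenance`` is the originating truth gene id when known.
    """

    id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    has_start: bool
    has_stop: bool
    provenance: str = UNKNOWN_PROVENANCE

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("model must have >= 1 exon")
        for (a, b), (c, _) in zip(self.exons, self.exons[1:]):
            if b > c:
                raise ValueError("exons must be disjoint and ascending")
        if any(b <= a for a, b in self.exons):
            raise ValueError("empty exon interval")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def is_complete(self) -> bool:
        return self.has_start and self.has_stop


def project_annotation(genes: Iterable["TrueGene"], plan: FragmentationPlan) -> list[GeneModel]:
    """Project truth genes onto the contigs of a fragmentation plan.

    Each gene yields one model per contig overlapping >= 1 of its exonic
    bases; exons are clipped at contig edges. Contigs touching only introns
    yield nothing (fragment predictors see exons, not introns). A gene hit by
    no breakpoint yields exactly one complete model.
    """
    models: list[GeneModel] = []
    for gene in genes:
        if gene.scaffold_id not in plan.scaffold_lengths:
            raise ValueError(f"gene {gene.id} on unknown scaffold {gene.scaffold_id}")
        first_cds = gene.exons[0][0] if gene.strand == "+" else gene.exons[-1][1] - 1
        last_cds = gene.exons[-1][1] - 1 if gene.strand == "+" else gene.exons[0][0]
        per_contig: dict[int, list[tuple[int, int]]] = {}
        intervals = plan.intervals(gene.scaffold_id)
        # walk only contigs within the gene's span
        lo, hi = gene.exons[0][0], gene.exons[-1][1]
        for idx, (cs, ce) in enumerate(intervals):
            if ce <= lo:
                continue
            if cs >= hi:
                break
            clipped = [(max(a, cs) - cs, min(b, ce) - cs)
                       for a, b in gene.exons if a < ce and b > cs]
            if clipped:
                per_contig[idx] = clipped
        n_pieces = len(per_contig)
        for part, (idx, exons) in enumerate(sorted(per_contig.items())):
            cs, ce = intervals[idx]
            cid = plan.contig_id(gene.scaffold_id, idx)
            has_start = cs <= first_cds < ce
            has_stop = cs <= last_cds < ce
            mid = gene.id if n_pieces == 1 else f"{gene.id}|{cid}"
            models.append(GeneModel(mid, cid, gene.strand, tuple(exons),
                                    has_start, has_stop, provenance=gene.id))
    return models


def emulate_boundary_invention(models: Sequence[GeneModel], p_invent: float,
                               seed: int) -> list[GeneModel]:
    """Set each missing start/stop flag to True with probability ``p_invent``.

    Models predictor behavior on fragments: ab initio tools routinely emit
    complete-looking models for partial genes. Deterministic per seed;
    provenance and coordinates untouched.
    """
    if not 0.0 <= p_invent <= 1.0:
        raise ValueError("p_invent must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[GeneModel] = []
    for m in models:
        has_start, has_stop = m.has_start, m.has_stop
        if not has_start and rng.random() < p_invent:
            has_start = True
        if not has_stop and rng.random() < p_invent:
            has_stop = True
        out.append(replace(m, has_start=has_start, has_stop=has_stop))
    return out


def filter_complete(models: Iterable[GeneModel]) -> list[GeneModel]:
    """Keep models whose sequence carries both a start and a stop codon flag."""
    return [m for m in models if m.is_complete]


def exons_per_gene(models: Iterable[GeneModel]) -> tuple[Counter, float]:
    """Histogram of exon counts per model, plus the mean (0.0 on empty input)."""
    hist = Counter(m.n_exons for m in models)
    total = sum(hist.values())
    mean = sum(k * v for k, v in hist.items()) / total if total else 0.0
    return hist, mean


def model_sequence(model: GeneModel, contig_sequences: Mapping[str, str]) -> str:
    """Spliced (transcription-order) nucleotide sequence of a model."""
    seq = "".join(contig_sequences[model.contig_id][a:b] for a, b in model.exons)
    return seq if model.strand == "+" else reverse_complement(seq)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def prediction_report(models: Sequence[GeneModel]) -> dict:
    """Per-assembly totals in the shape of an assembly/prediction summary row."""
    complete = filter_complete(models)
    hist, mean = exons_per_gene(models)
    return {
        "total_models": len(models),
        "complete_models": len(complete),
        "mean_exons_per_model": mean,
        "exon_histogram": dict(sorted(hist.items())),
    }
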