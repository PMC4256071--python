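"""Readers and writers for the standard formats the pipeline exchanges.

FASTA via Biopython, SAM via pysam, tables via pandas; GFF3 features are
written/parsed directly (fixed attribute order) so write -> read -> write is
byte-stable. Coordinates are 0-based half-open in memory and converted to
1-based inclusive only at the GFF3 boundary.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .family_clustering import SimilarityHit
from .fragmenter import Contig, FragmentationPlan
from .prediction_emulator import GeneModel
from .synthetic_data import Mate, ReadPair, TrueGene

SOURCE = "draftgauge"


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_contigs_fasta(path, contigs: Sequence[Contig]) -> None:
    write_fasta(path, {c.id: c.sequence for c in contigs})


# ---------------------------------------------------------------------------
# GFF3

def _gff_line(seqid: str, ftype: str, start0: int, end0: int, strand: str,
              attrs: str, phase: str = ".") -> str:
    return "\t".join([seqid, SOURCE, ftype, str(start0 + 1), str(end0), ".",
                      strand, phase, attrs])


def write_genes_gff3(path, genes: Sequence[TrueGene]) -> None:
    """Truth annotation as gene/mRNA/exon/CDS features."""
    lines = ["##gff-version 3"]
    for g in genes:
        lo, hi = g.span
        lines.append(_gff_line(g.scaffold_id, "gene", lo, hi, g.strand,
                               f"ID={g.id};expression={g.expression_level:g}"))
        lines.append(_gff_line(g.scaffold_id, "mRNA", lo, hi, g.strand,
                               f"ID={g.id}.t1;Parent={g.id}"))
        for i, (a, b) in enumerate(g.exons, start=1):
            lines.append(_gff_line(g.scaffold_id, "exon", a, b, g.strand,
                                   f"ID={g.id}.exon{i};Parent={g.id}.t1"))
            lines.append(_gff_line(g.scaffold_id, "CDS", a, b, g.strand,
                                   f"ID={g.id}.cds{i};Parent={g.id}.t1", phase="."))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part:
            key, _, val = part.partition("=")
            out[key] = val
    return out


def _iter_gff(path):
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {raw!r}")
        yield cols


def read_genes_gff3(path) -> list[TrueGene]:
    meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for cols in _iter_gff(path):
        seqid, _, ftype, start, end, _, strand, _, attrs = cols
        a = _parse_attrs(attrs)
        if ftype == "gene":
            gid = a["ID"]
            order.append(gid)
            meta[gid] = {"scaffold": seqid, "strand": strand,
                         "expression": float(a.get("expression", 1.0))}
            exons.setdefault(gid, [])
        elif ftype == "exon":
            gid = a["Parent"].rsplit(".t1", 1)[0]
            exons[gid].append((int(start) - 1, int(end)))
    return [TrueGene(gid, meta[gid]["scaffold"], meta[gid]["strand"],
                     tuple(sorted(exons[gid])), expression_level=meta[gid]["expression"])
            for gid in order]


def write_models_gff3(path, models: Sequence[GeneModel]) -> None:
    """Predicted models; completeness and provenance ride in the attributes."""
    lines = ["##gff-version 3"]
    for m in models:
        lo, hi = m.exons[0][0], m.exons[-1][1]
        attrs = (f"ID={m.id};has_start={str(m.has_start).lower()};"
                 f"has_stop={str(m.has_stop).lower()};provenance={m.provenance}")
        lines.append(_gff_line(m.contig_id, "gene", lo, hi, m.strand, attrs))
        for i, (a, b) in enumerate(m.exons, start=1):
            lines.append(_gff_line(m.contig_id, "exon", a, b, m.strand,
                                   f"ID={m.id}.exon{i};Parent={m.id}"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_models_gff3(path) -> list[GeneModel]:
    meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for cols in _iter_gff(path):
        seqid, _, ftype, start, end, _, strand, _, attrs = cols
        a = _parse_attrs(attrs)
        if ftype == "gene":
            mid = a["ID"]
            order.append(mid)
            meta[mid] = {"contig": seqid, "strand": strand,
                         "has_start": a["has_start"] == "true",
                         "has_stop": a["has_stop"] == "true",
                         "provenance": a.get("provenance", "unknown")}
            exons.setdefault(mid, [])
        elif ftype == "exon":
            exons[a["Parent"]].append((int(start) - 1, int(end)))
    return [GeneModel(mid, meta[mid]["contig"], meta[mid]["strand"],
                      tuple(sorted(exons[mid])), meta[mid]["has_start"],
                      meta[mid]["has_stop"], meta[mid]["provenance"])
            for mid in order]


# ---------------------------------------------------------------------------
# SAM

def _cigar(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """M/N cigar tuples (pysam codes 0/3) for spliced alignment blocks."""
    out: list[tuple[int, int]] = []
    prev_end = None
    for a, b in blocks:
        if prev_end is not None and a > prev_end:
            out.append((3, a - prev_end))
        out.append((0, b - a))
        prev_end = b
    return out


def write_sam(path, pairs: Sequence[ReadPair], contig_lengths: Mapping[str, int]) -> None:
    """Placed read pairs as a text SAM with proper @SQ headers."""
    names = list(contig_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(contig_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            for mate, flag_mate, other in ((p.mate1, 0x40, p.mate2), (p.mate2, 0x80, p.mate1)):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = p.id
                seg.flag = 0x1 | 0x2 | flag_mate
                seg.reference_id = tid[mate.contig_id]
                seg.reference_start = mate.interval[0]
                seg.mapping_quality = mate.mapq
                seg.cigartuples = _cigar(mate.blocks)
                length = sum(b - a for a, b in mate.blocks)
                seg.query_sequence = "N" * length
                seg.next_reference_id = tid[other.contig_id]
                seg.next_reference_start = other.interval[0]
                seg.set_tag("NH", 1 if mate.unique else 2)
                seg.set_tag("ZG", p.gene_id)
                out.write(seg)


def read_sam(path) -> tuple[list[ReadPair], dict[str, int]]:
    """Read pairs back from SAM; returns (pairs, contig lengths from @SQ)."""
    mates: dict[str, dict[int, Mate]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r") as f:
        lengths = dict(zip(f.references, f.lengths))
        for seg in f:
            which = 1 if seg.is_read1 else 2
            nh = seg.get_tag("NH") if seg.has_tag("NH") else 1
            mate = Mate(seg.reference_name, tuple(seg.get_blocks()),
                        mapq=seg.mapping_quality, unique=nh == 1)
            if seg.query_name not in mates:
                mates[seg.query_name] = {}
                order.append(seg.query_name)
            mates[seg.query_name][which] = mate
            if seg.has_tag("ZG"):
                genes[seg.query_name] = seg.get_tag("ZG")
    pairs = []
    for qname in order:
        pair = mates[qname]
        if set(pair) != {1, 2}:
            raise ValueError(f"unpaired record {qname}")
        pairs.append(ReadPair(qname, genes.get(qname, "unknown"), pair[1], pair[2]))
    return pairs, {k: int(v) for k, v in lengths.items()}


# ---------------------------------------------------------------------------
# plans, template lengths, tables

def write_plan(path, plan: FragmentationPlan) -> None:
    Path(path).write_text(plan.to_json())


def read_plan(path) -> FragmentationPlan:
    return FragmentationPlan.from_json(Path(path).read_text())


def write_template_lengths(path, lengths: Sequence[int]) -> None:
    Path(path).write_text("\n".join(str(v) for v in lengths) + "\n")


def read_template_lengths(path) -> list[int]:
    return [int(line) for line in Path(path).read_text().split()]


def write_hits_tsv(path, hits: Sequence[SimilarityHit]) -> None:
    df = pd.DataFrame([{"query": h.query, "subject": h.subject,
                        "identity": h.identity, "qcov": h.query_coverage,
                        "scov": h.subject_coverage, "score": h.score}
                       for h in hits],
                      columns=["query", "subject", "identity", "qcov", "scov", "score"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_hits_tsv(path) -> list[SimilarityHit]:
    df = pd.read_csv(path, sep="\t")
    return [SimilarityHit(r.query, r.subject, float(r.identity),
                          float(r.qcov), float(r.scov), float(r.score))
            for r in df.itertuples(index=False)]


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
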