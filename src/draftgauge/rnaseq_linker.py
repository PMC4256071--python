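"""Merge gene models stranded on different contigs using paired-end evidence.

Read pairs whose two ends hit exons of two different models on two different
contigs contribute support to an edge between those models; set merging
(union-find) at a minimum-support threshold collapses connected models into
one locus and yields a revised gene count.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .prediction_emulator import GeneModel
from .synthetic_data import ReadPair

log = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 30


@dataclass
class ConnectionGraph:
    """Gene models as nodes; edges weighted by supporting read-pair counts."""

    nodes: set[str]
    support: dict[frozenset, int]
    skipped: dict[str, int]

    def edges(self, k: int = 1) -> list[tuple[str, str, int]]:
        out = []
        for pair, s in self.support.items():
            if s >= k:
                a, b = sorted(pair)
                out.append((a, b, s))
        return sorted(out)


@dataclass
class MergeResult:
    groups: list[set[str]]       # merged groups of size >= 2
    original_count: int
    revised_count: int

    @property
    def reduction(self) -> int:
        return self.original_count - self.revised_count


class _DisjointSet:
    """Union-find with path compression and union by size."""

    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}
        self.size = {i: 1 for i in self.parent}

    def find(self, i: str) -> str:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]

    def groups(self) -> list[set[str]]:
        by_root: dict[str, set[str]] = defaultdict(set)
        for i in self.parent:
            by_root[self.find(i)].add(i)
        return [g for g in by_root.values() if len(g) >= 2]


def filter_alignments(
    pairs: Sequence[ReadPair],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    require_unique: bool = True,
) -> list[ReadPair]:
    """Keep pairs where both mates pass mapping quality and uniqueness."""
    kept: list[ReadPair] = []
    dropped = Counter()
    for p in pairs:
        if p.mate1.mapq < min_mapq or p.mate2.mapq < min_mapq:
            dropped["low_mapq"] += 1
        elif require_unique and not (p.mate1.unique and p.mate2.unique):
            dropped["multi_mapping"] += 1
        else:
            kept.append(p)
    if dropped:
        log.info("filter_alignments dropped %s", dict(dropped))
    return kept


def build_connection_graph(
    pairs: Sequence[ReadPair],
    models: Sequence[GeneModel],
) -> ConnectionGraph:
    """Accumulate cross-contig edge support from exon-overlapping read pairs.

    A pair supports edge (g1, g2) iff mate1 overlaps an exon of exactly one
    model g1, mate2 overlaps an exon of exactly one model g2, the models
    differ, and so do their contigs. Ambiguous mates (overlapping exons of
    more than one model) and mates on unknown contigs are skipped and counted.
    """
    by_contig: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_contig[m.contig_id].append(m)

    def hit_models(mate) -> list[str]:
        out = []
        for m in by_contig.get(mate.contig_id, []):
            for ea, eb in m.exons:
                if any(a < eb and b > ea for a, b in mate.blocks):
                    out.append(m.id)
                    break
        return out

    support: dict[frozenset, int] = defaultdict(int)
    skipped = Counter()
    known_contigs = set(by_contig)
    for p in pairs:
        if p.mate1.contig_id not in known_contigs or p.mate2.contig_id not in known_contigs:
            skipped["unknown_contig"] += 1
            continue
        h1, h2 = hit_models(p.mate1), hit_models(p.mate2)
        if not h1 or not h2:
            skipped["no_exon_overlap"] += 1
            continue
        if len(h1) > 1 or len(h2) > 1:
            skipped["ambiguous"] += 1
            continue
        g1, g2 = h1[0], h2[0]
        if g1 == g2:
            skipped["same_model"] += 1
            continue
        if p.mate1.contig_id == p.mate2.contig_id:
            skipped["same_contig"] += 1
            continue
        support[frozenset((g1, g2))] += 1
    return ConnectionGraph(nodes={m.id for m in models}, support=dict(support),
                           skipped=dict(skipped))


def merge_models(
    graph: ConnectionGraph,
    models: Sequence[GeneModel],
    k: int = 1,
) -> MergeResult:
    """Set-merge models connected by >= ``k`` supporting read pairs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    dsu = _DisjointSet(m.id for m in models)
    for a, b, _ in graph.edges(k):
        dsu.union(a, b)
    groups = sorted(dsu.groups(), key=lambda g: sorted(g)[0])
    original = len(models)
    revised = original - sum(len(g) - 1 for g in groups)
    return MergeResult(groups=groups, original_count=original, revised_count=revised)


def correction_curves(
    datasets: Sequence[Sequence[ReadPair]],
    models: Sequence[GeneModel],
    k_range: Sequence[int] = range(1, 11),
    min_mapq: int = DEFAULT_MIN_MAPQ,
    require_unique: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative-dataset and support-threshold correction tables.

    The cumulative table adds datasets in the given order and reports the
    revised count (at k=1) plus per-dataset and cumulative reductions. The
    threshold table pools all datasets and reports revised and collapsed
    counts per k.
    """
    if not datasets:
        raise ValueError("need >= 1 dataset")
    rows = []
    pooled: list[ReadPair] = []
    prev_revised = len(models)
    for i, ds in enumerate(datasets, start=1):
        pooled.extend(filter_alignments(ds, min_mapq, require_unique))
        graph = build_connection_graph(pooled, models)
        merge = merge_models(graph, models, k=1)
        rows.append({
            "n_datasets": i,
            "n_pairs": len(pooled),
            "revised_gene_count": merge.revised_count,
            "reduction": prev_revised - merge.revised_count,
            "cumulative_reduction": merge.reduction,
        })
        prev_revised = merge.revised_count
    cumulative = pd.DataFrame(rows)

    graph = build_connection_graph(pooled, models)
    thr_rows = []
    for k in k_range:
        merge = merge_models(graph, models, k=k)
        thr_rows.append({
            "min_reads": int(k),
            "revised_gene_count": merge.revised_count,
            "collapsed": merge.reduction,
        })
    threshold = pd.DataFrame(thr_rows)
    return cumulative, threshold


def recovery_report(
    merge: MergeResult,
    provenance: Mapping[str, str],
) -> dict:
    """Score merged groups against truth provenance (synthetic runs only).

    A group is correct iff all members share one truth gene; a truth gene is
    missed if it has >= 2 models that do not all end up in one group.
    """
    missing = [m for g in merge.groups for m in g if m not in provenance]
    if missing:
        raise ValueError(f"models without provenance: {missing[:5]}")
    correct = incorrect = 0
    merged_by_gene: dict[str, list[set[str]]] = defaultdict(list)
    for g in merge.groups:
        genes = {provenance[m] for m in g}
        if len(genes) == 1:
            correct += 1
            merged_by_gene[next(iter(genes))].append(g)
        else:
            incorrect += 1

    models_per_gene = Counter(provenance.values())
    missed = []
    group_of = {m: i for i, g in enumerate(merge.groups) for m in g}
    by_gene_models: dict[str, list[str]] = defaultdict(list)
    for m, g in provenance.items():
        by_gene_models[g].append(m)
    for gene, mids in by_gene_models.items():
        if len(mids) < 2:
            continue
        gids = {group_of.get(m, f"solo:{m}") for m in mids}
        if len(gids) > 1:
            missed.append(gene)
    return {
        "correct_merges": correct,
        "incorrect_merges": incorrect,
        "missed_fragmented_genes": sorted(missed),
    }
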