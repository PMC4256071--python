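"""Cluster gene models from multiple assemblies into families by similarity.

Similarity is computed in-process (best local alignment, or canonical k-mer
Jaccard for speed) and fed to a Markov clustering implementation; family sizes
are then compared per family against a designated reference assembly.
"""
from __future__ import annotations

import hashlib
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from Bio import Align

from .prediction_emulator import reverse_complement

log = logging.getLogger(__name__)

DEFAULT_KMER = 11
DEFAULT_MIN_SCORE = 40.0
DEFAULT_INFLATION = 2.0


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    identity: float          # percent, 0..100
    query_coverage: float    # fraction of query aligned, 0..1
    subject_coverage: float  # fraction of subject aligned, 0..1
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")
        for c in (self.query_coverage, self.subject_coverage):
            if not 0.0 <= c <= 1.0 + 1e-9:
                raise ValueError("coverage must be in [0, 1]")


@dataclass(frozen=True)
class GeneFamily:
    """A family of (assembly label, model id) members."""

    id: str
    members: tuple[tuple[str, str], ...]

    def count(self, label: str) -> int:
        return sum(1 for lab, _ in self.members if lab == label)

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(m for _, m in self.members)


@dataclass(frozen=True)
class FamilySizeDelta:
    family_id: str
    draft_count: int
    reference_count: int

    @property
    def delta(self) -> int:
        return self.draft_count - self.reference_count


def family_id(member_ids: Iterable[str]) -> str:
    """Content-addressed family id: stable across reruns and orderings."""
    h = hashlib.sha1("\x00".join(sorted(member_ids)).encode()).hexdigest()
    return f"fam_{h[:12]}"


# ---------------------------------------------------------------------------
# similarity

def _canonical_kmers(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    rc = reverse_complement(seq)
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        out.add(min(kmer, rc[len(seq) - k - i:len(seq) - i]))
    return out


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -2.0
    a.open_gap_score = -4.0
    a.extend_gap_score = -1.0
    return a


def align_pair(query: str, subject: str) -> tuple[float, float, float] | None:
    """Best local alignment of two sequences.

    Returns (percent identity over aligned columns, query coverage fraction,
    subject coverage fraction), or None if no positive-scoring alignment.
    """
    aligner = _aligner()
    if aligner.score(query, subject) <= 0:
        return None
    aln = next(iter(aligner.align(query, subject)))
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return None
    identity = 100.0 * counts.identities / columns
    # coverage from the outermost aligned block per sequence
    qblocks, sblocks = aln.aligned
    qcov = (qblocks[-1][1] - qblocks[0][0]) / len(query)
    scov = (sblocks[-1][1] - sblocks[0][0]) / len(subject)
    return identity, float(qcov), float(scov)


def aligned_footprint(query: str, subject: str) -> tuple[int, int] | None:
    """Interval of ``subject`` covered by the best local alignment of ``query``."""
    aligner = _aligner()
    if aligner.score(query, subject) <= 0:
        return None
    aln = next(iter(aligner.align(query, subject)))
    sblocks = aln.aligned[1]
    return int(sblocks[0][0]), int(sblocks[-1][1])


def all_vs_all_similarity(
    sequences: Mapping[str, str],
    method: str = "local-align",
    min_score: float = DEFAULT_MIN_SCORE,
    k: int = DEFAULT_KMER,
) -> list[SimilarityHit]:
    """Symmetric all-vs-all similarity hits above ``min_score``; no self-hits.

    ``local-align`` scores pairs by percent identity scaled by the larger
    coverage fraction (so a fragment contained in a full-length model scores
    highly, as it would under BLAST), after a shared-k-mer prescreen;
    ``kmer-jaccard`` scores
    by canonical k-mer Jaccard (x100) with containment fractions as coverages.
    """
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    if any(not s for s in sequences.values()):
        raise ValueError("empty sequence in input")
    if method not in ("local-align", "kmer-jaccard"):
        raise ValueError(f"unknown method {method!r}")

    ids = list(sequences)
    kmers = {i: _canonical_kmers(sequences[i], k) for i in ids}
    # inverted index: only pairs sharing >= 1 canonical k-mer are candidates
    by_kmer: dict[str, list[str]] = defaultdict(list)
    for i in ids:
        for km in kmers[i]:
            by_kmer[km].append(i)
    candidates: set[tuple[str, str]] = set()
    for members in by_kmer.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = sorted((members[a], members[b]))
                candidates.add((i, j))

    hits: list[SimilarityHit] = []
    for i, j in sorted(candidates):
        if method == "kmer-jaccard":
            inter = len(kmers[i] & kmers[j])
            union = len(kmers[i] | kmers[j])
            if not inter:
                continue
            score = 100.0 * inter / union
            identity = score
            qcov = inter / max(len(kmers[i]), 1)
            scov = inter / max(len(kmers[j]), 1)
        else:
            res = align_pair(sequences[i], sequences[j])
            if res is None:
                continue
            identity, qcov, scov = res
            score = identity * max(qcov, scov)
        if score < min_score:
            continue
        hits.append(SimilarityHit(i, j, identity, qcov, scov, score))
        hits.append(SimilarityHit(j, i, identity, scov, qcov, score))
    return hits


# ---------------------------------------------------------------------------
# Markov clustering

def mcl_cluster(
    hits: Sequence[SimilarityHit],
    inflation: float = DEFAULT_INFLATION,
    max_iter: int = 100,
    tol: float = 1e-6,
    nodes: Sequence[str] | None = None,
    prune: float = 1e-9,
) -> list[set[str]]:
    """Markov clustering of the similarity graph.

    Builds a column-stochastic matrix from hit scores with self-loops equal to
    each node's maximum incident edge weight, then alternates expansion
    (matrix squaring) and inflation (entrywise power + column renormalization)
    until the matrix is stable. Clusters are the connected components of the
    limit matrix's nonzero structure; extra ``nodes`` become singletons.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    node_set: set[str] = set(nodes or [])
    for h in hits:
        node_set.update((h.query, h.subject))
    order = sorted(node_set)
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    if n == 0:
        return []
    M = np.zeros((n, n))
    for h in hits:
        i, j = index[h.query], index[h.subject]
        if i != j:
            M[i, j] = max(M[i, j], h.score)
            M[j, i] = max(M[j, i], h.score)
    loop = M.max(axis=1)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)

    def normalize(A: np.ndarray) -> np.ndarray:
        cols = A.sum(axis=0)
        cols[cols == 0] = 1.0
        return A / cols

    M = normalize(M)
    converged = False
    for _ in range(max_iter):
        expanded = M @ M
        inflated = normalize(np.power(expanded, inflation))
        inflated[inflated < prune] = 0.0
        inflated = normalize(inflated)
        if np.abs(inflated - M).max() < tol:
            M = inflated
            converged = True
            break
        M = inflated
    if not converged:
        log.warning("MCL did not converge in %d iterations; using current matrix", max_iter)

    G = nx.Graph()
    G.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > tol)
    G.add_edges_from((int(r), int(c)) for r, c in zip(rows, cols) if r != c)
    comps = [sorted(order[i] for i in comp) for comp in nx.connected_components(G)]
    # deterministic order: by lowest member id
    return [set(c) for c in sorted(comps, key=lambda c: c[0])]


def build_families(
    clusters: Iterable[set[str]],
    labels: Mapping[str, str],
) -> list[GeneFamily]:
    """Wrap raw clusters into labeled, content-addressed families.

    ``labels`` maps model id -> assembly label; every clustered model must be
    labeled.
    """
    fams = []
    for cluster in clusters:
        members = tuple(sorted((labels[m], m) for m in cluster))
        fams.append(GeneFamily(family_id(cluster), members))
    return sorted(fams, key=lambda f: f.id)


def compare_family_sizes(
    families: Sequence[GeneFamily],
    draft_label: str,
    reference_label: str,
    tail: int = 3,
) -> tuple[list[FamilySizeDelta], dict[str, int]]:
    """Per-family draft-minus-reference size deltas plus a binned histogram.

    The histogram has integer bins from ``-tail`` to ``+tail``; families
    beyond the tails are collapsed into ``"<-tail"`` / ``">tail"`` buckets
    (reported, never dropped). Only families containing at least one member
    from either label are counted.
    """
    all_labels = {lab for f in families for lab, _ in f.members}
    for lab in (draft_label, reference_label):
        if lab not in all_labels:
            raise ValueError(f"label {lab!r} not present in clustering")
    deltas: list[FamilySizeDelta] = []
    for f in families:
        d, r = f.count(draft_label), f.count(reference_label)
        if d or r:
            deltas.append(FamilySizeDelta(f.id, d, r))
    hist: dict[str, int] = {str(i): 0 for i in range(-tail, tail + 1)}
    hist[f"<-{tail}"] = 0
    hist[f">{tail}"] = 0
    for d in deltas:
        if d.delta < -tail:
            hist[f"<-{tail}"] += 1
        elif d.delta > tail:
            hist[f">{tail}"] += 1
        else:
            hist[str(d.delta)] += 1
    return deltas, hist
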