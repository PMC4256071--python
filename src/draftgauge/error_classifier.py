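"""Classify excess draft genes as cleaved fragments or split alleles.

For every family with more members in the draft than in the reference, the
draft models are aligned against the family's full-length reference model and
against each other. Two near-identical full-length copies are a split allele;
two models matching disjoint, complementary parts of the reference are a
cleaved gene; anything else stays unclassified.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .family_clustering import (GeneFamily, SimilarityHit, align_pair,
                                aligned_footprint)

DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MIN_OVERLAP_FRAC = 0.80
DEFAULT_MAX_COMPLEMENT_OVERLAP = 0.10

VERDICTS = ("cleaved", "split", "unclassified")


@dataclass(frozen=True)
class ClassificationResult:
    family_id: str
    verdict: str
    evidence: tuple[SimilarityHit, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"bad verdict {self.verdict!r}")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_family(
    family_id: str,
    draft: Mapping[str, str],
    reference_id: str,
    reference_seq: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    max_complement_overlap: float = DEFAULT_MAX_COMPLEMENT_OVERLAP,
) -> ClassificationResult:
    """Classify one excess-gene family.

    ``draft`` maps draft model id -> spliced sequence; ``reference_seq`` is
    the full-length model from the higher-quality annotation.

    split: two draft models align to each other above ``min_identity`` over
    >= ``min_overlap_frac`` of both their lengths, and each also matches the
    reference over most of itself (both are full-length copies).

    cleaved: two draft models whose footprints on the reference are
    near-disjoint (pairwise overlap <= ``max_complement_overlap`` of the
    shorter footprint) while jointly covering >= ``min_overlap_frac`` of the
    reference (complementary fragments).
    """
    if len(draft) < 2:
        raise ValueError("need >= 2 draft models to classify an excess")
    if not reference_seq:
        raise ValueError("missing reference sequence")
    ids = sorted(draft)
    footprints: dict[str, tuple[int, int]] = {}
    ref_hits: dict[str, SimilarityHit] = {}
    for mid in ids:
        if not draft[mid]:
            raise ValueError(f"missing sequence for draft model {mid}")
        fp = aligned_footprint(draft[mid], reference_seq)
        if fp is not None:
            footprints[mid] = fp
            res = align_pair(draft[mid], reference_seq)
            if res is not None:
                ident, qcov, scov = res
                ref_hits[mid] = SimilarityHit(mid, reference_id, ident, qcov, scov,
                                              ident * min(qcov, scov))

    # split rule first: mutually near-identical full-length copies
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            res = align_pair(draft[a], draft[b])
            if res is None:
                continue
            ident, qcov, scov = res
            if (ident > min_identity
                    and qcov >= min_overlap_frac and scov >= min_overlap_frac
                    and a in ref_hits and ref_hits[a].query_coverage >= min_overlap_frac
                    and b in ref_hits and ref_hits[b].query_coverage >= min_overlap_frac):
                ev = (SimilarityHit(a, b, ident, qcov, scov, ident * min(qcov, scov)),
                      ref_hits[a], ref_hits[b])
                return ClassificationResult(family_id, "split", ev)

    # cleaved rule: >= 2 near-disjoint footprints jointly covering most of the
    # reference; built greedily, longest footprint first, so genes cleaved
    # into more than two pieces still qualify
    chosen: list[str] = []
    for mid in sorted(footprints, key=lambda m: footprints[m][0] - footprints[m][1]):
        fp = footprints[mid]
        ok = all(
            _overlap(fp, footprints[o]) <= max_complement_overlap
            * min(fp[1] - fp[0], footprints[o][1] - footprints[o][0])
            for o in chosen)
        if ok:
            chosen.append(mid)
    if len(chosen) >= 2:
        merged: list[tuple[int, int]] = []
        for fp in sorted(footprints[m] for m in chosen):
            if merged and fp[0] < merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], fp[1]))
            else:
                merged.append(fp)
        covered = sum(b - a for a, b in merged)
        if covered >= min_overlap_frac * len(reference_seq):
            ev = tuple(ref_hits[m] for m in sorted(chosen) if m in ref_hits)
            return ClassificationResult(family_id, "cleaved", ev)

    return ClassificationResult(family_id, "unclassified", tuple(ref_hits.values()))


def classify_all(
    families: Sequence[GeneFamily],
    sequences: Mapping[str, str],
    draft_label: str,
    reference_label: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    max_complement_overlap: float = DEFAULT_MAX_COMPLEMENT_OVERLAP,
) -> tuple[list[ClassificationResult], dict[str, int]]:
    """Classify every family where the draft has more members than the reference.

    The longest reference member is used as the full-length model. Families
    with a positive delta but no reference member cannot be classified and are
    reported as ``unclassified``. Returns (results, verdict counts).
    """
    results: list[ClassificationResult] = []
    for fam in families:
        draft_ids = [m for lab, m in fam.members if lab == draft_label]
        ref_ids = [m for lab, m in fam.members if lab == reference_label]
        if len(draft_ids) <= len(ref_ids):
            continue
        if not ref_ids or len(draft_ids) < 2:
            results.append(ClassificationResult(fam.id, "unclassified"))
            continue
        ref_id = max(ref_ids, key=lambda m: len(sequences[m]))
        draft = {m: sequences[m] for m in draft_ids}
        results.append(classify_family(
            fam.id, draft, ref_id, sequences[ref_id],
            min_identity=min_identity,
            min_overlap_frac=min_overlap_frac,
            max_complement_overlap=max_complement_overlap))
    summary = dict(Counter(r.verdict for r in results))
    for v in VERDICTS:
        summary.setdefault(v, 0)
    return results, summary
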