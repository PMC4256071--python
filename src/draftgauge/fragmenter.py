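"""Fragment an intact genome into a simulated draft assembly.

Two entry points mirror the two ways real drafts fragment: :func:`split_on_gaps`
cuts scaffolds at long N-runs, and :func:`plan_fragmentation` /
:func:`apply_fragmentation` cut a gap-free genome into exactly ``x`` contigs
with lengths matched to a template length distribution. Plans are explicit,
seeded and serializable so every fragmentation is replayable.
"""
from __future__ import annotations

import bisect
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_MIN_GAP = 50
DEFAULT_MIN_CONTIG = 1000


@dataclass(frozen=True)
class Contig:
    """A gap-free piece of a scaffold with provenance.

    ``start``/``end`` are 0-based half-open coordinates on the source scaffold;
    ``sequence`` always equals ``scaffold[start:end]``.
    """

    id: str
    scaffold_id: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FragmentationPlan:
    """Seeded breakpoint lists realizing ``x`` pieces over a genome.

    ``breakpoints`` maps scaffold id to a sorted list of internal cut
    positions (0 < b < scaffold length). Pieces tile each scaffold exactly,
    so the total piece count is ``len(scaffolds) + sum(len(bps))``.
    """

    x: int
    seed: int
    scaffold_lengths: dict[str, int]
    breakpoints: dict[str, list[int]]

    def __post_init__(self) -> None:
        n = 0
        for sid, length in self.scaffold_lengths.items():
            bps = self.breakpoints.get(sid, [])
            if bps != sorted(bps) or len(set(bps)) != len(bps):
                raise ValueError(f"breakpoints for {sid} not sorted/unique")
            if bps and (bps[0] <= 0 or bps[-1] >= length):
                raise ValueError(f"breakpoints for {sid} outside (0, {length})")
            n += len(bps) + 1
        if n != self.x:
            raise ValueError(f"plan realizes {n} pieces, expected x={self.x}")

    def intervals(self, scaffold_id: str) -> list[tuple[int, int]]:
        """Half-open piece intervals tiling the scaffold, in order."""
        length = self.scaffold_lengths[scaffold_id]
        edges = [0, *self.breakpoints.get(scaffold_id, []), length]
        return list(zip(edges[:-1], edges[1:]))

    def realized_lengths(self) -> list[int]:
        out: list[int] = []
        for sid in self.scaffold_lengths:
            out.extend(e - s for s, e in self.intervals(sid))
        return out

    def contig_id(self, scaffold_id: str, index: int) -> str:
        return f"{scaffold_id}.{index}"

    def locate(self, scaffold_id: str, pos: int) -> tuple[str, int, int]:
        """Map a scaffold position to (contig id, piece index, offset on contig)."""
        length = self.scaffold_lengths[scaffold_id]
        if not (0 <= pos < length):
            raise ValueError(f"position {pos} outside scaffold {scaffold_id}")
        bps = self.breakpoints.get(scaffold_id, [])
        i = bisect.bisect_right(bps, pos)
        start = bps[i - 1] if i else 0
        return self.contig_id(scaffold_id, i), i, pos - start

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "x": self.x,
            "seed": self.seed,
            "scaffold_lengths": self.scaffold_lengths,
            "breakpoints": self.breakpoints,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "FragmentationPlan":
        payload = json.loads(text)
        return cls(
            x=int(payload["x"]),
            seed=int(payload["seed"]),
            scaffold_lengths={k: int(v) for k, v in payload["scaffold_lengths"].items()},
            breakpoints={k: [int(b) for b in v] for k, v in payload["breakpoints"].items()},
        )


# ---------------------------------------------------------------------------
# gap splitting and filtering

_GAP_RE_CACHE: dict[int, re.Pattern] = {}


def split_on_gaps(scaffold_id: str, sequence: str, min_gap: int = DEFAULT_MIN_GAP) -> list[Contig]:
    """Split a scaffold into contigs at N-runs of length >= ``min_gap``.

    Shorter N-runs are retained inside contigs; leading/trailing/empty pieces
    of pure gap are dropped.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    pat = _GAP_RE_CACHE.get(min_gap)
    if pat is None:
        pat = _GAP_RE_CACHE[min_gap] = re.compile("[Nn]{%d,}" % min_gap)
    contigs: list[Contig] = []
    prev = 0
    idx = 0
    for m in pat.finditer(sequence):
        if m.start() > prev:
            contigs.append(Contig(f"{scaffold_id}.{idx}", scaffold_id, prev,
                                  m.start(), sequence[prev:m.start()]))
            idx += 1
        prev = m.end()
    if prev < len(sequence):
        contigs.append(Contig(f"{scaffold_id}.{idx}", scaffold_id, prev,
                              len(sequence), sequence[prev:]))
    # a piece that is itself pure N (short run at an edge) is useless for
    # prediction; drop it
    return [c for c in contigs if set(c.sequence.upper()) - {"N"}]


def filter_short(contigs: Sequence[Contig], min_len: int = DEFAULT_MIN_CONTIG) -> list[Contig]:
    """Keep contigs of length >= ``min_len``, preserving order."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [c for c in contigs if len(c) >= min_len]
    if contigs and not kept:
        log.warning("filter_short(min_len=%d) removed all %d contigs", min_len, len(contigs))
    return kept


# ---------------------------------------------------------------------------
# planned fragmentation

def _largest_remainder(target_total: int, weights: np.ndarray, minimum: int = 0) -> np.ndarray:
    """Integer apportionment of ``target_total`` proportional to ``weights``.

    Each entry gets at least ``minimum``; the result sums exactly to
    ``target_total``.
    """
    n = len(weights)
    if target_total < n * minimum:
        raise ValueError("target_total too small for per-entry minimum")
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    spare = target_total - n * minimum
    raw = spare * w / w.sum()
    base = np.floor(raw).astype(np.int64)
    short = spare - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base + minimum


def plan_fragmentation(
    scaffolds: Mapping[str, str] | Mapping[str, int],
    template: Sequence[int],
    x: int,
    seed: int,
) -> FragmentationPlan:
    """Plan cutting a genome into exactly ``x`` pieces length-matched to a template.

    Takes the longest ``x`` template lengths, rescales them so that they sum
    to the genome length (largest-remainder rounding), deals the shuffled
    lengths to scaffolds proportionally to scaffold size, and rescales within
    each scaffold so pieces tile it exactly. Nothing is discarded.
    """
    lengths = {sid: (len(s) if isinstance(s, str) else int(s)) for sid, s in scaffolds.items()}
    if not lengths:
        raise ValueError("empty genome")
    if x > len(template):
        raise ValueError(f"x={x} exceeds template size {len(template)}")
    if x < len(lengths):
        raise ValueError(f"x={x} below scaffold count {len(lengths)}")
    total = sum(lengths.values())
    chosen = np.sort(np.asarray(template, dtype=np.int64))[::-1][:x]
    # rescale the template multiset onto this genome's total length
    rescaled = _largest_remainder(total, chosen, minimum=1)

    rng = np.random.default_rng(seed)
    shuffled = rescaled.copy()
    rng.shuffle(shuffled)

    sids = list(lengths)
    counts = _largest_remainder(x, np.array([lengths[s] for s in sids], dtype=float), minimum=1)
    breakpoints: dict[str, list[int]] = {}
    cursor = 0
    for sid, n_pieces in zip(sids, counts):
        piece_template = shuffled[cursor:cursor + n_pieces]
        cursor += n_pieces
        if n_pieces > lengths[sid]:
            raise ValueError(f"scaffold {sid} too short for {n_pieces} pieces")
        realized = _largest_remainder(lengths[sid], piece_template, minimum=1)
        edges = np.cumsum(realized)[:-1]
        breakpoints[sid] = [int(e) for e in edges]
    return FragmentationPlan(x=x, seed=seed, scaffold_lengths=lengths, breakpoints=breakpoints)


def nested_plans(
    scaffolds: Mapping[str, str] | Mapping[str, int],
    template: Sequence[int],
    xs: Sequence[int],
    seed: int,
) -> dict[int, FragmentationPlan]:
    """Plans for several ``x`` values whose breakpoints nest.

    The plan at ``max(xs)`` is built with :func:`plan_fragmentation`; smaller
    plans drop a seeded random subset of its breakpoints, so for x1 < x2 every
    breakpoint of the x1 plan appears in the x2 plan. Exact template matching
    holds only at the largest x.
    """
    xs = sorted(set(int(v) for v in xs))
    full = plan_fragmentation(scaffolds, template, xs[-1], seed)
    all_bps = [(sid, b) for sid, bps in full.breakpoints.items() for b in bps]
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(all_bps))
    n_scaff = len(full.scaffold_lengths)
    plans: dict[int, FragmentationPlan] = {}
    for x in xs:
        if x < n_scaff:
            raise ValueError(f"x={x} below scaffold count {n_scaff}")
        take = x - n_scaff
        keep = sorted(order[:take])
        bps: dict[str, list[int]] = {sid: [] for sid in full.scaffold_lengths}
        for i in keep:
            sid, b = all_bps[i]
            bps[sid].append(b)
        for sid in bps:
            bps[sid].sort()
        plans[x] = FragmentationPlan(x=x, seed=seed, scaffold_lengths=dict(full.scaffold_lengths),
                                     breakpoints=bps)
    return plans


def apply_fragmentation(scaffolds: Mapping[str, str], plan: FragmentationPlan) -> list[Contig]:
    """Cut scaffolds at the plan's breakpoints. Conserves every base."""
    if set(scaffolds) != set(plan.scaffold_lengths):
        raise ValueError("plan/genome scaffold ids differ")
    contigs: list[Contig] = []
    for sid, seq in scaffolds.items():
        if len(seq) != plan.scaffold_lengths[sid]:
            raise ValueError(f"scaffold {sid} length {len(seq)} != plan {plan.scaffold_lengths[sid]}")
        for i, (s, e) in enumerate(plan.intervals(sid)):
            contigs.append(Contig(plan.contig_id(sid, i), sid, s, e, seq[s:e]))
    return contigs


# ---------------------------------------------------------------------------
# reporting

def assembly_stats(contigs: Sequence[Contig] | Sequence[int]) -> dict:
    """Contig count, total length, N50 and a log10 length histogram.

    N50 is the smallest length at which the cumulative sum over contigs sorted
    descending reaches half the total.
    """
    lengths = np.asarray([len(c) if isinstance(c, Contig) else int(c) for c in contigs],
                         dtype=np.int64)
    if lengths.size == 0:
        return {"count": 0, "total_length": 0, "n50": 0, "length_histogram": {}}
    desc = np.sort(lengths)[::-1]
    cum = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(cum, cum[-1] / 2.0)])
    bins = np.floor(np.log10(np.maximum(lengths, 1))).astype(int)
    hist = {int(b): int(n) for b, n in zip(*np.unique(bins, return_counts=True))}
    return {
        "count": int(lengths.size),
        "total_length": int(lengths.sum()),
        "n50": n50,
        "length_histogram": hist,
    }
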