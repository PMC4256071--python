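"""Seeded generators for every input the pipeline needs.

Produces multi-scaffold genomes with multi-exon protein-coding genes and known
truth annotation, heavy-tailed template contig-length lists, draft annotations
carrying engineered split-allele and collapsed-paralog artifacts, and
paired-end cDNA read pairs with known gene of origin. All generators are
byte-deterministic for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import _dists
from ._dists import LengthDist
from .fragmenter import FragmentationPlan
from .prediction_emulator import GeneModel, reverse_complement

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


@dataclass(frozen=True)
class TrueGene:
    """A truth gene: ordered disjoint exon intervals on one scaffold.

    Intervals are 0-based half-open genomic coordinates, ascending regardless
    of strand. Total exonic length is divisible by 3 (one CDS per gene; no
    UTRs or isoforms are modeled).
    """

    id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    expression_level: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene must have >= 1 exon")
        for (a, b), (c, _) in zip(self.exons, self.exons[1:]):
            if b > c:
                raise ValueError("exons must be disjoint and ascending")
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if self.expression_level < 0:
            raise ValueError("expression_level must be >= 0")

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class SyntheticGenome:
    """Scaffolds plus their truth annotation."""

    scaffolds: dict[str, str]
    genes: list[TrueGene]

    def transcript(self, gene: TrueGene) -> str:
        """Spliced CDS in transcription order (5'->3')."""
        seq = "".join(self.scaffolds[gene.scaffold_id][a:b] for a, b in gene.exons)
        return seq if gene.strand == "+" else reverse_complement(seq)

    def validate(self) -> None:
        for g in self.genes:
            scaffold = self.scaffolds[g.scaffold_id]
            if g.exons[-1][1] > len(scaffold):
                raise AssertionError(f"{g.id} extends past scaffold end")
            t = self.transcript(g)
            if not t.startswith(START_CODON):
                raise AssertionError(f"{g.id} CDS does not start with ATG")
            if t[-3:] not in STOP_CODONS:
                raise AssertionError(f"{g.id} CDS does not end with a stop codon")
            internal = {t[i:i + 3] for i in range(0, len(t) - 3, 3)}
            if internal & set(STOP_CODONS):
                raise AssertionError(f"{g.id} has an internal in-frame stop")


@dataclass(frozen=True)
class TemplateLengths:
    """Descending list of template contig lengths."""

    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.lengths):
            raise ValueError("lengths must be positive")
        if list(self.lengths) != sorted(self.lengths, reverse=True):
            raise ValueError("lengths must be sorted descending")

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class Mate:
    """One aligned read end: spliced alignment blocks on a single contig."""

    contig_id: str
    blocks: tuple[tuple[int, int], ...]
    mapq: int = 60
    unique: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 60:
            raise ValueError("mapq must be in [0, 60]")
        if not self.blocks:
            raise ValueError("mate must have >= 1 block")

    @property
    def interval(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass(frozen=True)
class ReadPair:
    id: str
    gene_id: str
    mate1: Mate
    mate2: Mate

    @property
    def cross_contig(self) -> bool:
        return self.mate1.contig_id != self.mate2.contig_id


# ---------------------------------------------------------------------------
# genome generation

def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n non-stop codons with the requested GC bias."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out: list[str] = []
    while len(out) < n:
        draw = rng.choice(list("ACGT"), size=3 * (n - len(out)), p=p)
        for i in range(0, len(draw), 3):
            codon = "".join(draw[i:i + 3])
            if codon not in STOP_CODONS:
                out.append(codon)
    return "".join(out[:n])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def make_genome(
    n_genes: int,
    exons_per_gene: LengthDist = _dists.geometric(0.25),
    exon_length: LengthDist = _dists.uniform(90, 300),
    intron_length: LengthDist = _dists.uniform(60, 400),
    intergenic_length: LengthDist = _dists.uniform(200, 2000),
    gc: float = 0.42,
    n_scaffolds: int = 1,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate a multi-scaffold genome whose every gene is a valid ORF.

    Genes are laid down left to right with intergenic spacers; exon counts and
    exon/intron/intergenic lengths are drawn from the given distributions.
    Deterministic per seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    if not 1 <= n_scaffolds <= n_genes:
        raise ValueError("need 1 <= n_scaffolds <= n_genes")
    rng = np.random.default_rng(seed)

    per_scaffold = [n_genes // n_scaffolds + (1 if i < n_genes % n_scaffolds else 0)
                    for i in range(n_scaffolds)]
    scaffolds: dict[str, str] = {}
    genes: list[TrueGene] = []
    gidx = 0
    for si, count in enumerate(per_scaffold):
        sid = f"chr{si + 1}"
        parts: list[str] = []
        cursor = 0
        for _ in range(count):
            spacer = int(intergenic_length.sample(rng, 1)[0])
            parts.append(_random_seq(rng, spacer, gc))
            cursor += spacer

            n_exons = int(exons_per_gene.sample(rng, 1)[0])
            exon_lens = exon_length.sample(rng, n_exons).astype(int)
            # pad so the CDS has room for start+stop and is a codon multiple
            total = int(exon_lens.sum())
            exon_lens[-1] += (-total) % 3
            if exon_lens.sum() < 6:
                exon_lens[-1] += 6
            total = int(exon_lens.sum())
            n_codons = total // 3
            cds = START_CODON + _random_codons(rng, n_codons - 2, gc) \
                + STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
            intron_lens = intron_length.sample(rng, n_exons - 1).astype(int) \
                if n_exons > 1 else np.array([], dtype=int)

            # cassette in transcription order
            cassette_parts: list[str] = []
            local_exons: list[tuple[int, int]] = []
            pos = 0
            off = 0
            for i, el in enumerate(exon_lens):
                cassette_parts.append(cds[off:off + el])
                local_exons.append((pos, pos + int(el)))
                off += int(el)
                pos += int(el)
                if i < len(intron_lens):
                    il = int(intron_lens[i])
                    intron = "GT" + _random_seq(rng, max(il - 4, 0), gc) + "AG"
                    cassette_parts.append(intron)
                    pos += len(intron)
            cassette = "".join(cassette_parts)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                cassette = reverse_complement(cassette)
                L = len(cassette)
                local_exons = sorted((L - b, L - a) for a, b in local_exons)
            exons = tuple((cursor + a, cursor + b) for a, b in local_exons)
            genes.append(TrueGene(f"g{gidx:05d}", sid, strand, exons))
            gidx += 1
            parts.append(cassette)
            cursor += len(cassette)
        tail = int(intergenic_length.sample(rng, 1)[0])
        parts.append(_random_seq(rng, tail, gc))
        scaffolds[sid] = "".join(parts)
    genome = SyntheticGenome(scaffolds, genes)
    genome.validate()
    return genome


def make_template_lengths(
    n: int,
    law: LengthDist = _dists.lognormal(8.5, 1.2),
    min_len: int = 200,
    seed: int = 0,
) -> TemplateLengths:
    """Draw ``n`` template contig lengths, clipped at ``min_len``, descending."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.maximum(law.sample(rng, n), min_len)
    return TemplateLengths(tuple(int(v) for v in np.sort(vals)[::-1]))


# ---------------------------------------------------------------------------
# artifact annotations (split alleles / collapsed paralogs)

@dataclass
class ArtifactSet:
    """A draft assembly + annotation carrying engineered artifacts.

    ``reference`` is the (possibly extended) truth genome: collapsed cases add
    a real paralog to the truth that the draft annotation misses.
    ``draft_sequences`` are the draft's sequences (truth scaffolds plus one
    extra allele contig per split case); ``draft_models`` its gene models.
    ``labels`` records per case: kind, truth gene ids, draft model ids.
    """

    reference: SyntheticGenome
    draft_sequences: dict[str, str]
    draft_models: list[GeneModel]
    labels: list[dict]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform random substitutions at the given per-base rate."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.where(rng.random(len(arr)) < rate)[0]
    alphabet = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    for i in hit:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _mutate_orf(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Substitutions that keep the CDS a valid ORF.

    Start and final stop codons are untouched; a substitution that would turn
    an internal codon into a stop is reverted.
    """
    out = list(cds)
    for i in np.nonzero(rng.random(len(out)) < rate)[0]:
        if i < 3 or i >= len(out) - 3:
            continue
        old = out[i]
        choices = [b for b in "ACGT" if b != old]
        out[i] = choices[int(rng.integers(3))]
        c0 = 3 * (i // 3)
        if "".join(out[c0:c0 + 3]) in STOP_CODONS:
            out[i] = old
    return "".join(out)


def _gene_as_model(gene: TrueGene, contig_id: str, offset: int = 0,
                   model_id: str | None = None) -> GeneModel:
    exons = tuple((a - offset, b - offset) for a, b in gene.exons)
    return GeneModel(model_id or gene.id, contig_id, gene.strand, exons,
                     has_start=True, has_stop=True, provenance=gene.id)


def make_artifact_annotation(
    genome: SyntheticGenome,
    n_split: int,
    n_collapsed: int,
    divergence: float = 0.01,
    seed: int = 0,
) -> ArtifactSet:
    """Engineer split-allele and collapsed-paralog artifacts with truth labels.

    Split: a gene's full cassette (exons + introns) is copied onto its own
    extra contig with substitutions at ``divergence``, and the draft annotates
    both copies — one truth gene, two near-identical draft models.

    Collapsed: a diverged copy of a gene's cassette is appended to its
    scaffold and added to the truth annotation as a genuine paralog, but the
    draft annotates only the original — two truth paralogs, one draft model.
    """
    if not 0.0 <= divergence <= 0.05:
        raise ValueError("divergence must be in [0, 0.05] (alleles are near-identical)")
    if n_split < 0 or n_collapsed < 0:
        raise ValueError("artifact counts must be >= 0")
    if n_split + n_collapsed > len(genome.genes):
        raise ValueError("more artifacts requested than truth genes")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(genome.genes), size=n_split + n_collapsed, replace=False)
    split_idx = set(int(i) for i in picked[:n_split])
    collapsed_idx = set(int(i) for i in picked[n_split:])

    scaffolds = dict(genome.scaffolds)
    truth_genes = list(genome.genes)
    draft_sequences = dict(genome.scaffolds)
    draft_models: list[GeneModel] = []
    labels: list[dict] = []

    for i, gene in enumerate(genome.genes):
        draft_models.append(_gene_as_model(gene, gene.scaffold_id))
        lo, hi = gene.span
        cassette = genome.scaffolds[gene.scaffold_id][lo:hi]
        if i in split_idx:
            allele_contig = f"allele_{gene.id}"
            draft_sequences[allele_contig] = _mutate(cassette, divergence, rng)
            copy = GeneModel(f"{gene.id}_allele", allele_contig, gene.strand,
                             tuple((a - lo, b - lo) for a, b in gene.exons),
                             has_start=True, has_stop=True, provenance=gene.id)
            draft_models.append(copy)
            labels.append({"kind": "split", "truth_genes": [gene.id],
                           "draft_models": [gene.id, copy.id]})
        elif i in collapsed_idx:
            sid = gene.scaffold_id
            offset = len(scaffolds[sid])
            # introns mutate freely; the CDS mutates ORF-safely so the paralog
            # is a legitimate truth gene
            copy_arr = list(_mutate(cassette, divergence, rng))
            new_cds = _mutate_orf(genome.transcript(gene), divergence, rng)
            if gene.strand == "-":
                new_cds = reverse_complement(new_cds)
            pos = 0
            for a, b in gene.exons:
                copy_arr[a - lo:b - lo] = new_cds[pos:pos + (b - a)]
                pos += b - a
            paralog_seq = "".join(copy_arr)
            scaffolds[sid] = scaffolds[sid] + paralog_seq
            # keep the draft sequence identical to the extended truth scaffold:
            # the paralog is assembled (collapse is an annotation-level miss here)
            draft_sequences[sid] = scaffolds[sid]
            paralog = TrueGene(f"{gene.id}_par", sid, gene.strand,
                               tuple((a - lo + offset, b - lo + offset) for a, b in gene.exons),
                               expression_level=gene.expression_level)
            truth_genes.append(paralog)
            labels.append({"kind": "collapsed", "truth_genes": [gene.id, paralog.id],
                           "draft_models": [gene.id]})
        else:
            labels.append({"kind": "normal", "truth_genes": [gene.id],
                           "draft_models": [gene.id]})
    reference = SyntheticGenome(scaffolds, truth_genes)
    return ArtifactSet(reference, draft_sequences, draft_models, labels)


# ---------------------------------------------------------------------------
# paired-end cDNA reads

def _project_transcript_interval(
    gene: TrueGene, t_start: int, t_end: int,
) -> list[tuple[int, int]]:
    """Map a transcript interval to genomic blocks (ascending)."""
    blocks: list[tuple[int, int]] = []
    if gene.strand == "+":
        offset = 0
        for a, b in gene.exons:
            el = b - a
            s, e = max(t_start - offset, 0), min(t_end - offset, el)
            if s < e:
                blocks.append((a + s, a + e))
            offset += el
    else:
        tlen = gene.cds_length
        # transcript position t corresponds to genomic ascending position
        # measured from the right end of the exon chain
        s2, e2 = tlen - t_end, tlen - t_start
        offset = 0
        for a, b in gene.exons:
            el = b - a
            s, e = max(s2 - offset, 0), min(e2 - offset, el)
            if s < e:
                blocks.append((a + s, a + e))
            offset += el
    return blocks


def make_read_pairs(
    genome: SyntheticGenome,
    plan: FragmentationPlan,
    n_pairs: int,
    fragment_length: LengthDist = _dists.uniform(250, 500),
    read_length: int = 75,
    seed: int = 0,
) -> list[ReadPair]:
    """Sample paired-end cDNA fragments and place them on the plan's contigs.

    Genes are sampled proportionally to ``expression_level``; each fragment
    lies on the spliced transcript and the two read ends are projected through
    exons into contig coordinates. A read end whose genomic blocks span a
    breakpoint is unmappable and the draw is rejected. Deterministic per seed.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    weights = np.array([g.expression_level for g in genome.genes], dtype=float)
    usable = [(g, w) for g, w in zip(genome.genes, weights)
              if w > 0 and g.cds_length >= 2 * read_length]
    if n_pairs and not usable:
        raise ValueError("no expressed gene long enough for the read length")
    if n_pairs == 0:
        return []
    glist = [g for g, _ in usable]
    p = np.array([w for _, w in usable], dtype=float)
    p /= p.sum()
    rng = np.random.default_rng(seed)

    pairs: list[ReadPair] = []
    attempts = 0
    max_attempts = 50 * n_pairs + 1000
    while len(pairs) < n_pairs and attempts < max_attempts:
        attempts += 1
        gene = glist[int(rng.choice(len(glist), p=p))]
        tlen = gene.cds_length
        flen = int(fragment_length.sample(rng, 1)[0])
        if flen < 2 * read_length:
            raise ValueError("fragment size shorter than two read lengths")
        flen = min(flen, tlen)
        start = int(rng.integers(0, tlen - flen + 1))
        mates: list[Mate] = []
        ok = True
        ends = ((start, start + read_length), (start + flen - read_length, start + flen))
        for t_s, t_e in ends:
            gblocks = _project_transcript_interval(gene, t_s, t_e)
            placed: list[tuple[int, int]] = []
            cids = set()
            for a, b in gblocks:
                cid_a, idx_a, off_a = plan.locate(gene.scaffold_id, a)
                cid_b, idx_b, _ = plan.locate(gene.scaffold_id, b - 1)
                if cid_a != cid_b:
                    ok = False  # block itself crosses a breakpoint
                    break
                cids.add(cid_a)
                placed.append((off_a, off_a + (b - a)))
            if not ok or len(cids) != 1:
                ok = False
                break
            mates.append(Mate(cids.pop(), tuple(sorted(placed))))
        if not ok:
            continue
        pid = f"pair{len(pairs):07d}"
        pairs.append(ReadPair(pid, gene.id, mates[0], mates[1]))
    if len(pairs) < n_pairs:
        raise RuntimeError(
            f"could only place {len(pairs)}/{n_pairs} pairs; genome too fragmented "
            "for the requested fragment sizes")
    return pairs
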