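import numpy as np
import pytest

from draftgauge import _dists
from draftgauge.fragmenter import FragmentationPlan, apply_fragmentation, plan_fragmentation
from draftgauge.synthetic_data import make_genome, make_template_lengths


@pytest.fixture(scope="session")
def small_genome():
    """30 genes on 2 scaffolds; multi-exon guaranteed for half the tests' needs."""
    return make_genome(30, n_scaffolds=2, seed=11)


@pytest.fixture(scope="session")
def multiexon_genome():
    """Every gene has 2-6 exons (so any gene can be cleaved through an intron)."""
    return make_genome(
        60,
        exons_per_gene=_dists.uniform(2, 6),
        n_scaffolds=2,
        seed=23,
    )


@pytest.fixture(scope="session")
def template():
    return make_template_lengths(400, seed=1)


@pytest.fixture(scope="session")
def small_plan(small_genome, template):
    return plan_fragmentation(small_genome.scaffolds, template.lengths, 60, seed=3)


@pytest.fixture(scope="session")
def small_contigs(small_genome, small_plan):
    return apply_fragmentation(small_genome.scaffolds, small_plan)


def intron_breakpoint_plan(genome, target_gene_ids):
    """A plan cutting each target gene once, through its middle intron.

    Deterministic alternative to template-driven planning for tests that need
    specific genes cleaved into exactly two exon-bearing fragments.
    """
    by_id = {g.id: g for g in genome.genes}
    breakpoints = {sid: [] for sid in genome.scaffolds}
    for gid in target_gene_ids:
        g = by_id[gid]
        assert len(g.exons) >= 2, f"{gid} has a single exon; cannot cut an intron"
        mid = len(g.exons) // 2
        intron = (g.exons[mid - 1][1], g.exons[mid][0])
        breakpoints[g.scaffold_id].append((intron[0] + intron[1]) // 2)
    for sid in breakpoints:
        breakpoints[sid].sort()
    lengths = {sid: len(s) for sid, s in genome.scaffolds.items()}
    x = len(lengths) + sum(len(b) for b in breakpoints.values())
    return FragmentationPlan(x=x, seed=0, scaffold_lengths=lengths, breakpoints=breakpoints)
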