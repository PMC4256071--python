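import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from draftgauge.prediction_emulator import GeneModel
from draftgauge.rnaseq_linker import (ConnectionGraph, build_connection_graph,
                                      correction_curves, filter_alignments,
                                      merge_models, recovery_report)
from draftgauge.synthetic_data import Mate, ReadPair

from conftest import intron_breakpoint_plan


def _model(mid, contig, exons=((0, 100),), provenance="unknown"):
    return GeneModel(mid, contig, "+", tuple(exons), True, True, provenance)


def _pair(pid, c1, iv1, c2, iv2, mapq=60, unique=True, gene="g"):
    return ReadPair(pid, gene,
                    Mate(c1, (iv1,), mapq=mapq, unique=unique),
                    Mate(c2, (iv2,), mapq=mapq, unique=unique))


class TestFilterAlignments:
    def test_good_pair_kept(self):
        p = _pair("p", "c1", (0, 75), "c2", (0, 75))
        assert filter_alignments([p]) == [p]

    def test_low_mapq_dropped(self):
        p = _pair("p", "c1", (0, 75), "c2", (0, 75), mapq=0)
        assert filter_alignments([p]) == []

    def test_engineered_multimappers_dropped_exactly(self):
        pairs = [_pair(f"u{i}", "c1", (0, 75), "c2", (0, 75)) for i in range(900)]
        pairs += [_pair(f"m{i}", "c1", (0, 75), "c2", (0, 75), unique=False)
                  for i in range(100)]
        assert len(filter_alignments(pairs, require_unique=True)) == 900
        assert len(filter_alignments(pairs, require_unique=False)) == 1000


class TestBuildConnectionGraph:
    MODELS = [_model("g1", "c1"), _model("g2", "c2"), _model("g3", "c2", exons=((200, 300),))]

    def test_same_model_no_edge(self):
        g = build_connection_graph([_pair("p", "c1", (0, 50), "c1", (50, 100))], self.MODELS)
        assert g.support == {}
        assert g.skipped.get("same_model") == 1

    def test_cross_contig_edge_support(self):
        pairs = [_pair("p1", "c1", (0, 50), "c2", (0, 50)),
                 _pair("p2", "c1", (10, 60), "c2", (10, 60))]
        g = build_connection_graph(pairs, self.MODELS)
        assert g.support == {frozenset({"g1", "g2"}): 2}

    def test_same_contig_models_not_connected(self):
        p = _pair("p", "c2", (0, 50), "c2", (210, 260))
        g = build_connection_graph([p], self.MODELS)
        assert g.support == {}
        assert g.skipped.get("same_contig") == 1

    def test_unknown_contig_skipped_and_counted(self):
        p = _pair("p", "cX", (0, 50), "c2", (0, 50))
        g = build_connection_graph([p], self.MODELS)
        assert g.support == {}
        assert g.skipped.get("unknown_contig") == 1

    def test_non_exonic_mate_skipped(self):
        p = _pair("p", "c2", (150, 190), "c1", (0, 50))  # c2 interval hits no exon
        g = build_connection_graph([p], self.MODELS)
        assert g.support == {}
        assert g.skipped.get("no_exon_overlap") == 1


def _graph(edges, nodes):
    support = {frozenset((a, b)): s for a, b, s in edges}
    return ConnectionGraph(nodes=set(nodes), support=support, skipped={})


class TestMergeModels:
    def test_threshold_drops_weak_edge(self):
        models = [_model(m, f"c_{m}") for m in "ABC"]
        g = _graph([("A", "B", 3), ("B", "C", 1)], "ABC")
        merge = merge_models(g, models, k=2)
        assert merge.groups == [{"A", "B"}]
        assert merge.revised_count == 2
        assert merge.reduction == 1

    def test_chain_transitivity(self):
        models = [_model(m, f"c_{m}") for m in "ABC"]
        g = _graph([("A", "B", 1), ("B", "C", 1)], "ABC")
        merge = merge_models(g, models, k=1)
        assert merge.groups == [{"A", "B", "C"}]
        assert merge.reduction == 2

    def test_empty_graph_identity(self):
        models = [_model(m, f"c_{m}") for m in "ABCD"]
        merge = merge_models(_graph([], "ABCD"), models, k=1)
        assert merge.revised_count == 4 and merge.reduction == 0

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            merge_models(_graph([], ""), [], k=0)

    @given(st.integers(min_value=0, max_value=400), st.integers(min_value=1, max_value=5),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence_random_graphs(self, n_edges, k, seed):
        # union-find vs networkx connected components on graphs <= 200 nodes
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(200)]
        models = [_model(m, f"c_{m}") for m in nodes]
        edges = []
        for _ in range(n_edges):
            a, b = rng.choice(200, size=2, replace=False)
            edges.append((nodes[a], nodes[b], int(rng.integers(1, 6))))
        support = {}
        for a, b, s in edges:
            support[frozenset((a, b))] = support.get(frozenset((a, b)), 0) + s
        graph = ConnectionGraph(set(nodes), support, {})
        merge = merge_models(graph, models, k=k)

        G = nx.Graph()
        G.add_nodes_from(nodes)
        G.add_edges_from((a, b) for e, s in support.items() if s >= k for a, b in [tuple(e)])
        comps = [c for c in nx.connected_components(G) if len(c) >= 2]
        assert sorted(map(sorted, merge.groups)) == sorted(map(sorted, comps))
        assert merge.revised_count + len(models) - merge.revised_count == len(models)
        assert merge.revised_count == len(models) - sum(len(c) - 1 for c in comps)


class TestCorrectionCurves:
    def _setup(self):
        models = [_model(m, f"c_{m}") for m in "ABCD"]
        ds1 = [_pair("p1", "c_A", (0, 50), "c_B", (0, 50))]
        ds2 = [_pair("p2", "c_A", (0, 50), "c_B", (0, 50)),
               _pair("p3", "c_C", (0, 50), "c_D", (0, 50))]
        return models, ds1, ds2

    def test_duplicate_dataset_adds_nothing(self):
        models, ds1, _ = self._setup()
        cumulative, _ = correction_curves([ds1, ds1], models)
        assert list(cumulative["revised_gene_count"]) == [3, 3]
        assert list(cumulative["reduction"]) == [1, 0]

    def test_cumulative_revised_monotone_non_increasing(self):
        models, ds1, ds2 = self._setup()
        cumulative, _ = correction_curves([ds1, ds2], models)
        revised = list(cumulative["revised_gene_count"])
        assert revised == sorted(revised, reverse=True)
        assert list(cumulative["cumulative_reduction"]) == \
            [len(models) - r for r in revised]

    def test_threshold_collapsed_non_increasing_in_k(self):
        models, ds1, ds2 = self._setup()
        _, threshold = correction_curves([ds1, ds2, ds2], models, k_range=range(1, 6))
        collapsed = list(threshold["collapsed"])
        assert collapsed == sorted(collapsed, reverse=True)
        revised = list(threshold["revised_gene_count"])
        assert revised == sorted(revised)

    def test_requires_a_dataset(self):
        with pytest.raises(ValueError):
            correction_curves([], [])


class TestRecoveryReport:
    def test_no_reads_misses_all_cleaved(self):
        models = [_model("g1a", "c1", provenance="g1"), _model("g1b", "c2", provenance="g1"),
                  _model("g2", "c3", provenance="g2")]
        merge = merge_models(_graph([], [m.id for m in models]), models, k=1)
        rep = recovery_report(merge, {m.id: m.provenance for m in models})
        assert rep["correct_merges"] == 0
        assert rep["missed_fragmented_genes"] == ["g1"]

    def test_perfect_merge(self):
        models = [_model("g1a", "c1", provenance="g1"), _model("g1b", "c2", provenance="g1")]
        g = _graph([("g1a", "g1b", 4)], ["g1a", "g1b"])
        rep = recovery_report(merge_models(g, models, k=1),
                              {m.id: m.provenance for m in models})
        assert rep == {"correct_merges": 1, "incorrect_merges": 0,
                       "missed_fragmented_genes": []}

    def test_incorrect_merge_detected(self):
        models = [_model("a", "c1", provenance="g1"), _model("b", "c2", provenance="g2")]
        g = _graph([("a", "b", 1)], ["a", "b"])
        rep = recovery_report(merge_models(g, models, k=1),
                              {m.id: m.provenance for m in models})
        assert rep["incorrect_merges"] == 1

    def test_missing_provenance_rejected(self):
        models = [_model("a", "c1"), _model("b", "c2")]
        g = _graph([("a", "b", 1)], ["a", "b"])
        with pytest.raises(ValueError):
            recovery_report(merge_models(g, models, k=1), {"a": "g1"})


class TestSplitAllelesUnfixable:
    def test_split_allele_models_gain_no_edges(self, multiexon_genome):
        # reads come from the genome; both split-allele copies are full-length
        # on their own contigs, so no cross-contig pair can involve them
        from draftgauge.synthetic_data import make_artifact_annotation, make_read_pairs
        art = make_artifact_annotation(multiexon_genome, n_split=5, n_collapsed=0, seed=3)
        targets = [multiexon_genome.genes[0].id]
        plan = intron_breakpoint_plan(multiexon_genome, targets)
        from draftgauge.prediction_emulator import project_annotation
        models = project_annotation(multiexon_genome.genes, plan)
        split_models = [m for m in art.draft_models if m.id.endswith("_allele")]
        all_models = models + split_models
        pairs = make_read_pairs(multiexon_genome, plan, 1500, seed=4)
        graph = build_connection_graph(filter_alignments(pairs), all_models)
        merge = merge_models(graph, all_models, k=1)
        touched = {m for g in merge.groups for m in g}
        assert not touched & {m.id for m in split_models}
        assert any(m.id in touched for m in models if m.provenance == targets[0])
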