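import itertools

import numpy as np
import pytest

from draftgauge.family_clustering import (FamilySizeDelta, GeneFamily, SimilarityHit,
                                          align_pair, all_vs_all_similarity,
                                          build_families, compare_family_sizes,
                                          family_id, mcl_cluster)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAllVsAllSimilarity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        s = _random_seq(rng, 300)
        hits = all_vs_all_similarity({"a": s, "b": s})
        assert len(hits) == 2
        h = hits[0]
        assert h.identity == pytest.approx(100.0)
        assert h.query_coverage == pytest.approx(1.0)
        assert h.subject_coverage == pytest.approx(1.0)

    def test_unrelated_sequences_no_hit(self):
        rng = np.random.default_rng(1)
        seqs = {"a": _random_seq(rng, 1000), "b": _random_seq(rng, 1000)}
        assert all_vs_all_similarity(seqs) == []

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        base = _random_seq(rng, 400)
        seqs = {"a": base, "b": base[:250], "c": _random_seq(rng, 400)}
        hits = all_vs_all_similarity(seqs, min_score=10)
        pairs = {(h.query, h.subject): h.score for h in hits}
        for (q, s), score in pairs.items():
            assert pairs[(s, q)] == score

    def test_fragment_containment_scores_high(self):
        rng = np.random.default_rng(3)
        base = _random_seq(rng, 600)
        hits = all_vs_all_similarity({"full": base, "frag": base[100:300]})
        assert hits and hits[0].score > 90

    def test_kmer_method(self):
        rng = np.random.default_rng(4)
        base = _random_seq(rng, 300)
        hits = all_vs_all_similarity({"a": base, "b": base}, method="kmer-jaccard")
        assert hits[0].score == pytest.approx(100.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            all_vs_all_similarity({"a": "ACGT"})
        with pytest.raises(ValueError):
            all_vs_all_similarity({"a": "ACGT", "b": ""})
        with pytest.raises(ValueError):
            all_vs_all_similarity({"a": "ACGT", "b": "ACGT"}, method="blast")

    def test_hit_field_invariants(self):
        with pytest.raises(ValueError):
            SimilarityHit("a", "b", 120.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            SimilarityHit("a", "b", 50.0, 1.5, 1.0, 1.0)


def _clique_hits(nodes, weight=10.0):
    hits = []
    for a, b in itertools.combinations(nodes, 2):
        hits.append(SimilarityHit(a, b, 100, 1, 1, weight))
        hits.append(SimilarityHit(b, a, 100, 1, 1, weight))
    return hits


class TestMclCluster:
    def test_two_disjoint_cliques(self):
        hits = _clique_hits(["a1", "a2", "a3"]) + _clique_hits(["b1", "b2", "b3"])
        clusters = mcl_cluster(hits)
        assert sorted(sorted(c) for c in clusters) == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]

    def test_single_edge(self):
        hits = [SimilarityHit("a", "b", 100, 1, 1, 5.0),
                SimilarityHit("b", "a", 100, 1, 1, 5.0)]
        assert mcl_cluster(hits) == [{"a", "b"}]

    def test_barbell_splits_at_weak_bridge(self):
        # two 4-cliques joined by one weak edge; verified against an
        # independently coded expansion/inflation iteration (see oracle below)
        left, right = ["l1", "l2", "l3", "l4"], ["r1", "r2", "r3", "r4"]
        hits = _clique_hits(left) + _clique_hits(right)
        hits += [SimilarityHit("l1", "r1", 100, 1, 1, 0.5),
                 SimilarityHit("r1", "l1", 100, 1, 1, 0.5)]
        clusters = mcl_cluster(hits, inflation=2.0)
        assert sorted(sorted(c) for c in clusters) == [left, right]
        assert _mcl_oracle(hits) == [set(left), set(right)]

    def test_inflation_limits_vs_connected_components(self):
        # clusters always refine connected components (they can never merge
        # two components); as inflation -> 1 the flow mixes freely and the
        # clustering converges to the components themselves
        import networkx as nx
        rng = np.random.default_rng(7)
        G = nx.gnp_random_graph(25, 0.08, seed=3)
        hits = []
        for a, b in G.edges:
            w = float(rng.uniform(1, 10))
            hits.append(SimilarityHit(f"n{a}", f"n{b}", 100, 1, 1, w))
            hits.append(SimilarityHit(f"n{b}", f"n{a}", 100, 1, 1, w))
        nodes = [f"n{i}" for i in G.nodes]
        comps = [set(f"n{i}" for i in c) for c in nx.connected_components(G)]
        for inflation in (1.05, 2.0, 20.0):
            clusters = mcl_cluster(hits, inflation=inflation, nodes=nodes)
            for cluster in clusters:
                assert any(cluster <= comp for comp in comps)
        near_one = mcl_cluster(hits, inflation=1.05, nodes=nodes)
        assert sorted(map(sorted, near_one)) == sorted(map(sorted, comps))

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(30)]
        hits = []
        for _ in range(60):
            a, b = rng.choice(nodes, size=2, replace=False)
            w = float(rng.uniform(1, 5))
            hits.append(SimilarityHit(a, b, 100, 1, 1, w))
            hits.append(SimilarityHit(b, a, 100, 1, 1, w))
        clusters = mcl_cluster(hits, nodes=nodes)
        flat = [n for c in clusters for n in c]
        assert sorted(flat) == sorted(nodes)

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster([], inflation=1.0)

    def test_isolated_nodes_become_singletons(self):
        clusters = mcl_cluster([], nodes=["x", "y"])
        assert sorted(map(sorted, clusters)) == [["x"], ["y"]]


def _mcl_oracle(hits, inflation=2.0, iters=60):
    """Independent plain-numpy Markov clustering for cross-checking."""
    nodes = sorted({h.query for h in hits} | {h.subject for h in hits})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for h in hits:
        A[idx[h.query], idx[h.subject]] = h.score
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, A.max(axis=1))
    M = A / A.sum(axis=0)
    for _ in range(iters):
        M = M @ M
        M = M ** inflation
        M = M / M.sum(axis=0)
        M[M < 1e-12] = 0.0
    groups = {}
    seen = set()
    clusters = []
    for i in range(n):
        if i in seen:
            continue
        members = set(np.nonzero(M[:, i] > 1e-6)[0]) | {i}
        # expand transitively over shared attractors
        changed = True
        while changed:
            changed = False
            for j in range(n):
                if j in members:
                    continue
                if members & (set(np.nonzero(M[:, j] > 1e-6)[0]) | {j}):
                    members.add(j)
                    changed = True
        seen |= members
        clusters.append({nodes[i] for i in members})
    return sorted(clusters, key=lambda c: sorted(c)[0])


class TestFamiliesAndDeltas:
    def _families(self):
        labels = {"d1": "draft", "d2": "draft", "d3": "draft", "r1": "ref", "r2": "ref"}
        return build_families([{"d1", "d2", "d3", "r1", "r2"}], labels)

    def test_excess_delta(self):
        (fam,) = self._families()
        deltas, _ = compare_family_sizes([fam], "draft", "ref")
        assert deltas[0].delta == 1

    def test_all_equal_gives_all_zero(self):
        labels = {f"d{i}": "draft" for i in range(4)} | {f"r{i}": "ref" for i in range(4)}
        fams = build_families([{f"d{i}", f"r{i}"} for i in range(4)], labels)
        deltas, hist = compare_family_sizes(fams, "draft", "ref")
        assert all(d.delta == 0 for d in deltas)
        assert hist["0"] == 4

    def test_histogram_sums_to_family_count(self):
        (fam,) = self._families()
        _, hist = compare_family_sizes([fam], "draft", "ref")
        assert sum(hist.values()) == 1

    def test_tails_collapsed_not_dropped(self):
        labels = {f"d{i}": "draft" for i in range(6)} | {"r0": "ref"}
        fams = build_families([{f"d{i}" for i in range(6)} | {"r0"}], labels)
        _, hist = compare_family_sizes(fams, "draft", "ref")
        assert hist[">3"] == 1

    def test_unknown_label_rejected(self):
        (fam,) = self._families()
        with pytest.raises(ValueError):
            compare_family_sizes([fam], "draft", "nope")

    def test_family_id_content_addressed(self):
        assert family_id(["b", "a"]) == family_id(["a", "b"])
        assert family_id(["a"]) != family_id(["a", "b"])


class TestEndToEndRecovery:
    def test_artifact_free_families_recovered(self, multiexon_genome):
        # no artifacts: each truth gene should form exactly one draft+ref family
        from draftgauge.prediction_emulator import model_sequence
        from draftgauge.synthetic_data import make_artifact_annotation
        art = make_artifact_annotation(multiexon_genome, 0, 0, seed=0)
        seqs, labels = {}, {}
        for m in art.draft_models:
            seqs[f"D:{m.id}"] = model_sequence(m, art.draft_sequences)
            labels[f"D:{m.id}"] = "draft"
        for g in art.reference.genes:
            seqs[f"R:{g.id}"] = art.reference.transcript(g)
            labels[f"R:{g.id}"] = "ref"
        hits = all_vs_all_similarity(seqs)
        fams = build_families(mcl_cluster(hits, nodes=list(seqs)), labels)
        exact = sum(1 for f in fams
                    if len(f.members) == 2 and f.count("draft") == 1 and f.count("ref") == 1)
        assert exact / len(multiexon_genome.genes) >= 0.99
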