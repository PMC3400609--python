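"""Shared-neighbor clustering: kernels, graph building, partitions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_cluster, brute_weighted_jaccard
from tbdtscan import (PairwiseMatch, build_match_graph, cluster,
                      lek_similarity)
from tbdtscan.clustering import MatchNeighborhood


def _match(q, s, evalue, bits=100.0):
    return PairwiseMatch(q, s, 50.0, bits, evalue, 90.0, 100)


def _random_neighborhoods(rng, n_seqs):
    """Random weighted neighborhoods with self-matches, symmetric."""
    ids = [f"s{i}" for i in range(n_seqs)]
    nbh = {i: {i: float(rng.integers(50, 200))} for i in ids}
    for i in range(n_seqs):
        for j in range(i + 1, n_seqs):
            if rng.random() < 0.35:
                score = float(rng.integers(40, 160))
                nbh[ids[i]][ids[j]] = score
                nbh[ids[j]][ids[i]] = score
    return nbh


def _as_graph(nbh):
    return {k: MatchNeighborhood(k, dict(v)) for k, v in nbh.items()}


class TestBuildMatchGraph:
    def test_pair_below_cutoff_kept(self):
        matches = [_match("a", "a", 0.0), _match("b", "b", 0.0),
                   _match("a", "b", 1e-50), _match("b", "a", 1e-50)]
        graph = build_match_graph(matches, 1e-40)
        assert set(graph["a"].neighbors) == {"a", "b"}
        assert set(graph["b"].neighbors) == {"a", "b"}

    def test_pair_above_cutoff_dropped(self):
        matches = [_match("a", "a", 0.0), _match("b", "b", 0.0),
                   _match("a", "b", 1e-10), _match("b", "a", 1e-10)]
        graph = build_match_graph(matches, 1e-40)
        assert set(graph["a"].neighbors) == {"a"}
        assert set(graph["b"].neighbors) == {"b"}

    def test_symmetrized_if_either_direction_passes(self):
        matches = [_match("a", "a", 0.0), _match("b", "b", 0.0),
                   _match("a", "b", 1e-50), _match("b", "a", 1e-10)]
        graph = build_match_graph(matches, 1e-40)
        assert "b" in graph["a"].neighbors and "a" in graph["b"].neighbors

    def test_neighborhoods_equal_direct_filter(self, rng):
        """On a random 10-sequence instance the neighborhoods equal a
        direct filter of the match list."""
        ids = [f"s{i}" for i in range(10)]
        matches, expected = [], {i: {i} for i in ids}
        for i in ids:
            matches.append(_match(i, i, 0.0))
        for a in ids:
            for b in ids:
                if a < b:
                    ev = 10.0 ** -rng.integers(0, 80)
                    matches.append(_match(a, b, ev))
                    if ev <= 1e-40:
                        expected[a].add(b)
                        expected[b].add(a)
        graph = build_match_graph(matches, 1e-40)
        assert {k: set(v.neighbors) for k, v in graph.items()} == expected

    def test_unknown_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_match_graph([_match("a", "zzz", 1e-50)], 1e-40,
                              seq_ids=["a", "b"])


class TestLekSimilarity:
    def test_identical_neighborhoods_score_one(self):
        a = MatchNeighborhood("a", {"x": 10.0, "y": 20.0})
        b = MatchNeighborhood("b", {"x": 10.0, "y": 20.0})
        assert lek_similarity(a, b) == pytest.approx(1.0)

    def test_disjoint_neighborhoods_score_zero(self):
        a = MatchNeighborhood("a", {"x": 10.0})
        b = MatchNeighborhood("b", {"y": 10.0})
        assert lek_similarity(a, b) == 0.0

    def test_hand_evaluated_kernel_value(self):
        """{x:10, y:10} vs {x:10, z:10} = min-overlap 10 over union 30."""
        a = MatchNeighborhood("a", {"x": 10.0, "y": 10.0})
        b = MatchNeighborhood("b", {"x": 10.0, "z": 10.0})
        assert lek_similarity(a, b) == pytest.approx(10.0 / 30.0)

    @given(st.integers(0, 5000))
    @settings(max_examples=40, deadline=None)
    def test_symmetry_and_range_all_kernels(self, seed):
        rng = np.random.default_rng(seed)
        nbh = _random_neighborhoods(rng, 6)
        graph = _as_graph(nbh)
        ids = sorted(graph)
        for kernel in ("weighted_jaccard", "jaccard", "cosine"):
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    sij = lek_similarity(graph[ids[i]], graph[ids[j]], kernel)
                    sji = lek_similarity(graph[ids[j]], graph[ids[i]], kernel)
                    assert sij == pytest.approx(sji)
                    assert 0.0 <= sij <= 1.0 + 1e-12

    def test_matches_independent_kernel_oracle(self, rng):
        nbh = _random_neighborhoods(rng, 8)
        graph = _as_graph(nbh)
        for a in nbh:
            for b in nbh:
                assert lek_similarity(graph[a], graph[b]) == pytest.approx(
                    brute_weighted_jaccard(nbh[a], nbh[b]))


class TestCluster:
    def test_mutually_similar_triple_clusters_together(self):
        nbh = {i: {j: 100.0 for j in "abc"} for i in "abc"}
        part = cluster(_as_graph(nbh), 0.6)
        assert part.clusters == [("a", "b", "c")]

    def test_chain_merges_transitively(self):
        # a-b and b-c overlap strongly, a-c barely: still one component.
        nbh = {
            "a": {"a": 100.0, "b": 100.0, "x": 100.0, "y": 100.0},
            "b": {"a": 100.0, "b": 100.0, "c": 100.0, "x": 100.0, "y": 100.0},
            "c": {"b": 100.0, "c": 100.0, "x": 100.0, "y": 100.0},
        }
        graph = _as_graph(nbh)
        assert lek_similarity(graph["a"], graph["c"]) < \
            lek_similarity(graph["a"], graph["b"])
        part = cluster(graph, 0.6)
        assert part.clusters == [("a", "b", "c")]

    def test_matches_brute_force_union_find(self, rng):
        """Random 12-node instances partition identically to brute-force
        union-find over all pairwise similarities."""
        for _ in range(20):
            nbh = _random_neighborhoods(rng, 12)
            part = cluster(_as_graph(nbh), 0.6)
            assert {frozenset(c) for c in part.clusters} == \
                brute_cluster(nbh, 0.6)

    def test_permutation_invariance(self, rng):
        nbh = _random_neighborhoods(rng, 10)
        part1 = cluster(_as_graph(nbh), 0.6)
        shuffled = dict(reversed(list(nbh.items())))
        part2 = cluster(_as_graph(shuffled), 0.6)
        assert part1.clusters == part2.clusters

    def test_raising_cutoff_only_refines(self, rng):
        nbh = _random_neighborhoods(rng, 10)
        graph = _as_graph(nbh)
        coarse = cluster(graph, 0.4).cluster_of()
        fine = cluster(graph, 0.8).cluster_of()
        # Every fine cluster sits inside one coarse cluster.
        ids = sorted(nbh)
        for a in ids:
            for b in ids:
                if fine[a] == fine[b]:
                    assert coarse[a] == coarse[b]

    def test_removing_sequences_never_merges_survivors(self, rng):
        """Restricting the similarity graph to a subset of sequences must
        not merge two previously separate clusters among the survivors
        (the dataset-reduction stability the method relies on)."""
        nbh = _random_neighborhoods(rng, 12)
        graph = _as_graph(nbh)
        full = cluster(graph, 0.6).cluster_of()
        survivors = sorted(nbh)[:8]
        sub_graph = {k: graph[k] for k in survivors}
        reduced = cluster(sub_graph, 0.6).cluster_of()
        for a in survivors:
            for b in survivors:
                if reduced[a] == reduced[b]:
                    assert full[a] == full[b]

    def test_singletons_retained_and_filterable(self):
        nbh = {"a": {"a": 50.0}, "b": {"b": 50.0}}
        part = cluster(_as_graph(nbh), 0.6)
        assert sorted(part.clusters) == [("a",), ("b",)]
        assert part.filter_min_size(2).clusters == []

    def test_average_linkage_variant_runs(self, rng):
        nbh = _random_neighborhoods(rng, 8)
        part = cluster(_as_graph(nbh), 0.6, linkage="average")
        assert part.members == set(nbh)
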