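"""Shared-neighbor (Lek-style) clustering of the all-vs-all match graph.

Gene families are built in two thresholded stages: (1) an all-vs-all
protein search is reduced to per-sequence *match neighborhoods* keeping
only matches at E <= 1e-40 (the graph cutoff), symmetrized so a pair is
kept if either direction passes; (2) pairs of sequences whose
neighborhoods are similar enough (shared-neighbor similarity >= 0.6 by
default) are linked, and connected components of that similarity graph
are the clusters.

The cited shared-neighbor similarity has no single published closed
form, so the kernel is a configuration choice with three variants:

``weighted_jaccard`` (default)
    sum over shared neighbors of min(score_a, score_b) divided by the
    sum over the neighbor union of the larger available score.  Equals 1
    for identical weighted neighborhoods and 0 for disjoint ones.
``jaccard``
    unweighted |intersection| / |union| of neighbor id sets.
``cosine``
    cosine of the two bit-score vectors over the neighbor union.

Connected components make the partition deterministic and independent
of input order; average-linkage agglomeration is available as an
alternative linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .align import PairwiseMatch

KERNELS = ("weighted_jaccard", "jaccard", "cosine")
LINKAGES = ("connected", "average")


@dataclass
class MatchNeighborhood:
    """One sequence's significant-match set with bit scores."""

    seq_id: str
    neighbors: dict[str, float]  # neighbor id -> bit score (self included)


@dataclass
class ClusterPartition:
    """Disjoint clusters covering the input sequence set."""

    clusters: list[tuple[str, ...]]
    evalue_cutoff: float
    similarity_cutoff: float

    def __post_init__(self) -> None:
        members = [m for c in self.clusters for m in c]
        if len(members) != len(set(members)):
            raise ValueError("clusters must be disjoint")
        if any(len(c) == 0 for c in self.clusters):
            raise ValueError("empty cluster")

    @property
    def members(self) -> set[str]:
        return {m for c in self.clusters for m in c}

    def cluster_of(self) -> dict[str, int]:
        """Member id -> cluster index."""
        return {m: i for i, c in enumerate(self.clusters) for m in c}

    def filter_min_size(self, min_size: int) -> "ClusterPartition":
        """Reporting filter (e.g. clusters with more than two members)."""
        return ClusterPartition(
            [c for c in self.clusters if len(c) >= min_size],
            self.evalue_cutoff, self.similarity_cutoff)


def build_match_graph(matches: Iterable[PairwiseMatch],
                      evalue_cutoff: float = 1e-40,
                      seq_ids: Sequence[str] | None = None) -> dict[str, MatchNeighborhood]:
    """Reduce an all-vs-all match list to per-sequence neighborhoods.

    Neighborhoods contain exactly the matches at E <= cutoff,
    symmetrized: a pair is kept for both sequences if either direction
    passes, with the better bit score.  When ``seq_ids`` is given,
    matches referencing unknown ids raise; otherwise the universe is
    inferred from the match list.
    """
    matches = list(matches)
    known = set(seq_ids) if seq_ids is not None else None
    ids: set[str] = set()
    for m in matches:
        if known is not None and (m.query_id not in known or m.subject_id not in known):
            raise ValueError(f"match references unknown sequence: "
                             f"{m.query_id} vs {m.subject_id}")
        ids.add(m.query_id)
        ids.add(m.subject_id)
    if known is not None:
        ids = set(known)
    graph = {sid: MatchNeighborhood(sid, {}) for sid in sorted(ids)}
    for m in matches:
        if m.evalue > evalue_cutoff:
            continue
        for a, b in ((m.query_id, m.subject_id), (m.subject_id, m.query_id)):
            prev = graph[a].neighbors.get(b)
            if prev is None or m.bit_score > prev:
                graph[a].neighbors[b] = m.bit_score
    return graph


def lek_similarity(a: MatchNeighborhood, b: MatchNeighborhood,
                   kernel: str = "weighted_jaccard") -> float:
    """Shared-neighbor similarity of two neighborhoods, in [0, 1]."""
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    na, nb = a.neighbors, b.neighbors
    union = set(na) | set(nb)
    if not union:
        return 0.0
    if kernel == "jaccard":
        shared = set(na) & set(nb)
        return len(shared) / len(union)
    if kernel == "cosine":
        va = np.array([na.get(x, 0.0) for x in union])
        vb = np.array([nb.get(x, 0.0) for x in union])
        denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
        return float(va @ vb / denom) if denom > 0 else 0.0
    shared = set(na) & set(nb)
    num = sum(min(na[x], nb[x]) for x in shared)
    den = sum(max(na.get(x, -np.inf), nb.get(x, -np.inf)) for x in union)
    return num / den if den > 0 else 0.0


def similarity_edges(graph: Mapping[str, MatchNeighborhood],
                     similarity_cutoff: float,
                     kernel: str = "weighted_jaccard") -> list[tuple[str, str, float]]:
    """All pairs with similarity >= cutoff.

    Only pairs co-occurring in at least one neighborhood can have a
    nonzero shared-neighbor term, so candidate pairs are enumerated from
    the neighborhoods rather than from the full quadratic grid.
    """
    present = set(graph)
    candidates: set[tuple[str, str]] = set()
    for nb in graph.values():
        # Neighbor ids absent from the graph (e.g. after subsetting) are
        # not cluster members and cannot form edges.
        ids = sorted(present.intersection(nb.neighbors))
        candidates.update(combinations(ids, 2))
    edges = []
    for x, y in sorted(candidates):
        sim = lek_similarity(graph[x], graph[y], kernel)
        if sim >= similarity_cutoff:
            edges.append((x, y, sim))
    return edges


def cluster(graph: Mapping[str, MatchNeighborhood],
            similarity_cutoff: float = 0.6,
            kernel: str = "weighted_jaccard",
            linkage: str = "connected") -> ClusterPartition:
    """Partition the sequences at the given similarity cutoff.

    ``connected`` linkage takes connected components of the thresholded
    similarity graph (deterministic, order-free).  ``average`` linkage
    agglomerates greedily while the mean inter-cluster similarity stays
    at or above the cutoff.  Singletons are retained as size-1 clusters;
    size-based reporting filters are applied downstream.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    ids = sorted(graph)
    edges = similarity_edges(graph, similarity_cutoff, kernel)
    if linkage == "connected":
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from((x, y) for x, y, _ in edges)
        comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    else:
        comps = _average_linkage(graph, ids, similarity_cutoff, kernel)
    comps.sort(key=lambda c: (-len(c), c))
    return ClusterPartition(comps, evalue_cutoff=np.nan,
                            similarity_cutoff=similarity_cutoff)


def _average_linkage(graph: Mapping[str, MatchNeighborhood], ids: list[str],
                     cutoff: float, kernel: str) -> list[tuple[str, ...]]:
    sims = {(x, y): lek_similarity(graph[x], graph[y], kernel)
            for x, y in combinations(ids, 2)}

    def pair_sim(x: str, y: str) -> float:
        return sims[(x, y)] if (x, y) in sims else sims[(y, x)]

    clusters: list[list[str]] = [[i] for i in ids]
    while True:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            mean = float(np.mean([pair_sim(x, y)
                                  for x in clusters[i] for y in clusters[j]]))
            if mean >= cutoff and (best is None or mean > best[0]):
                best = (mean, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
    return [tuple(sorted(c)) for c in clusters]
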