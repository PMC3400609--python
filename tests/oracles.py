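"""Independent reference implementations used only as test oracles.

Deliberately written from scratch, without importing the code paths they
check: a bottom-up Gotoh affine-gap local aligner, a brute-force
enumerator of all local alignments for tiny inputs, a brute-force
shared-neighbor clustering via union-find, and a by-hand mid-rank
Spearman correlation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sub_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a][b])


def gotoh_local_score(s: str, t: str, gap_open: float = 11.0,
                      gap_extend: float = 1.0) -> float:
    """Classic three-matrix Gotoh recurrence for local alignment."""
    m, n = len(s), len(t)
    NEG = -1e18
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in s (horizontal)
    F = np.full((m + 1, n + 1), NEG)  # gap in t (vertical)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + sub_score(s[i - 1], t[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_local_score(s: str, t: str, gap_open: float = 11.0,
                          gap_extend: float = 1.0) -> float:
    """Truly exhaustive enumeration of every local alignment (tiny inputs).

    Explores every alignment path starting at every residue pair; a path
    is a sequence of match/insert/delete ops with affine gap charging.
    Paths start and end on a match op (flanking gaps cannot help with
    positive penalties).
    """
    best = 0.0

    def extend(i: int, j: int, score: float, state: str) -> None:
        nonlocal best
        if state == "M":
            best = max(best, score)
        if i < len(s) and j < len(t):
            extend(i + 1, j + 1, score + sub_score(s[i], t[j]), "M")
        if j < len(t):
            cost = gap_extend if state == "E" else gap_open + gap_extend
            extend(i, j + 1, score - cost, "E")
        if i < len(s):
            cost = gap_extend if state == "F" else gap_open + gap_extend
            extend(i + 1, j, score - cost, "F")

    for i in range(len(s)):
        for j in range(len(t)):
            extend(i + 1, j + 1, sub_score(s[i], t[j]), "M")
    return best


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def brute_weighted_jaccard(na: dict[str, float], nb: dict[str, float]) -> float:
    union = set(na) | set(nb)
    if not union:
        return 0.0
    num = sum(min(na[x], nb[x]) for x in set(na) & set(nb))
    den = 0.0
    for x in union:
        if x in na and x in nb:
            den += max(na[x], nb[x])
        else:
            den += na.get(x, 0.0) + nb.get(x, 0.0)
    return num / den if den > 0 else 0.0


def brute_cluster(neighborhoods: dict[str, dict[str, float]],
                  cutoff: float) -> set[frozenset[str]]:
    """Union-find over all pairs with brute-force similarity."""
    uf = UnionFind(neighborhoods)
    for a, b in combinations(sorted(neighborhoods), 2):
        if brute_weighted_jaccard(neighborhoods[a], neighborhoods[b]) >= cutoff:
            uf.union(a, b)
    groups: dict[str, set[str]] = {}
    for x in neighborhoods:
        groups.setdefault(uf.find(x), set()).add(x)
    return {frozenset(g) for g in groups.values()}


def midrank(values) -> list[float]:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_by_hand(x, y) -> float:
    """Pearson correlation of mid-ranks, computed from first principles."""
    rx, ry = np.array(midrank(x)), np.array(midrank(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
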