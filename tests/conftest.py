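"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the library's own algorithms: motif
location by exhaustive window enumeration, alignment scoring by recursive
enumeration of every gapped alignment, and additive distance matrices built
by summing branch lengths over explicitly constructed random trees.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


@pytest.fixture(scope="session")
def rab_consensus_protein() -> str:
    """Protein with all five Rab motifs in order and a CC terminus."""
    return (
        "M" + "IGVDF" + "A" * 10 + "KLQIW" + "A" * 10 + "RFRSIT"
        + "A" * 10 + "YYRGA" + "A" * 10 + "LVYDIT" + "SNCC"
    )


# ---------------------------------------------------------------------------
# oracle: exhaustive window enumeration for motif scanning


def enumerate_best_window(seq: str, motif: str) -> tuple[int, int] | None:
    """(1-based position, matches) of the best window, leftmost on ties."""
    m = len(motif)
    best = None
    for i in range(len(seq) - m + 1):
        matches = sum(a == b for a, b in zip(seq[i : i + m], motif))
        if best is None or matches > best[1]:
            best = (i + 1, matches)
    return best


# ---------------------------------------------------------------------------
# oracle: brute-force affine-gap alignment by full path enumeration


def brute_force_global_score(
    a: str, b: str, open_pen: float = 11.0, ext_pen: float = 1.0
) -> float:
    """Optimal global affine-gap score by enumerating every alignment.

    A gap of length L costs open_pen + L·ext_pen.  No dynamic programming:
    plain recursion over (consume both / gap in b / gap in a) moves.
    """
    m, n = len(a), len(b)
    best = [-np.inf]

    def rec(i: int, j: int, score: float, state: int) -> None:
        if i == m and j == n:
            if score > best[0]:
                best[0] = score
            return
        if i < m and j < n:
            rec(i + 1, j + 1, score + BLOSUM62[a[i]][b[j]], 0)
        if i < m:
            cost = ext_pen if state == 1 else open_pen + ext_pen
            rec(i + 1, j, score - cost, 1)
        if j < n:
            cost = ext_pen if state == 2 else open_pen + ext_pen
            rec(i, j + 1, score - cost, 2)

    rec(0, 0, 0.0, -1)
    return float(best[0])


# ---------------------------------------------------------------------------
# oracle: random additive trees and their exact leaf-to-leaf distances


def random_additive_tree(
    rng: np.random.Generator, n_leaves: int
) -> tuple[dict, list[str]]:
    """Random unrooted binary tree with uniform(0.1, 1) branch lengths.

    Returns (adjacency {node: [(neighbor, length), ...]}, leaf names).
    Grown by repeatedly subdividing a random edge with a new leaf.
    """
    assert n_leaves >= 3

    def bl() -> float:
        return float(rng.uniform(0.1, 1.0))

    adj: dict[str, list] = {}

    def connect(u: str, v: str, w: float) -> None:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def disconnect(u: str, v: str) -> None:
        adj[u] = [(x, w) for x, w in adj[u] if x != v]
        adj[v] = [(x, w) for x, w in adj[v] if x != u]

    leaves = [f"t{k}" for k in range(n_leaves)]
    connect("i0", leaves[0], bl())
    connect("i0", leaves[1], bl())
    connect("i0", leaves[2], bl())
    n_internal = 1
    for k in range(3, n_leaves):
        edges = [
            (u, v) for u in adj for v, _ in adj[u] if u < v
        ]
        u, v = edges[rng.integers(len(edges))]
        x = f"i{n_internal}"
        n_internal += 1
        disconnect(u, v)
        connect(u, x, bl())
        connect(x, v, bl())
        connect(x, leaves[k], bl())
    return adj, leaves


def path_distances(adj: dict, leaves: list[str]) -> np.ndarray:
    """Exact pairwise leaf distances by breadth-first path summation."""
    n = len(leaves)
    d = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        frontier = [src]
        while frontier:
            node = frontier.pop()
            for nbr, w in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    frontier.append(nbr)
        for j, dst in enumerate(leaves):
            d[i, j] = dist[dst]
    np.fill_diagonal(d, 0.0)
    return d


def tree_splits_from_adjacency(adj: dict, leaves: list[str]) -> set[frozenset]:
    """Canonical nontrivial splits of an adjacency-represented tree."""
    leafset = frozenset(leaves)
    ref = min(leafset)
    splits = set()
    for u in adj:
        for v, _ in adj[u]:
            if u >= v:
                continue
            # leaves on v's side of edge (u, v)
            seen = {u, v}
            frontier = [v]
            side = set()
            while frontier:
                node = frontier.pop()
                if node in leafset:
                    side.add(node)
                for nbr, _ in adj[node]:
                    if nbr not in seen:
                        seen.add(nbr)
                        frontier.append(nbr)
            if 1 < len(side) < len(leafset) - 1:
                canonical = (
                    frozenset(leafset - side) if ref in side else frozenset(side)
                )
                splits.add(canonical)
    return splits
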