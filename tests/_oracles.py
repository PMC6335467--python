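"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the production code paths: trees are
re-parsed with dendropy, shortest paths use a hand-rolled heapq Dijkstra,
and LMG shares enumerate orderings explicitly.
"""
from __future__ import annotations

import heapq
import itertools
import math

import dendropy
import numpy as np


# ---------------------------------------------------------------- trees

def random_newick(rng: np.random.Generator, n_tips: int, prefix: str = "T") -> str:
    """Random binary tree with uniform(0.1, 1) branch lengths."""
    frags = [f"{prefix}{i}" for i in range(n_tips)]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        la, lb = rng.uniform(0.1, 1.0, size=2)
        frags.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return frags[0] + ";"


def edge_bitmasks(newick: str) -> tuple[list[str], list[tuple[float, int]]]:
    """Edges of a newick tree as (length, bitmask-of-descendant-tips)."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    bit = {lbl: 1 << i for i, lbl in enumerate(labels)}
    edges = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        mask = 0
        for lf in nd.leaf_iter():
            mask |= bit[lf.taxon.label]
        edges.append((float(nd.edge.length), mask))
    return labels, edges


def beta_sim_oracle(edges: list[tuple[float, int]], m1: int, m2: int) -> float:
    """Simpson turnover by classifying each edge as shared or unique."""
    a = b = c = 0.0
    for length, mask in edges:
        in1 = mask & m1
        in2 = mask & m2
        if in1 and in2:
            a += length
        elif in1:
            b += length
        elif in2:
            c += length
    m = min(b, c)
    if m == 0.0:
        return 0.0
    return m / (a + m) if a + m > 0 else 0.0


def taxonomic_simpson(c1: set, c2: set) -> float:
    a = len(c1 & c2)
    b = len(c1 - c2)
    c = len(c2 - c1)
    m = min(b, c)
    return 0.0 if m == 0 else m / (a + m)


# ------------------------------------------------------------ distances

def dijkstra_grid(
    cost: np.ndarray,
    resolution_km: float,
    source: tuple[int, int],
    connectivity: int = 8,
) -> np.ndarray:
    """Single-source least-cost distances over a grid, average-of-endpoints
    edge costs, sqrt(2) diagonal factor."""
    rows, cols = cost.shape
    moves = [(-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0)]
    if connectivity == 8:
        rt2 = math.sqrt(2.0)
        moves += [(-1, -1, rt2), (-1, 1, rt2), (1, -1, rt2), (1, 1, rt2)]
    dist = np.full((rows, cols), np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc, f in moves:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols:
                nd = d + resolution_km * f * 0.5 * (cost[r, c] + cost[nr, nc])
                if nd < dist[nr, nc]:
                    dist[nr, nc] = nd
                    heapq.heappush(heap, (nd, (nr, nc)))
    return dist


# ------------------------------------------------------------------ LMG

def _r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    A = np.column_stack([np.ones(len(y)), X[:, cols]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return 1.0 - float(resid @ resid) / float((y - y.mean()) @ (y - y.mean()))


def lmg_bruteforce(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """LMG shares by enumerating every ordering of the p columns."""
    p = X.shape[1]
    cache: dict[tuple[int, ...], float] = {}

    def r2(cols: tuple[int, ...]) -> float:
        key = tuple(sorted(cols))
        if key not in cache:
            cache[key] = _r2(y, X, key)
        return cache[key]

    shares = np.zeros(p)
    orderings = list(itertools.permutations(range(p)))
    for order in orderings:
        prefix: tuple[int, ...] = ()
        for j in order:
            shares[j] += r2(prefix + (j,)) - r2(prefix)
            prefix = prefix + (j,)
    return shares / len(orderings)
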