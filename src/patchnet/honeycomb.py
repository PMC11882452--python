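"""Maximally compact honeycomb reference used to normalize network density.

A trisymmetric three-patch monomer network is, at its crystalline ideal, a
subgraph of the honeycomb lattice.  The network-density metric divides an
island's bond count by the largest bond count any honeycomb subgraph with
the same number of vertices can have; this module computes that normalizer.

Two routes are provided:

* :func:`max_edges_exhaustive` — exact branch enumeration over all connected
  vertex subsets of a honeycomb patch (practical for ``n <= 12``).
* a face-spiral construction — hexagonal faces added ring by ring around a
  seed face, each face's vertices added along its cycle.  The spiral agrees
  with the exhaustive optimum for every ``n <= 12`` and with the closed form
  ``floor(3n/2 - sqrt(3n/2))`` for all n checked (up to 3000).

:func:`compact_reference_edges` serves exhaustive values for small n from a
memo table and extends it with the spiral for larger islands.
"""

from __future__ import annotations

import math
import sys

import networkx as nx
import numpy as np

__all__ = ["compact_reference_edges", "max_edges_exhaustive"]

# exhaustive optimum for n = 0..12 (n=0 sentinel); spiral extends the table
_MEMO: list[int] = [0, 0, 1, 2, 3, 4, 6, 7, 8, 9, 11, 12, 13]


def max_edges_exhaustive(n: int, patch: int = 6) -> int:
    """Exact maximum edge count of an n-vertex connected honeycomb subgraph.

    Enumerates every connected vertex subset of a ``patch x patch``-cell
    honeycomb patch exactly once (rooted enumeration: the root is the
    smallest-index vertex of the subset).  Exponential in n; intended as the
    small-n oracle, use ``n <= 12``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    G = nx.hexagonal_lattice_graph(patch, patch)
    nodes = sorted(G.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    adjmask = [0] * len(nodes)
    for v in nodes:
        for w in G.neighbors(v):
            adjmask[idx[v]] |= 1 << idx[w]

    best = [0] * (n + 1)
    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 10 * n + 100))

    def extend(S: int, size: int, edges: int, cand: int, forb: int, root: int) -> None:
        if edges > best[size]:
            best[size] = edges
        if size == n:
            return
        c = cand & ~forb & ~S
        f = forb
        while c:
            vbit = c & (-c)
            c ^= vbit
            v = vbit.bit_length() - 1
            if v < root:
                f |= vbit
                continue
            gained = bin(adjmask[v] & S).count("1")
            extend(S | vbit, size + 1, edges + gained, cand | adjmask[v], f, root)
            f |= vbit

    for root in range(len(nodes)):
        extend(1 << root, 1, 0, adjmask[root], 0, root)
    sys.setrecursionlimit(limit)
    return best[n]


def _face_spiral_counts(nmax: int) -> list[int]:
    """Cumulative edge counts of the honeycomb face-spiral vertex ordering.

    Hexagonal faces are visited ring by ring around a seed face (ring index =
    hexagonal distance on the dual triangular lattice, then angle); within a
    face, vertices are appended walking the 6-cycle starting just after the
    vertices already present, so each ring of faces closes as it is laid.
    """
    R = int(math.sqrt(nmax / 3.0)) + 3
    a1 = np.array([math.sqrt(3.0), 0.0])
    a2 = np.array([math.sqrt(3.0) / 2.0, 1.5])
    faces = []
    for i in range(-R, R + 1):
        for j in range(-R, R + 1):
            ring = (abs(i) + abs(j) + abs(i + j)) // 2
            c = i * a1 + j * a2
            faces.append((ring, math.atan2(c[1], c[0]), c))
    faces.sort(key=lambda t: (t[0], t[1]))

    def key(p: np.ndarray) -> tuple[float, float]:
        return (round(float(p[0]), 6), round(float(p[1]), 6))

    def corners(c: np.ndarray) -> list[np.ndarray]:
        return [
            c + np.array([math.cos(math.pi / 6 + k * math.pi / 3),
                          math.sin(math.pi / 6 + k * math.pi / 3)])
            for k in range(6)
        ]

    def lattice_neighbours(p: np.ndarray) -> list[np.ndarray]:
        # 6 candidate directions; only the 3 on the right sublattice resolve
        return [
            p + np.array([math.cos(k * math.pi / 3 + math.pi / 2),
                          math.sin(k * math.pi / 3 + math.pi / 2)])
            for k in range(6)
        ]

    chosen: set[tuple[float, float]] = set()
    counts: list[int] = []
    edges = 0
    for _, _, c in faces:
        cs = corners(c)
        present = [key(p) in chosen for p in cs]
        if all(present):
            continue
        start = 0
        for k in range(6):
            if present[k] and not present[(k + 1) % 6]:
                start = (k + 1) % 6
                break
        for t in range(6):
            p = cs[(start + t) % 6]
            kk = key(p)
            if kk in chosen:
                continue
            edges += sum(1 for q in lattice_neighbours(p) if key(q) in chosen)
            chosen.add(kk)
            counts.append(edges)
            if len(counts) >= nmax:
                return counts
    return counts


def compact_reference_edges(n: int) -> int:
    """Maximum edge count of any n-vertex subgraph of the honeycomb lattice.

    Exhaustive values (memoized) for n <= 12; the validated face-spiral
    construction beyond.  ``compact_reference_edges(1) == 0``.
    """
    if n < 1:
        raise ValueError("island must contain at least one particle")
    if n >= len(_MEMO):
        counts = _face_spiral_counts(max(n, 2 * len(_MEMO)))
        for m in range(len(_MEMO), len(counts) + 1):
            _MEMO.append(counts[m - 1])
    return _MEMO[n]
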