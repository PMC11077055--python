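"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results by the most transparent method
available (dynamic programming over full score tables, per-step re-averaging
over all leaf pairs, breadth-first search) so they share no code with the
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def local_align_score(a: str, b: str, gap_open: float = 11.0,
                      gap_extend: float = 1.0) -> float:
    """Smith-Waterman-Gotoh best local score under BLOSUM62 affine gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    Full O(n*m) table, no pruning.
    """
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), neg)  # gap in a (consumes b)
    M[0, :] = 0.0
    M[:, 0] = 0.0
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, M[i - 1, j - 1], Ix[i - 1, j - 1],
                          Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return float(best)


def upgma_naive(labels: list[str], dist: np.ndarray):
    """Average-linkage agglomeration recomputing every inter-cluster average
    from the original leaf-leaf matrix at every step (O(n^3) per run).

    Returns a list of (frozenset_left, frozenset_right, height) merges with
    the same lexicographic tie-break as the implementation.
    """
    clusters: list[frozenset[str]] = [frozenset([l]) for l in labels]
    idx = {l: i for i, l in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for ca, cb in itertools.combinations(sorted(clusters, key=min), 2):
            avg = np.mean([dist[idx[x], idx[y]] for x in ca for y in cb])
            ra, rb = sorted((min(ca), min(cb)))
            key = (avg, ra, rb)
            if best is None or key < best[0]:
                best = (key, ca, cb)
        (height, _, _), ca, cb = best
        left, right = (ca, cb) if min(ca) <= min(cb) else (cb, ca)
        merges.append((left, right, float(height)))
        clusters.remove(ca)
        clusters.remove(cb)
        clusters.append(ca | cb)
    return merges


def components_bfs(edges, nodes):
    """Connected components by explicit breadth-first search."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = []
    for start in sorted(adj):
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps
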