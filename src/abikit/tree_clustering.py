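"""Average-linkage (UPGMA) clustering of the PCD matrix.

At every step the two clusters with the smallest *average* pairwise
leaf-to-leaf distance are merged, and the merge height is that average.
Average linkage is monotone, so merge heights never decrease; this is
asserted on every constructed tree.  Ties are broken deterministically by
the lexicographically smallest (representative, representative) pair, where
a cluster's representative is its smallest leaf id.

Merge heights are the raw inter-cluster average distances (the convention of
the usual hierarchical-clustering toolchains).  Newick export places each
node at age ``height / 2`` so the tree is ultrametric; branch lengths are
the parent/child age differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Merge:
    """One agglomeration step.  Node ids: leaves are 0..n-1 in leaf order;
    the i-th merge creates node n+i."""

    left: int
    right: int
    height: float
    size: int


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree over ``leaves`` (n - 1 merges for n leaves)."""

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(f"{n} leaves require {n - 1} merges")
        used: set[int] = set()
        prev = 0.0
        for i, m in enumerate(self.merges):
            for child in (m.left, m.right):
                if child in used or child >= n + i:
                    raise ValueError("invalid merge structure")
                used.add(child)
            if m.height < prev - 1e-9:
                raise AssertionError("merge heights must be non-decreasing (UPGMA)")
            prev = max(prev, m.height)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def members(self, node: int) -> frozenset[str]:
        """Leaf ids under ``node``."""
        n = self.n_leaves
        if node < n:
            return frozenset([self.leaves[node]])
        m = self.merges[node - n]
        return self.members(m.left) | self.members(m.right)

    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1 if self.merges else 0

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.left, m.right, m.height, m.size) for m in self.merges],
            columns=["left", "right", "height", "size"],
        )


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomerative clustering of a symmetric distance matrix.

    Inter-cluster averages are computed exactly from sums of original
    leaf-to-leaf distances (no successive-averaging drift).
    """
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix labels must match on rows and columns")
    values = dist.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (values < 0).any():
        raise ValueError("distances must be non-negative")

    leaves = tuple(str(x) for x in dist.index)
    n = len(leaves)
    if n == 0:
        raise ValueError("empty distance matrix")
    # active cluster state keyed by node id
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, str] = {i: leaves[i] for i in range(n)}
    # pair_sum[(a, b)] = sum of leaf-leaf distances between clusters a < b
    pair_sum: dict[tuple[int, int], float] = {
        (i, j): values[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[Merge] = []
    next_node = n
    active = set(range(n))
    while len(active) > 1:
        best: tuple[float, str, str, int, int] | None = None
        for (a, b), s in pair_sum.items():
            avg = s / (len(members[a]) * len(members[b]))
            ra, rb = sorted((rep[a], rep[b]))
            key = (avg, ra, rb)
            if best is None or key < (best[0], best[1], best[2]):
                best = (avg, ra, rb, a, b)
        assert best is not None
        height, _, _, a, b = best
        new = next_node
        next_node += 1
        members[new] = members[a] + members[b]
        rep[new] = min(rep[a], rep[b])
        active.discard(a)
        active.discard(b)
        for c in active:
            pair_sum[tuple(sorted((new, c)))] = (
                pair_sum.pop(tuple(sorted((a, c)))) + pair_sum.pop(tuple(sorted((b, c))))
            )
        pair_sum.pop((min(a, b), max(a, b)))
        active.add(new)
        left, right = (a, b) if rep[a] <= rep[b] else (b, a)
        merges.append(Merge(left, right, float(height), len(members[new])))
    return Dendrogram(leaves, tuple(merges))


def cut(
    tree: Dendrogram, height: float | None = None, k: int | None = None
) -> dict[str, str]:
    """Flat clusters from the dendrogram, by height or by cluster count.

    Cutting at ``height`` keeps every merge with height <= the cut; cutting
    at ``k`` stops after n - k merges.  Cluster labels are deterministic:
    each cluster is labelled by its smallest member id.
    """
    if (height is None) == (k is None):
        raise ValueError("specify exactly one of height or k")
    n = tree.n_leaves
    if height is not None:
        if height < 0:
            raise ValueError("cut height must be >= 0")
        n_merges = sum(m.height <= height for m in tree.merges)
    else:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        n_merges = n - k
    parent: dict[int, int] = {}
    for i, m in enumerate(tree.merges[:n_merges]):
        parent[m.left] = n + i
        parent[m.right] = n + i
    clusters: dict[int, set[str]] = {}
    for leaf_idx, leaf in enumerate(tree.leaves):
        node = leaf_idx
        while node in parent:
            node = parent[node]
        clusters.setdefault(node, set()).add(leaf)
    return {
        leaf: min(group) for group in clusters.values() for leaf in group
    }


def _node_rep(tree: Dendrogram, node: int) -> str:
    return min(tree.members(node))


def leaf_order(tree: Dendrogram) -> list[str]:
    """In-order leaf traversal; at each internal node the child subtree with
    the smaller representative (smallest leaf id) comes first."""
    order: list[str] = []

    def visit(node: int) -> None:
        n = tree.n_leaves
        if node < n:
            order.append(tree.leaves[node])
            return
        m = tree.merges[node - n]
        first, second = m.left, m.right
        if _node_rep(tree, second) < _node_rep(tree, first):
            first, second = second, first
        visit(first)
        visit(second)

    visit(tree.root())
    return order


def to_newick(tree: Dendrogram) -> str:
    """Ultrametric Newick: node age = merge height / 2, leaves at age 0,
    branch length = parent age - child age."""
    n = tree.n_leaves

    def age(node: int) -> float:
        return 0.0 if node < n else tree.merges[node - n].height / 2.0

    def render(node: int, parent_age: float) -> str:
        branch = parent_age - age(node)
        if node < n:
            return f"{tree.leaves[node]}:{_fmt(branch)}"
        m = tree.merges[node - n]
        first, second = m.left, m.right
        if _node_rep(tree, second) < _node_rep(tree, first):
            first, second = second, first
        inner = f"({render(first, age(node))},{render(second, age(node))})"
        return f"{inner}:{_fmt(branch)}"

    root = tree.root()
    if root < n:
        return f"{tree.leaves[root]}:0;"
    m = tree.merges[root - n]
    first, second = m.left, m.right
    if _node_rep(tree, second) < _node_rep(tree, first):
        first, second = second, first
    return (
        f"({render(first, age(root))},{render(second, age(root))});"
    )


def _fmt(x: float) -> str:
    return format(round(x, 10), "g")


def write_outputs(
    tree: Dendrogram,
    out_dir: str | Path,
    assignment: dict[str, str] | None = None,
) -> None:
    """Write Newick, merge table and optional flat-cluster assignment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(to_newick(tree) + "\n")
    tree.to_merge_table().to_csv(out / "merges.tsv", sep="\t", index=False)
    if assignment is not None:
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("phage_id\tcluster\n")
            for pid in leaf_order(tree):
                fh.write(f"{pid}\t{assignment[pid]}\n")
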