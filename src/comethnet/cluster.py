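"""Average-linkage (UPGMA) agglomerative clustering of genes.

The distance between two clusters is the arithmetic mean of all cross-pair
dissimilarities.  At each step the minimum-distance pair of clusters is
merged; exact ties are broken deterministically by the lexicographically
smallest (left node id, right node id) pair so that repeated runs produce
identical trees.  Average linkage is reducible, so merge heights are
non-decreasing along the merge sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DissimMatrix

__all__ = ["Dendrogram", "average_linkage_tree"]


@dataclass
class Dendrogram:
    """Binary merge tree over genes.

    Leaves are numbered ``0 .. n-1`` in the order of ``leaves``; the k-th
    merge creates internal node ``n + k``.  ``merges`` holds
    ``(left, right, height, size)`` tuples with ``left < right``.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        used: set[int] = set()
        for k, (left, right, height, size) in enumerate(self.merges):
            for child in (left, right):
                if child in used:
                    raise ValueError(f"node {child} used as a child twice")
                if child >= n + k:
                    raise ValueError(f"merge {k} references not-yet-created node {child}")
                used.add(child)
            if height < 0:
                raise ValueError("merge heights must be nonnegative")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else self.merges[node - n][2]

    def children(self, node: int) -> tuple[int, int] | None:
        n = self.n_leaves
        return None if node < n else self.merges[node - n][:2]

    def node_size(self, node: int) -> int:
        n = self.n_leaves
        return 1 if node < n else self.merges[node - n][3]

    def members(self, node: int) -> list[int]:
        """Leaf indices under ``node`` (iterative; safe for deep chains)."""
        out: list[int] = []
        stack = [node]
        n = self.n_leaves
        while stack:
            u = stack.pop()
            if u < n:
                out.append(u)
            else:
                left, right = self.merges[u - n][:2]
                stack.extend((right, left))
        return out

    @property
    def leaf_order(self) -> list[int]:
        """Display order: left subtree first, children ordered by node id."""
        return self.members(self.root)

    def to_newick(self) -> str:
        """Ultrametric Newick string: leaves at height 0, branch length =
        parent merge height - child merge height."""
        n = self.n_leaves
        if n == 1:
            return f"{self.leaves[0]};"
        parts: dict[int, str] = {}
        # children always have smaller ids, so one pass in id order suffices
        for k, (left, right, height, _) in enumerate(self.merges):
            pieces = []
            for child in (left, right):
                label = self.leaves[child] if child < n else parts.pop(child)
                length = height - self.node_height(child)
                pieces.append(f"{label}:{length:.10g}")
            parts[n + k] = f"({pieces[0]},{pieces[1]})"
        return parts[self.root] + ";"

    def to_merge_table(self) -> list[dict]:
        """Flat merge table (node, left, right, height, size) for TSV export."""
        n = self.n_leaves
        return [
            {"node": n + k, "left": left, "right": right, "height": height, "size": size}
            for k, (left, right, height, size) in enumerate(self.merges)
        ]


def average_linkage_tree(d: DissimMatrix) -> Dendrogram:
    """UPGMA dendrogram of a gene dissimilarity matrix.

    Uses the Lance-Williams size-weighted update, which is exactly the
    all-cross-pairs mean for average linkage.
    """
    n = len(d.gene_ids)
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    if np.isnan(d.values).any():
        raise ValueError("dissimilarity contains NaN")

    dist = d.values.astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    node_ids = list(range(n))
    sizes = [1] * n
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        m = dist.shape[0]
        height = dist.min()
        # tie-break: among all minimal pairs pick the smallest (id, id) pair
        ii, jj = np.nonzero(dist == height)
        best = None
        for i, j in zip(ii, jj):
            if i >= j:
                continue
            pair = (min(node_ids[i], node_ids[j]), max(node_ids[i], node_ids[j]))
            if best is None or pair < best[0]:
                best = (pair, int(i), int(j))
        (left, right), i, j = best
        si, sj = sizes[i], sizes[j]
        new_size = si + sj
        merges.append((left, right, float(height), new_size))

        # Lance-Williams average-linkage update against remaining clusters
        new_row = (si * dist[i] + sj * dist[j]) / new_size
        keep = [x for x in range(m) if x not in (i, j)]
        dist = dist[np.ix_(keep, keep)]
        row = new_row[keep]
        dist = np.pad(dist, ((0, 1), (0, 1)), constant_values=np.inf)
        dist[-1, :-1] = row
        dist[:-1, -1] = row
        node_ids = [node_ids[x] for x in keep] + [n + step]
        sizes = [sizes[x] for x in keep] + [new_size]

    return Dendrogram(leaves=list(d.gene_ids), merges=merges)
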