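"""One-dimensional agglomerative clustering with median (WPGMC) linkage.

Each gene's normalized values (per-class z-scores, or paired ratios) are
clustered on the line.  Under median linkage a merged cluster is
represented by the midpoint of its children's representatives, and the
distance between clusters is the absolute difference of their
representatives (Euclidean in 1D).  The linkage is implemented directly
rather than through a generic library routine because downstream results
depend on an exactly specified merge order: when several pairs are at
the minimal distance, the pair with the lexicographically smallest
(node id, node id) indices merges first, which makes runs reproducible
without hidden randomness.  Median linkage permits inversions (a merge
lower than an earlier one), so heights are not required to be monotone.

Every internal node of the dendrogram except the root is a candidate
sample cluster; "extreme" candidates — those whose median value is
furthest, in z-score units, from the centre of the gene's distribution —
become nodes of the expression graph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dendrogram",
    "CandidateCluster",
    "median_linkage_tree",
    "enumerate_clusters",
    "select_extreme_clusters",
    "cluster_gene",
]


@dataclass
class Dendrogram:
    """Agglomeration history over ``n_leaves`` one-dimensional points.

    Leaves are numbered ``0 .. n_leaves-1``; the internal node created by
    merge ``k`` is ``n_leaves + k``.  ``merges`` holds, in order, tuples
    ``(left, right, height, size)``; there are exactly ``n_leaves - 1``.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]
    leaf_values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")
        for left, right, height, size in self.merges:
            if not (math.isfinite(height) and height >= 0):
                raise ValueError("merge heights must be finite and non-negative")
            if self._size(left) + self._size(right) != size:
                raise ValueError("merged sizes must sum")

    def _size(self, node: int) -> int:
        if node < self.n_leaves:
            return 1
        return self.merges[node - self.n_leaves][3]

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def children(self, node: int) -> tuple[int, int] | None:
        if node < self.n_leaves:
            return None
        left, right, _, _ = self.merges[node - self.n_leaves]
        return left, right

    def leaves_under(self, node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.extend(self.children(v))
        return sorted(out)

    def depths(self) -> dict[int, int]:
        """Number of merges on the path from the root to each node (root = 0)."""
        depth = {self.root: 0}
        for node in range(self.root, self.n_leaves - 1, -1):
            left, right = self.children(node)
            depth[left] = depth[node] + 1
            depth[right] = depth[node] + 1
        return depth

    def to_newick(self) -> str:
        """Newick string with leaf ids; branch length = parent minus child height."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        for k, (_, _, h, _) in enumerate(self.merges):
            height[self.n_leaves + k] = h

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < self.n_leaves:
                return f"{self.leaf_ids[node]}:{bl:.6g}"
            left, right = self.children(node)
            h = height[node]
            return f"({render(left, h)},{render(right, h)}):{bl:.6g}"

        root = self.root
        left, right = self.children(root)
        h = height[root]
        return f"({render(left, h)},{render(right, h)});"


@dataclass
class CandidateCluster:
    """A subtree of one gene's dendrogram, viewed as a sample cluster.

    ``tree_level`` is the depth of the subtree root (root = 0);
    ``extremeness`` is filled in by :func:`select_extreme_clusters`.
    """

    gene_id: str
    members: frozenset[str]
    median_value: float
    size: int
    tree_level: int
    extremeness: float | None = None
    node_id: int = field(default=-1, compare=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster must have members")
        if self.size != len(self.members):
            raise ValueError("size must equal the member count")

    @property
    def key(self) -> tuple[str, ...]:
        """Deterministic identity used in tie-breaking and node naming."""
        return tuple(sorted(self.members))


def median_linkage_tree(values: np.ndarray | list[float],
                        ids: list[str] | None = None) -> Dendrogram:
    """Greedy WPGMC agglomeration of one-dimensional points.

    At each step the two active clusters with the smallest representative
    distance merge; the merged representative is the midpoint of the two.
    Ties resolve to the lowest-index pair.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise ValueError("need at least two one-dimensional values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    n = vals.size
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids must match values")

    # active clusters ordered by node id: parallel arrays
    node = list(range(n))
    reps = vals.copy().astype(float)
    sizes = [1] * n
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        m = len(node)
        d = np.abs(reps[:, None] - reps[None, :])
        iu = np.triu_indices(m, k=1)
        flat = d[iu]
        # first occurrence in row-major upper-triangle order = lowest-index pair
        best = int(np.argmin(flat))
        i, j = int(iu[0][best]), int(iu[1][best])
        height = float(flat[best])
        merged_rep = 0.5 * (reps[i] + reps[j])
        merged_size = sizes[i] + sizes[j]
        merges.append((node[i], node[j], height, merged_size))
        # replace i with the merged cluster, drop j; new node id is the largest,
        # appended at the end to keep node ids ascending in the active list
        for arr in (node, sizes):
            del arr[j], arr[i]
        reps = np.delete(reps, [i, j])
        node.append(n + step)
        sizes.append(merged_size)
        reps = np.append(reps, merged_rep)

    return Dendrogram(n_leaves=n, merges=merges, leaf_ids=list(ids),
                      leaf_values=vals)


def enumerate_clusters(tree: Dendrogram, min_size: int = 2,
                       gene_id: str = "") -> list[CandidateCluster]:
    """One candidate per internal node with ``size >= min_size``, root excluded."""
    depth = tree.depths()
    out: list[CandidateCluster] = []
    for k, (_, _, _, size) in enumerate(tree.merges):
        node = tree.n_leaves + k
        if node == tree.root or size < min_size:
            continue
        leaves = tree.leaves_under(node)
        vals = tree.leaf_values[leaves]
        out.append(CandidateCluster(
            gene_id=gene_id,
            members=frozenset(tree.leaf_ids[i] for i in leaves),
            median_value=float(np.median(vals)),
            size=size,
            tree_level=depth[node],
            node_id=node,
        ))
    return out


def select_extreme_clusters(
    candidates: list[CandidateCluster],
    gene_distribution: np.ndarray | list[float],
    fraction: float = 0.1,
) -> list[CandidateCluster]:
    """Keep the top ``fraction`` of candidates by absolute z-scored median.

    The z-score reference is the gene's own normalized value vector; the
    candidate count kept is ``ceil(fraction * n)`` (never 0 when
    candidates exist).  Ties break by larger size, then lexicographic
    member ids, so selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not candidates:
        warnings.warn("no candidate clusters to select from")
        return []
    dist = np.asarray(gene_distribution, dtype=float)
    mu = float(dist.mean())
    sd = float(dist.std(ddof=1)) if dist.size > 1 else 0.0
    scored = []
    for c in candidates:
        z = 0.0 if sd == 0 else (c.median_value - mu) / sd
        scored.append(CandidateCluster(
            gene_id=c.gene_id, members=c.members, median_value=c.median_value,
            size=c.size, tree_level=c.tree_level, extremeness=z,
            node_id=c.node_id,
        ))
    k = math.ceil(fraction * len(scored))
    scored.sort(key=lambda c: (-abs(c.extremeness), -c.size, c.key))
    return scored[:k]


def cluster_gene(values: np.ndarray, ids: list[str], gene_id: str,
                 min_size: int = 2, fraction: float = 0.1) -> list[CandidateCluster]:
    """Tree -> candidates -> extreme selection for one gene's value vector."""
    if np.asarray(values).size < 2:
        return []
    tree = median_linkage_tree(values, ids)
    cands = enumerate_clusters(tree, min_size=min_size, gene_id=gene_id)
    if not cands:
        return []
    return select_extreme_clusters(cands, values, fraction=fraction)
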