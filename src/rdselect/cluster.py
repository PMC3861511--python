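"""Average-linkage validation of discrimination claims.

A gene set that discriminates all treatment groups by the rd criterion
should also let unsupervised clustering recover the groups: agglomerative
clustering of the replicate profiles (Euclidean distance, average linkage
— inter-cluster distance is the mean over all cross-cluster replicate
pairs) is cut into K clusters and each group is checked for *purity*
(all its replicates alone in one cluster).

The agglomeration is implemented directly so that ties in merge height are
broken deterministically (merge the pair whose sorted leaf-index tuple is
lexicographically smallest); scipy's linkage leaves tie order unspecified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io import FoldChangeMatrix

__all__ = ["DendrogramResult", "average_linkage_cluster"]


@dataclass(frozen=True)
class DendrogramResult:
    """An average-linkage dendrogram over replicate leaves, with purity.

    ``merges`` records the agglomeration: each entry is (cluster_i,
    cluster_j, height, new_cluster_id), clusters 0..n-1 being the leaves in
    column order, heights non-decreasing. ``assignments`` labels each leaf
    with its cluster at the k = n_groups cut (the partition left after
    n - k merges). ``indeterminate`` flags a cut that is not separated in
    height from the next merge (e.g. all replicates identical), in which
    case purity should not be over-read.
    """

    leaf_labels: tuple[str, ...]
    leaf_groups: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    assignments: tuple[int, ...]
    purity: dict[str, bool]
    all_pure: bool
    indeterminate: bool

    def newick(self) -> str:
        """Newick string with ultrametric branch lengths (height / 2)."""
        n = len(self.leaf_labels)
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaf_labels[i] for i in range(n)}
        for i, j, h, new in self.merges:
            bi = h / 2.0 - height[i] / 2.0
            bj = h / 2.0 - height[j] / 2.0
            node[new] = f"({node[i]}:{bi:.6g},{node[j]}:{bj:.6g})"
            height[new] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"


def _average_linkage(dist: np.ndarray) -> list[tuple[int, int, float, int]]:
    """UPGMA agglomeration with deterministic lexicographic tie-breaking.

    Inter-cluster distance is the unweighted mean over all cross-cluster
    leaf pairs; on equal heights the pair with the lexicographically
    smallest (min leaf index of i, min leaf index of j) merges first.
    """
    n = dist.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = sorted(members)
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for x in range(len(active)):
            for y in range(x + 1, len(active)):
                ci, cj = active[x], active[y]
                d = dist[np.ix_(members[ci], members[cj])].mean()
                key = (d, min(members[ci]), min(members[cj]))
                if best is None or key < best[0]:
                    best = (key, ci, cj)
        (d, _, _), ci, cj = best
        members[next_id] = sorted(members.pop(ci) + members.pop(cj))
        active = sorted(members)
        merges.append((ci, cj, float(d), next_id))
        next_id += 1
    return merges


def _cut(merges: Sequence[tuple[int, int, float, int]], n: int, k: int) -> list[int]:
    """Leaf -> cluster labels after the first n - k merges."""
    parent = list(range(n + len(merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _, new in merges[: n - k]:
        parent[find(i)] = new
        parent[find(j)] = new
    roots: dict[int, int] = {}
    labels = []
    for leaf in range(n):
        r = find(leaf)
        labels.append(roots.setdefault(r, len(roots)))
    return labels


def _clade_sets(merges: Sequence[tuple[int, int, float, int]], n: int) -> list[frozenset[int]]:
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    clades = [members[i] for i in range(n)]
    for i, j, _, new in merges:
        members[new] = members[i] | members[j]
        clades.append(members[new])
    return clades


def average_linkage_cluster(
    matrix: FoldChangeMatrix,
    gene_set: Sequence[str] | None = None,
    purity: Literal["cut", "clade"] = "cut",
) -> DendrogramResult:
    """Cluster replicates on a gene set and check group purity.

    Parameters
    ----------
    gene_set
        Genes defining the coordinate space (default: all genes in the
        matrix). Must be non-empty.
    purity
        ``cut`` (default): each group must occupy exactly one cluster, alone,
        when the tree is cut into K = n_groups clusters. ``clade``: each
        group's replicates must form a complete subtree of the dendrogram.
    """
    if gene_set is not None and len(tuple(gene_set)) == 0:
        raise ValueError("gene_set must be non-empty")
    sub = matrix if gene_set is None else matrix.subset(tuple(gene_set))
    X = sub.values.T  # replicates x genes
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 replicates to cluster")
    diffs = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diffs**2).sum(axis=2))

    merges = _average_linkage(dist)
    heights = [m[2] for m in merges]
    groups = sub.groups
    k = len(groups)
    labels = _cut(merges, n, k)

    boundary = n - k  # index of the first merge NOT applied by the k-cut
    indeterminate = (
        0 < boundary < len(merges) and np.isclose(heights[boundary - 1], heights[boundary])
    )

    leaf_groups = sub.group_labels
    if purity == "cut":
        pure = {}
        for g in groups:
            own = {labels[i] for i in range(n) if leaf_groups[i] == g}
            others = {labels[i] for i in range(n) if leaf_groups[i] != g}
            pure[g] = len(own) == 1 and not (own & others)
    elif purity == "clade":
        clades = set(_clade_sets(merges, n))
        pure = {
            g: frozenset(i for i in range(n) if leaf_groups[i] == g) in clades
            for g in groups
        }
    else:
        raise ValueError("purity must be 'cut' or 'clade'")

    all_pure = all(pure.values()) and not indeterminate
    leaf_labels = tuple(f"{g}.{r}" for g, r in zip(sub.group_labels, sub.replicate_ids))
    return DendrogramResult(
        leaf_labels=leaf_labels,
        leaf_groups=tuple(leaf_groups),
        merges=tuple(merges),
        assignments=tuple(labels),
        purity=pure,
        all_pure=all_pure,
        indeterminate=indeterminate,
    )
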