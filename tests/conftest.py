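"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorized code paths:
the rd oracle works replicate-by-replicate with ``math`` / ``statistics``,
and the clustering oracle recomputes every cluster-pair mean distance from
the raw leaf distance table at every agglomeration step.
"""

from __future__ import annotations

import itertools
import math
import statistics

import numpy as np
import pytest

from rdselect.io import FoldChangeMatrix


# -- brute-force rd oracle -------------------------------------------------


def brute_euclid(x, y):
    return math.sqrt(sum((xi - yi) ** 2 for xi, yi in zip(x, y)))


def brute_rd(focal, A, B, sd="sample", form="margin"):
    """Scalar-loop re-derivation of the directed relative distance."""
    a1 = A[focal]
    d_between = [brute_euclid(a1, b) for b in B]
    d_within = [brute_euclid(a1, a) for i, a in enumerate(A) if i != focal]
    md_ab = sum(d_between) / len(d_between)
    md_aa = sum(d_within) / len(d_within)

    def sdev(vals):
        if sd == "sample":
            return statistics.stdev(vals) if len(vals) > 1 else 0.0
        return statistics.pstdev(vals)

    sd_ab, sd_aa = sdev(d_between), sdev(d_within)
    if form == "margin":
        return (md_ab - sd_ab) - (md_aa + sd_aa)
    num, den = md_ab - md_aa, sd_ab + sd_aa
    if den == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return num / den


def brute_pair_rds(A, B, **kw):
    return [brute_rd(i, A, B, **kw) for i in range(len(A))] + [
        brute_rd(i, B, A, **kw) for i in range(len(B))
    ]


# -- brute-force average-linkage oracle ------------------------------------


def brute_average_linkage(dist):
    """O(n^3)-style agglomeration recomputing each cluster-pair mean distance
    from the raw leaf distances at every step; same lexicographic tie-break
    contract as the implementation, arrived at independently."""
    n = len(dist)
    clusters = {i: [i] for i in range(n)}
    merges = []
    nid = n
    while len(clusters) > 1:
        candidates = []
        for ci, cj in itertools.combinations(sorted(clusters), 2):
            d = sum(dist[a][b] for a in clusters[ci] for b in clusters[cj])
            d /= len(clusters[ci]) * len(clusters[cj])
            candidates.append((d, min(clusters[ci]), min(clusters[cj]), ci, cj))
        d, _, _, ci, cj = min(candidates)
        clusters[nid] = sorted(clusters.pop(ci) + clusters.pop(cj))
        merges.append((ci, cj, d, nid))
        nid += 1
    return merges


def cophenetic_from_merges(merges, n):
    """Leaf-pair matrix of the heights at which pairs first join."""
    members = {i: [i] for i in range(n)}
    C = np.zeros((n, n))
    for i, j, h, new in merges:
        for a in members[i]:
            for b in members[j]:
                C[a, b] = C[b, a] = h
        members[new] = members[i] + members[j]
    return C


# -- builders --------------------------------------------------------------


def make_matrix(values, n_reps=3, group_names=None, gene_ids=None):
    """FoldChangeMatrix from a (genes x columns) array of log2 fold changes."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cols = values.shape
    assert n_cols % n_reps == 0
    k = n_cols // n_reps
    groups = group_names or [f"grp{i+1}" for i in range(k)]
    gene_ids = gene_ids or [f"g{i+1:03d}" for i in range(n_genes)]
    labels = tuple(g for g in groups for _ in range(n_reps))
    reps = tuple(r + 1 for _ in groups for r in range(n_reps))
    return FoldChangeMatrix(tuple(gene_ids), labels, reps, values)


@pytest.fixture
def two_group_matrix():
    """2 genes, 2 well-separated triplicate groups."""
    vals = np.array(
        [
            [0.0, 0.1, -0.1, 5.0, 5.1, 4.9],
            [0.0, -0.1, 0.1, -4.0, -4.1, -3.9],
        ]
    )
    return make_matrix(vals, group_names=["ctrlA", "ctrlB"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
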