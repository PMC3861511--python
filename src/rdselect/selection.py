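"""Gene screening and gene-set search by relative distance.

Three layers of selection:

1. :func:`screen_genes` — every single gene against every pair of treatment
   groups: the six directed rd values, their mean, and the all-positive
   discrimination flag.
2. :func:`overall_mean_rd` — a gene set's score across the whole design:
   the arithmetic mean of every directed rd value pooled over all group
   pairs (for 5 triplicate groups, 10 pairs x 6 values = 60).
3. :func:`search_gene_sets` — for each requested set size, the gene set
   maximizing the overall mean rd, plus whether it discriminates every
   group pair simultaneously. Subsets are enumerated exhaustively while the
   count C(G, s) stays within a budget; beyond it the search continues by
   deterministic greedy (or beam) forward selection seeded with the best
   exhaustively-found set, and the strategy used is recorded per size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import FoldChangeMatrix
from .rd import RDOptions, directed_rds_from_dist, pairwise_rd, squared_diff_tensor

__all__ = [
    "screen_genes",
    "overall_mean_rd",
    "search_gene_sets",
    "GeneSetResult",
    "GeneSetSearchResult",
]


def _group_pairs(matrix: FoldChangeMatrix) -> list[tuple[str, str]]:
    groups = matrix.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    return list(itertools.combinations(groups, 2))


def screen_genes(matrix: FoldChangeMatrix, options: RDOptions = RDOptions()) -> pd.DataFrame:
    """Score every (gene, group pair) for pairwise discrimination.

    Returns a DataFrame with one row per gene and group pair — G x K(K-1)/2
    rows — holding ``mean_rd``, the discrimination flag, and the individual
    directed rd values ``rd1..rd6`` for audit. Within each pair, rows are
    sorted by ``mean_rd`` descending, ties broken by gene id.
    """
    pairs = _group_pairs(matrix)
    d2 = squared_diff_tensor(matrix.values)
    pair_cols = [(matrix.group_columns(a), matrix.group_columns(b)) for a, b in pairs]

    rows = []
    for gi, gene in enumerate(matrix.gene_ids):
        dist = np.sqrt(d2[gi])
        for (ga, gb), (ca, cb) in zip(pairs, pair_cols):
            rds = directed_rds_from_dist(dist, ca, cb, options)
            row = {
                "gene": gene,
                "group_a": ga,
                "group_b": gb,
                "mean_rd": float(rds.mean()),
                "discriminates": bool(np.all(rds > 0)),
            }
            row.update({f"rd{k + 1}": float(v) for k, v in enumerate(rds)})
            rows.append(row)
    df = pd.DataFrame(rows)
    df["pair"] = df["group_a"] + "/" + df["group_b"]
    df = df.sort_values(["pair", "mean_rd", "gene"], ascending=[True, False, True], kind="mergesort")
    return df.reset_index(drop=True)


def overall_mean_rd(
    matrix: FoldChangeMatrix,
    gene_set: Sequence[str],
    options: RDOptions = RDOptions(),
) -> float:
    """Mean of all directed rd values over all group pairs for one gene set.

    Pooling all directed values coincides with averaging the per-pair means
    when every group has the same replicate count (the reference design).
    """
    gene_set = tuple(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    vals: list[float] = []
    for ga, gb in _group_pairs(matrix):
        vals.extend(pairwise_rd(matrix, gene_set, ga, gb, options).rd_values)
    return float(np.mean(vals))


@dataclass(frozen=True)
class GeneSetResult:
    """Best gene set found at one size."""

    size: int
    gene_set: tuple[str, ...]
    mean_rd: float
    discriminates_all: bool
    strategy: str


@dataclass(frozen=True)
class GeneSetSearchResult:
    """The size -> best-set curve."""

    results: tuple[GeneSetResult, ...]

    def best(self, size: int) -> GeneSetResult:
        for r in self.results:
            if r.size == size:
                return r
        raise KeyError(f"no result for size {size}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": [r.size for r in self.results],
                "max_mean_rd": [r.mean_rd for r in self.results],
                "discriminates_all": [r.discriminates_all for r in self.results],
                "strategy": [r.strategy for r in self.results],
                "genes": [";".join(r.gene_set) for r in self.results],
            }
        )


class _SetScorer:
    """Scores gene subsets from the precomputed per-gene distance tensor."""

    def __init__(self, matrix: FoldChangeMatrix, options: RDOptions):
        self.options = options
        self.d2 = squared_diff_tensor(matrix.values)
        self.pairs = _group_pairs(matrix)
        self.pair_cols = [
            (matrix.group_columns(a), matrix.group_columns(b)) for a, b in self.pairs
        ]
        self.gene_ids = matrix.gene_ids

    def directed_rds(self, idx: Sequence[int]) -> np.ndarray:
        dist = np.sqrt(self.d2[list(idx)].sum(axis=0))
        return np.concatenate(
            [directed_rds_from_dist(dist, ca, cb, self.options) for ca, cb in self.pair_cols]
        )

    def score(self, idx: Sequence[int]) -> tuple[float, bool]:
        rds = self.directed_rds(idx)
        return float(rds.mean()), bool(np.all(rds > 0))


def _exhaustive_best(scorer: _SetScorer, size: int) -> tuple[tuple[int, ...], float, bool]:
    best_idx: tuple[int, ...] | None = None
    best_score = -np.inf
    best_disc = False
    # gene ids iterated in lexicographic order so that the first maximum
    # encountered is the documented tie-break winner
    order = sorted(range(len(scorer.gene_ids)), key=lambda i: scorer.gene_ids[i])
    for combo in itertools.combinations(order, size):
        score, disc = scorer.score(combo)
        if score > best_score:
            best_idx, best_score, best_disc = combo, score, disc
    assert best_idx is not None
    return best_idx, best_score, best_disc


def _beam_extend(
    scorer: _SetScorer,
    seeds: list[tuple[int, ...]],
    target_size: int,
    beam: int,
) -> tuple[tuple[int, ...], float, bool]:
    """Grow seed sets one gene at a time, keeping the ``beam`` best fronts."""
    n = len(scorer.gene_ids)
    order = sorted(range(n), key=lambda i: scorer.gene_ids[i])
    frontier = [(scorer.score(s)[0], s) for s in seeds]
    while len(frontier[0][1]) < target_size:
        candidates: dict[tuple[int, ...], float] = {}
        for _, s in frontier:
            present = set(s)
            for g in order:
                if g in present:
                    continue
                new = tuple(sorted(s + (g,), key=lambda i: scorer.gene_ids[i]))
                if new not in candidates:
                    candidates[new] = scorer.score(new)[0]
        # sort by score desc, tie-break lexicographic by gene ids
        ranked = sorted(
            candidates.items(),
            key=lambda kv: (-kv[1], tuple(scorer.gene_ids[i] for i in kv[0])),
        )
        frontier = [(sc, s) for s, sc in ranked[:beam]]
    best_score, best_set = frontier[0]
    _, disc = scorer.score(best_set)
    return best_set, best_score, disc


def search_gene_sets(
    matrix: FoldChangeMatrix,
    sizes: Iterable[int] | None = None,
    strategy: Literal["auto", "exhaustive", "greedy"] = "auto",
    exhaustive_limit: int = 1_000_000,
    beam: int = 1,
    options: RDOptions = RDOptions(),
) -> GeneSetSearchResult:
    """Best gene set per size by overall mean rd.

    Parameters
    ----------
    sizes
        Set sizes to search (default: 1..G).
    strategy
        ``auto`` enumerates exhaustively while C(G, s) <= ``exhaustive_limit``
        and switches to forward selection beyond; ``exhaustive`` and
        ``greedy`` force one mode (exhaustive raises if over budget).
    beam
        Width of the forward-selection frontier; 1 is plain greedy.
    """
    G = len(matrix.gene_ids)
    sizes = sorted(set(sizes)) if sizes is not None else list(range(1, G + 1))
    if not sizes or sizes[0] < 1 or sizes[-1] > G:
        raise ValueError(f"sizes must lie in [1, {G}]")
    if beam < 1:
        raise ValueError("beam must be >= 1")

    scorer = _SetScorer(matrix, options)
    gene_ids = matrix.gene_ids
    results: list[GeneSetResult] = []
    exhaustive_cache: dict[int, tuple[tuple[int, ...], float, bool]] = {}

    def exhaustible(s: int) -> bool:
        return comb(G, s) <= exhaustive_limit

    for s in sizes:
        use_exhaustive = (strategy == "exhaustive") or (strategy == "auto" and exhaustible(s))
        if strategy == "exhaustive" and not exhaustible(s):
            raise ValueError(f"C({G},{s}) exceeds exhaustive_limit={exhaustive_limit}")
        if use_exhaustive:
            if s not in exhaustive_cache:
                exhaustive_cache[s] = _exhaustive_best(scorer, s)
            idx, score, disc = exhaustive_cache[s]
            label = "exhaustive"
        else:
            if strategy == "auto":
                # seed with the best exhaustively-found set of the largest
                # exhaustible size below s, then grow forward
                seed_size = max((t for t in range(1, s) if exhaustible(t)), default=0)
            else:
                seed_size = 0  # forced greedy: pure forward selection
            if seed_size == 0:
                seeds: list[tuple[int, ...]] = [()]
            else:
                if seed_size not in exhaustive_cache:
                    exhaustive_cache[seed_size] = _exhaustive_best(scorer, seed_size)
                seeds = [exhaustive_cache[seed_size][0]]
            idx, score, disc = _beam_extend(scorer, seeds, s, beam)
            label = "greedy" if beam == 1 else f"beam{beam}"
        genes = tuple(sorted((gene_ids[i] for i in idx)))
        results.append(GeneSetResult(s, genes, score, disc, label))
    return GeneSetSearchResult(tuple(results))
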