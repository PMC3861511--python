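"""The relative-distance (RD) separability statistic.

RD quantifies whether a single biological replicate of treatment group A can
be told apart from group B on a chosen gene set. Replicates are points in
log2 fold-change space; for focal replicate a1,

    rd_a1b = (md_a1b - SD_a1b) - (md_aa + SD_aa)

where md_a1b / SD_a1b are the mean and standard deviation of the Euclidean
distances from a1 to each replicate of B, and md_aa / SD_aa the same for the
distances from a1 to its own group's siblings. A positive rd means a1 sits
closer to its siblings than to the other group even after inflating the
within-group spread and deflating the between-group separation by one SD.

Two triplicate groups yield six directed rd values (each replicate of each
group as focal); the groups are called *discriminated* by the gene set iff
all six are strictly positive. The default "margin" form above makes the
sign depend on all four component quantities; a t-like "ratio" form
(md difference over SD sum) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import FoldChangeMatrix

__all__ = [
    "RDOptions",
    "RDComponents",
    "PairwiseRDResult",
    "euclidean_distance",
    "rd_directed",
    "pairwise_rd",
]


@dataclass(frozen=True)
class RDOptions:
    """Conventions for the rd statistic.

    form
        ``margin`` (default): rd = (md_between - SD_between) - (md_within + SD_within).
        ``ratio``: rd = (md_between - md_within) / (SD_between + SD_within),
        a t-like alternative whose sign ignores the SDs.
    sd
        ``sample`` (default, denominator n-1) or ``population`` (n).
    """

    form: Literal["margin", "ratio"] = "margin"
    sd: Literal["sample", "population"] = "sample"

    def __post_init__(self):
        if self.form not in ("margin", "ratio"):
            raise ValueError(f"form must be 'margin' or 'ratio', got {self.form!r}")
        if self.sd not in ("sample", "population"):
            raise ValueError(f"sd must be 'sample' or 'population', got {self.sd!r}")

    @property
    def ddof(self) -> int:
        return 1 if self.sd == "sample" else 0


@dataclass(frozen=True)
class RDComponents:
    """All intermediate quantities behind one directed rd value.

    Distances are in log2 fold-change units over the ``j`` genes of the
    active set. ``d_between`` holds the distances from the focal replicate
    to every replicate of the opposite group; ``d_within`` those to its own
    group's siblings.
    """

    j: int
    d_between: tuple[float, ...]
    d_within: tuple[float, ...]
    md_a1b: float
    md_aa: float
    sd_a1b: float
    sd_aa: float
    rd: float


@dataclass(frozen=True)
class PairwiseRDResult:
    """The directed rd values of one group pair on one gene set.

    For the reference triplicate design ``rd_values`` has six entries in the
    order (a1->B, a2->B, a3->B, b1->A, b2->A, b3->A). ``discriminates`` is
    True iff every directed value is strictly positive (rd = 0 fails).
    """

    group_a: str
    group_b: str
    gene_set: tuple[str, ...]
    rd_values: tuple[float, ...]
    mean_rd: float
    discriminates: bool

    components: tuple[RDComponents, ...] | None = field(default=None, compare=False)


def euclidean_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Euclidean distance between two replicate profiles of equal length."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError(f"profiles must be equal-length 1-D vectors, got {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def _sd(values: np.ndarray, ddof: int) -> float:
    # the SD of a single distance is undefined under the sample convention;
    # the degenerate one-sibling case (2-replicate groups) contributes 0
    if values.size <= ddof:
        return 0.0
    return float(np.std(values, ddof=ddof))


def _compose(md_between: float, sd_between: float, md_within: float, sd_within: float,
             form: str) -> float:
    if form == "margin":
        return (md_between - sd_between) - (md_within + sd_within)
    num = md_between - md_within
    den = sd_between + sd_within
    if den == 0.0:
        return 0.0 if num == 0.0 else float(np.sign(num) * np.inf)
    return num / den


def rd_directed(
    focal: int,
    group_a: np.ndarray,
    group_b: np.ndarray,
    options: RDOptions = RDOptions(),
) -> RDComponents:
    """Directed rd of replicate ``focal`` of group A against group B.

    Parameters
    ----------
    focal
        Row index of the focal replicate within ``group_a``.
    group_a, group_b
        ``(n_reps, j)`` arrays of replicate profiles over the same j genes.
        The published statistic is defined for triplicates; any sizes >= 2
        are accepted as the natural generalization.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the same gene set")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least 2 replicates")
    if not 0 <= focal < A.shape[0]:
        raise IndexError(f"focal index {focal} out of range for group of size {A.shape[0]}")

    a1 = A[focal]
    d_between = np.sqrt(np.sum((B - a1) ** 2, axis=1))
    siblings = np.delete(A, focal, axis=0)
    d_within = np.sqrt(np.sum((siblings - a1) ** 2, axis=1))

    md_ab = float(d_between.mean())
    md_aa = float(d_within.mean())
    sd_ab = _sd(d_between, options.ddof)
    sd_aa = _sd(d_within, options.ddof)
    rd = _compose(md_ab, sd_ab, md_aa, sd_aa, options.form)
    return RDComponents(
        j=A.shape[1],
        d_between=tuple(float(v) for v in d_between),
        d_within=tuple(float(v) for v in d_within),
        md_a1b=md_ab,
        md_aa=md_aa,
        sd_a1b=sd_ab,
        sd_aa=sd_aa,
        rd=float(rd),
    )


def pairwise_rd(
    matrix: FoldChangeMatrix,
    gene_set: Sequence[str],
    group_a: str,
    group_b: str,
    options: RDOptions = RDOptions(),
    keep_components: bool = False,
) -> PairwiseRDResult:
    """All directed rd values between two groups on a gene set.

    Each replicate of each group serves as focal against the opposite
    group: 3+3 replicates give six values. ``discriminates`` is True iff
    every value is strictly positive.
    """
    gene_set = tuple(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    A = matrix.profiles(group_a, gene_set)
    B = matrix.profiles(group_b, gene_set)

    comps: list[RDComponents] = []
    for i in range(A.shape[0]):
        comps.append(rd_directed(i, A, B, options))
    for i in range(B.shape[0]):
        comps.append(rd_directed(i, B, A, options))

    rd_values = tuple(c.rd for c in comps)
    return PairwiseRDResult(
        group_a=group_a,
        group_b=group_b,
        gene_set=gene_set,
        rd_values=rd_values,
        mean_rd=float(np.mean(rd_values)),
        discriminates=bool(all(v > 0 for v in rd_values)),
        components=tuple(comps) if keep_components else None,
    )


# -- vectorized kernel used by the subset search ---------------------------


def squared_diff_tensor(values: np.ndarray) -> np.ndarray:
    """Per-gene squared differences between all column pairs.

    Returns ``(n_genes, n_cols, n_cols)``; summing over any gene subset and
    taking the square root yields that subset's replicate distance matrix.
    """
    v = np.asarray(values, dtype=float)
    return (v[:, :, None] - v[:, None, :]) ** 2


def directed_rds_from_dist(
    dist: np.ndarray,
    cols_a: np.ndarray,
    cols_b: np.ndarray,
    options: RDOptions = RDOptions(),
) -> np.ndarray:
    """Directed rd values of one group pair from a full distance matrix.

    ``dist`` is the symmetric replicate-by-replicate distance matrix;
    ``cols_a``/``cols_b`` the column indices of the two groups. The result
    concatenates the A->B values (one per A replicate) and the B->A values.
    Equivalent to looping :func:`rd_directed`; used where many gene subsets
    are scored against precomputed distances.
    """
    ddof = options.ddof
    out = []
    for ia, ib in ((cols_a, cols_b), (cols_b, cols_a)):
        between = dist[np.ix_(ia, ib)]  # (na, nb)
        md_ab = between.mean(axis=1)
        sd_ab = between.std(axis=1, ddof=ddof) if between.shape[1] > ddof else np.zeros(len(ia))
        within_full = dist[np.ix_(ia, ia)]
        na = len(ia)
        mask = ~np.eye(na, dtype=bool)
        within = within_full[mask].reshape(na, na - 1)
        md_aa = within.mean(axis=1)
        sd_aa = within.std(axis=1, ddof=ddof) if within.shape[1] > ddof else np.zeros(na)
        if options.form == "margin":
            out.append((md_ab - sd_ab) - (md_aa + sd_aa))
        else:
            num = md_ab - md_aa
            den = sd_ab + sd_aa
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(den == 0.0, np.where(num == 0.0, 0.0, np.sign(num) * np.inf), num / np.where(den == 0.0, 1.0, den))
            out.append(r)
    return np.concatenate(out)
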