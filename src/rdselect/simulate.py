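"""Synthetic grouped expression tables with known ground truth.

The generator emulates the structure of a multi-gene qRT-PCR array
experiment: G genes x (K treatment groups x n replicates), expressed as
fold change relative to an untreated control. "Planted" genes are given
distinct per-group mean log2 fold changes, so their discriminability is
known by construction; all other (null) genes share one mean across
groups. Replicate noise is Gaussian in log2 space by default — the
standard model for expression ratios — with a lognormal-in-linear-space
alternative for stress-testing scale sensitivity.

:func:`generate_ct` emits the same design as a raw Ct table (targets plus
three constant housekeeping genes and a noiseless control group) built so
that 2^-ddCt normalization recovers the generated fold changes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .io import ExpressionTable

__all__ = ["SyntheticDesign", "generate", "generate_ct", "panel_design"]

DEFAULT_NULL_SIGMA = 0.3  # within-group SD of log2 fold change, a typical
                          # replicate-to-replicate spread for qPCR arrays


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground-truth description of a synthetic expression panel.

    Parameters
    ----------
    n_genes, n_groups, n_reps
        Panel shape; gene ids are ``g001..``, group labels ``grp1..``.
        The reference design is 3 replicates per group.
    planted
        Map of gene id -> per-group mean log2 fold change (length
        ``n_groups``). Genes not listed are null: mean 0 in every group.
    null_sigma
        Within-group SD of log2 fold change applied to every gene.
    noise_model
        ``gaussian_log2`` (default) adds N(0, null_sigma) in log2 space;
        ``lognormal_linear`` multiplies the linear fold change by
        exp(N(0, null_sigma)).
    seed
        Fully determines the output.
    """

    n_genes: int
    n_groups: int
    n_reps: int = 3
    planted: Mapping[str, Sequence[float]] = field(default_factory=dict)
    null_sigma: float = DEFAULT_NULL_SIGMA
    noise_model: Literal["gaussian_log2", "lognormal_linear"] = "gaussian_log2"
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_groups < 2 or self.n_reps < 2:
            raise ValueError("need n_genes >= 1, n_groups >= 2, n_reps >= 2")
        if self.null_sigma < 0:
            raise ValueError("null_sigma must be >= 0")
        if self.noise_model not in ("gaussian_log2", "lognormal_linear"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        gene_set = set(self.gene_ids)
        for g, means in self.planted.items():
            if g not in gene_set:
                raise ValueError(f"planted gene {g!r} not in the panel")
            if len(means) != self.n_groups:
                raise ValueError(f"planted gene {g!r}: need {self.n_groups} group means")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        width = max(3, len(str(self.n_genes)))
        return tuple(f"g{i + 1:0{width}d}" for i in range(self.n_genes))

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(f"grp{k + 1}" for k in range(self.n_groups))

    def mean_log2fc(self) -> np.ndarray:
        """(n_genes, n_groups) matrix of designed mean log2 fold changes."""
        mu = np.zeros((self.n_genes, self.n_groups))
        for g, means in self.planted.items():
            mu[self.gene_ids.index(g)] = np.asarray(means, dtype=float)
        return mu


def _noise(design: SyntheticDesign) -> np.ndarray:
    rng = np.random.default_rng(design.seed)
    return rng.normal(0.0, design.null_sigma, size=(design.n_genes, design.n_groups * design.n_reps))


def _linear_foldchange(design: SyntheticDesign) -> np.ndarray:
    mu = np.repeat(design.mean_log2fc(), design.n_reps, axis=1)
    eps = _noise(design)
    if design.noise_model == "gaussian_log2":
        return np.power(2.0, mu + eps)
    return np.power(2.0, mu) * np.exp(eps)


def _column_design(design: SyntheticDesign) -> tuple[tuple[str, ...], tuple[int, ...]]:
    groups = tuple(g for g in design.group_names for _ in range(design.n_reps))
    reps = tuple(r + 1 for _ in design.group_names for r in range(design.n_reps))
    return groups, reps


def generate(design: SyntheticDesign) -> ExpressionTable:
    """Fold-change table (treatment groups only) for a synthetic design."""
    groups, reps = _column_design(design)
    return ExpressionTable(
        gene_ids=design.gene_ids,
        group_labels=groups,
        replicate_ids=reps,
        values=_linear_foldchange(design),
        value_kind="fold_change",
    )


def generate_ct(
    design: SyntheticDesign,
    hk_ct: Sequence[float] = (18.0, 20.0, 22.0),
    target_baseline_ct: float = 25.0,
    control_label: str = "control",
) -> ExpressionTable:
    """Raw Ct table whose 2^-ddCt normalization recovers :func:`generate`.

    Targets carry Ct = baseline - log2 fold change (noise injected in Ct
    space, i.e. in log2 expression); the three housekeeping genes are
    constant at ``hk_ct`` and the control group is noiseless, so the
    normalized fold changes equal the generated ones exactly. Only defined
    for the ``gaussian_log2`` noise model (Ct space *is* log2 space).
    """
    if design.noise_model != "gaussian_log2":
        raise ValueError("Ct simulation requires the gaussian_log2 noise model")
    if len(hk_ct) != 3:
        raise ValueError("three housekeeping genes are expected")
    groups, reps = _column_design(design)
    log2fc = np.repeat(design.mean_log2fc(), design.n_reps, axis=1) + _noise(design)

    n_treat_cols = len(groups)
    n_ctrl = design.n_reps
    hk_names = ("hk_actb", "hk_b2m", "hk_rpl13a")
    n_rows = design.n_genes + len(hk_names)
    ct = np.empty((n_rows, n_treat_cols + n_ctrl))
    # a higher expression level means an earlier (lower) Ct
    ct[: design.n_genes, :n_treat_cols] = target_baseline_ct - log2fc
    ct[: design.n_genes, n_treat_cols:] = target_baseline_ct
    for i, c in enumerate(hk_ct):
        ct[design.n_genes + i, :] = c

    return ExpressionTable(
        gene_ids=design.gene_ids + hk_names,
        group_labels=groups + tuple(control_label for _ in range(n_ctrl)),
        replicate_ids=reps + tuple(r + 1 for r in range(n_ctrl)),
        values=ct,
        value_kind="ct",
        housekeeping_genes=hk_names,
        control_group=control_label,
    )


def panel_design(
    seed: int = 0,
    n_null: int = 56,
    n_groups: int = 5,
    n_reps: int = 3,
    effect: float = 3.0,
    n_planted: int = 5,
    null_sigma: float = DEFAULT_NULL_SIGMA,
) -> SyntheticDesign:
    """A realistic discriminating panel shaped like a 61-gene array.

    The first ``n_planted`` genes get distinct per-group mean log2 fold
    changes drawn uniformly from ±``effect`` (seeded); the rest are null.
    Defaults give 61 genes x 5 groups x 3 replicates.
    """
    n_genes = n_null + n_planted
    width = max(3, len(str(n_genes)))
    rng = np.random.default_rng(seed)
    planted = {
        f"g{i + 1:0{width}d}": rng.uniform(-effect, effect, size=n_groups).tolist()
        for i in range(n_planted)
    }
    return SyntheticDesign(
        n_genes=n_genes,
        n_groups=n_groups,
        n_reps=n_reps,
        planted=planted,
        null_sigma=null_sigma,
        seed=seed,
    )
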