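"""Grouped qPCR expression tables: reading, 2^-ddCt normalization, log2 transform.

The central containers are :class:`ExpressionTable` (a gene x replicate-column
matrix of Ct cycles or fold changes, with a treatment-group design) and
:class:`FoldChangeMatrix` (log2 fold changes with the control group removed —
the coordinate space in which all replicate distances are computed).

Column headers follow the ``group.replicate`` convention (e.g. ``TCDD.1``,
``TCDD.2``); alternatively an explicit design table can map arbitrary column
names to (group, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "FoldChangeMatrix",
    "read_expression_table",
    "write_expression_table",
    "ddct_normalize",
    "to_log2_foldchange",
]

VALUE_KINDS = ("ct", "fold_change", "log2_fold_change")


class DesignError(ValueError):
    """Raised when the group/replicate design of a table is invalid."""


@dataclass(frozen=True)
class ExpressionTable:
    """A gene x replicate expression matrix with a treatment-group design.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row.
    group_labels
        Treatment-group name of each column.
    replicate_ids
        Replicate index of each column within its group (1-based by
        convention; any hashable distinct-within-group labels work).
    values
        ``(n_genes, n_columns)`` array. Ct cycles when ``value_kind='ct'``,
        expression ratios when ``'fold_change'``, log2 ratios when
        ``'log2_fold_change'``.
    value_kind
        One of ``'ct'``, ``'fold_change'``, ``'log2_fold_change'``.
    housekeeping_genes
        Internal-control genes (required for Ct tables; dropped from the
        output of :func:`ddct_normalize`).
    control_group
        Label of the untreated/reference group (required for Ct tables).
    """

    gene_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    replicate_ids: tuple[int, ...]
    values: np.ndarray
    value_kind: str
    housekeeping_genes: tuple[str, ...] = ()
    control_group: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        object.__setattr__(self, "replicate_ids", tuple(self.replicate_ids))
        object.__setattr__(self, "housekeeping_genes", tuple(self.housekeeping_genes))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x column matrix")
        n_genes, n_cols = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match the number of rows")
        if len(self.group_labels) != n_cols or len(self.replicate_ids) != n_cols:
            raise ValueError("group_labels/replicate_ids length does not match the number of columns")
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN/Inf; missing values are rejected, not imputed")

        seen: dict[str, set] = {}
        for g, r in zip(self.group_labels, self.replicate_ids):
            reps = seen.setdefault(g, set())
            if r in reps:
                raise DesignError(f"duplicate replicate id {r!r} in group {g!r}")
            reps.add(r)
        for g, reps in seen.items():
            if len(reps) < 2:
                raise DesignError(f"group {g!r} has {len(reps)} replicate(s); at least 2 are required")

        unknown_hk = set(self.housekeeping_genes) - set(self.gene_ids)
        if unknown_hk:
            raise ValueError(f"housekeeping genes not in table: {sorted(unknown_hk)}")
        if self.value_kind == "ct":
            if not self.housekeeping_genes:
                raise ValueError("Ct tables require housekeeping_genes")
            if self.control_group is None:
                raise ValueError("Ct tables require a control_group")
            if self.control_group not in seen:
                raise ValueError(f"control group {self.control_group!r} not present in columns")
        if self.value_kind == "fold_change" and np.any(self.values <= 0):
            raise ValueError("fold changes must be strictly positive (log2 must be defined)")
        if self.value_kind == "ct" and np.any(self.values < 0):
            raise ValueError("Ct values must be non-negative")

    # -- accessors -------------------------------------------------------

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels in first-appearance column order."""
        out: list[str] = []
        for g in self.group_labels:
            if g not in out:
                out.append(g)
        return tuple(out)

    def group_columns(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.group_labels, dtype=object) == group)
        if idx.size == 0:
            raise KeyError(f"unknown group {group!r}")
        return idx

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{g}.{r}" for g, r in zip(self.group_labels, self.replicate_ids)]
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=cols)


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Log2 fold changes for the treatment groups, control excluded.

    Row order defines the coordinate order used by every distance
    computation; selecting a gene subset preserves column order.
    """

    gene_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    replicate_ids: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        object.__setattr__(self, "replicate_ids", tuple(self.replicate_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape != (len(self.gene_ids), len(self.group_labels)):
            raise ValueError("values shape does not match gene/column labels")
        if not np.all(np.isfinite(values)):
            raise ValueError("log2 fold changes must be finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    @property
    def groups(self) -> tuple[str, ...]:
        out: list[str] = []
        for g in self.group_labels:
            if g not in out:
                out.append(g)
        return tuple(out)

    def group_columns(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.group_labels, dtype=object) == group)
        if idx.size == 0:
            raise KeyError(f"unknown group {group!r}")
        return idx

    def gene_indices(self, gene_set: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_set if g not in pos]
        if missing:
            raise KeyError(f"unknown gene(s): {missing}")
        return np.asarray([pos[g] for g in gene_set], dtype=int)

    def subset(self, gene_set: Sequence[str]) -> "FoldChangeMatrix":
        idx = self.gene_indices(gene_set)
        return FoldChangeMatrix(
            tuple(gene_set), self.group_labels, self.replicate_ids, self.values[idx]
        )

    def profiles(self, group: str, gene_set: Sequence[str] | None = None) -> np.ndarray:
        """Replicate profiles of one group as an (n_reps, n_genes) array."""
        cols = self.group_columns(group)
        rows = slice(None) if gene_set is None else self.gene_indices(gene_set)
        return self.values[rows][:, cols].T

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{g}.{r}" for g, r in zip(self.group_labels, self.replicate_ids)]
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=cols)


# -- reading / writing ----------------------------------------------------


def _parse_header(col: str) -> tuple[str, int]:
    group, _, rep = col.rpartition(".")
    if not group:
        raise DesignError(
            f"column {col!r} does not follow the 'group.replicate' convention "
            "and no design table was given"
        )
    try:
        return group, int(rep)
    except ValueError:
        raise DesignError(f"column {col!r}: replicate part {rep!r} is not an integer") from None


def read_expression_table(
    path: str | Path,
    value_kind: str,
    *,
    design: str | Path | None = None,
    housekeeping_genes: Sequence[str] = (),
    control_group: str | None = None,
    sep: str | None = None,
) -> ExpressionTable:
    """Read a delimited gene x replicate table into an :class:`ExpressionTable`.

    The first column holds gene ids. Remaining column headers are either
    ``group.replicate`` labels, or arbitrary names resolved through a
    *design* CSV with columns ``column,group,replicate``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path} has no data columns")

    if design is not None:
        dmap = pd.read_csv(design)
        required = {"column", "group", "replicate"}
        if not required.issubset(dmap.columns):
            raise DesignError(f"design file must have columns {sorted(required)}")
        lookup = {
            str(row.column): (str(row.group), int(row.replicate))
            for row in dmap.itertuples()
        }
        missing = [c for c in df.columns if c not in lookup]
        if missing:
            raise DesignError(f"columns missing from design file: {missing}")
        pairs = [lookup[c] for c in df.columns]
    else:
        pairs = [_parse_header(str(c)) for c in df.columns]

    groups, reps = zip(*pairs)
    mat = df.to_numpy(dtype=float)
    return ExpressionTable(
        gene_ids=tuple(str(g) for g in df.index),
        group_labels=groups,
        replicate_ids=reps,
        values=mat,
        value_kind=value_kind,
        housekeeping_genes=tuple(housekeeping_genes),
        control_group=control_group,
    )


def write_expression_table(table: ExpressionTable | FoldChangeMatrix, path: str | Path) -> None:
    """Write in the same dialect :func:`read_expression_table` reads."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.to_frame().to_csv(path, sep=sep, index_label="gene")


# -- normalization ---------------------------------------------------------


def ddct_normalize(
    table: ExpressionTable,
    housekeeping: Sequence[str] | None = None,
    control_group: str | None = None,
) -> ExpressionTable:
    """2^-ddCt normalization against the geometric mean of housekeeping genes.

    For target gene *g* and treatment replicate *r*::

        dCt(g, r)  = Ct(g, r) - mean_HK_Ct(r)
        ddCt(g, r) = dCt(g, r) - mean over control replicates of dCt(g, .)
        fold change = 2 ** -ddCt

    ``mean_HK_Ct(r)`` is the arithmetic mean of the housekeeping Ct in
    replicate *r* — identically the log2 of the geometric mean of the
    housekeeping expression levels, so averaging in Ct space implements the
    geometric-mean normalizer exactly.

    Housekeeping genes are dropped from the output; the control group's
    columns are kept (their fold changes geometric-average to 1 per gene).
    """
    if table.value_kind != "ct":
        raise ValueError("ddct_normalize expects a Ct table")
    housekeeping = tuple(housekeeping) if housekeeping is not None else table.housekeeping_genes
    control_group = control_group if control_group is not None else table.control_group
    if not housekeeping:
        raise ValueError("no housekeeping genes designated")
    if control_group is None:
        raise ValueError("no control group designated")
    missing = set(housekeeping) - set(table.gene_ids)
    if missing:
        raise ValueError(f"missing housekeeping gene(s): {sorted(missing)}")
    if control_group not in table.groups:
        raise ValueError(f"missing control group {control_group!r}")

    hk_rows = [table.gene_index(g) for g in housekeeping]
    target_rows = [i for i, g in enumerate(table.gene_ids) if g not in housekeeping]
    if not target_rows:
        raise ValueError("no target genes left after removing housekeeping genes")

    hk_mean = table.values[hk_rows].mean(axis=0)  # per-column normalizer
    dct = table.values[target_rows] - hk_mean
    ctrl_cols = table.group_columns(control_group)
    ddct = dct - dct[:, ctrl_cols].mean(axis=1, keepdims=True)
    fc = np.power(2.0, -ddct)

    return ExpressionTable(
        gene_ids=tuple(table.gene_ids[i] for i in target_rows),
        group_labels=table.group_labels,
        replicate_ids=table.replicate_ids,
        values=fc,
        value_kind="fold_change",
        housekeeping_genes=(),
        control_group=control_group,
    )


def to_log2_foldchange(table: ExpressionTable) -> FoldChangeMatrix:
    """Entry-wise log2 of a fold-change table, control columns dropped.

    Accepts ``fold_change`` (log2-transformed here) or ``log2_fold_change``
    (taken as-is) tables. If the table designates a control group that is
    present among the columns, those columns are excluded: distances between
    treatment replicates do not involve the reference condition.
    """
    if table.value_kind == "fold_change":
        if np.any(table.values <= 0):
            raise ValueError("fold changes must be strictly positive")
        vals = np.log2(table.values)
    elif table.value_kind == "log2_fold_change":
        vals = table.values.copy()
    else:
        raise ValueError("expected a fold_change or log2_fold_change table; run ddct_normalize first")

    keep = [
        i
        for i, g in enumerate(table.group_labels)
        if table.control_group is None or g != table.control_group
    ]
    if not keep:
        raise ValueError("no treatment columns left after excluding the control group")
    return FoldChangeMatrix(
        gene_ids=table.gene_ids,
        group_labels=tuple(table.group_labels[i] for i in keep),
        replicate_ids=tuple(table.replicate_ids[i] for i in keep),
        values=vals[:, keep],
    )
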