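"""Pseudo-bulk aggregation, missing rates, and randomized technical replicates.

A pseudo-bulk is the per-(individual, cell type) sum of single-cell counts,
mimicking a bulk RNA-seq profile.  Technical replicates are built by randomly
partitioning one individual's cells of a given type into ``g`` disjoint,
equally sized groups and summing within each group; variability across the
replicate profiles measures purely technical precision of the expression
estimate at that cell number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import CellAnnotation, CountMatrix

__all__ = [
    "PseudobulkMatrix",
    "ReplicateSet",
    "make_pseudobulk",
    "missing_rate",
    "sample_replicates",
]


@dataclass
class PseudobulkMatrix:
    """Summed expression per (individual, cell type) group, genes in rows."""

    values: np.ndarray
    gene_ids: list[str]
    group_keys: list[tuple[str, str]]
    cell_counts: list[int]

    def __post_init__(self) -> None:
        if len(self.group_keys) != self.values.shape[1]:
            raise ValueError("one group key per column required")
        if len(set(self.group_keys)) != len(self.group_keys):
            raise ValueError("group keys must be unique")
        if any(c <= 0 for c in self.cell_counts):
            raise ValueError("cell_counts must be positive")

    @property
    def column_ids(self) -> list[str]:
        return [f"{ind}|{ct}" for ind, ct in self.group_keys]

    def to_count_matrix(self) -> CountMatrix:
        return CountMatrix(self.values, list(self.gene_ids), self.column_ids, "pseudobulk")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


@dataclass
class ReplicateSet:
    """``g`` disjoint same-size pseudo-bulk technical replicates of one group."""

    values: np.ndarray
    gene_ids: list[str]
    source: tuple[str, str]
    cells_per_replicate: int
    member_cells: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        all_cells = [c for grp in self.member_cells for c in grp]
        if len(set(all_cells)) != len(all_cells):
            raise ValueError("replicate member lists must be disjoint")
        if any(len(grp) != self.cells_per_replicate for grp in self.member_cells):
            raise ValueError("every replicate must hold exactly cells_per_replicate cells")
        if self.values.shape[1] != len(self.member_cells):
            raise ValueError("one column per replicate required")

    @property
    def g(self) -> int:
        return len(self.member_cells)


def make_pseudobulk(counts: CountMatrix, ann: CellAnnotation) -> PseudobulkMatrix:
    """Sum counts over cells within each observed (individual, cell type).

    Columns are ordered by sorted group key for determinism.  Every cell in
    ``counts`` must be annotated.
    """
    ann.check_covers(counts)
    meta = ann.table.loc[counts.column_ids]
    keys = list(zip(meta["individual_id"].astype(str), meta["cell_type"].astype(str)))
    order = sorted(set(keys))
    key_pos = {k: j for j, k in enumerate(order)}
    col_group = np.array([key_pos[k] for k in keys])

    out = np.zeros((counts.n_genes, len(order)), dtype=np.int64)
    for j in range(len(order)):
        out[:, j] = counts.values[:, col_group == j].sum(axis=1, dtype=np.int64)
    cell_counts = np.bincount(col_group, minlength=len(order))
    return PseudobulkMatrix(out, list(counts.gene_ids), order, cell_counts.tolist())


def missing_rate(
    counts: CountMatrix,
    ann: CellAnnotation,
    cell_type: str,
    level: str = "cell",
) -> pd.DataFrame:
    """Per-gene fraction of zero-count units for one cell type.

    ``level="cell"`` measures the dropout rate over single cells;
    ``level="pseudobulk"`` first sums each individual's cells of that type and
    measures zeros over the per-individual pseudo-bulk profiles.  Summation can
    only rescue zeros, so the cell-level rate always dominates the
    pseudo-bulk-level rate.
    """
    if level not in ("cell", "pseudobulk"):
        raise ValueError("level must be 'cell' or 'pseudobulk'")
    ann.check_covers(counts)
    meta = ann.table.loc[counts.column_ids]
    in_type = (meta["cell_type"].astype(str) == cell_type).to_numpy()
    if not in_type.any():
        raise ValueError(f"unknown cell type {cell_type!r}")
    sub = counts.values[:, in_type]
    if level == "pseudobulk":
        individuals = meta["individual_id"].astype(str).to_numpy()[in_type]
        uniq, inv = np.unique(individuals, return_inverse=True)
        pb = np.zeros((counts.n_genes, len(uniq)), dtype=np.int64)
        for j in range(len(uniq)):
            pb[:, j] = sub[:, inv == j].sum(axis=1, dtype=np.int64)
        sub = pb
    n_units = sub.shape[1]
    rate = (sub == 0).sum(axis=1) / n_units
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "rate": rate,
            "level": level,
            "n_units": n_units,
        }
    )


def sample_replicates(
    counts: CountMatrix,
    ann: CellAnnotation,
    individual: str,
    cell_type: str,
    g: int = 3,
    cells_per_replicate: int | None = None,
    seed: int = 0,
) -> ReplicateSet:
    """Randomly partition one group's cells into ``g`` summed replicates.

    Cells of ``(individual, cell_type)`` are shuffled with ``seed`` and the
    first ``g * cells_per_replicate`` are dealt into ``g`` disjoint groups
    (default size ``floor(n / g)``); remaining cells are left out so that
    replicate library sizes are comparable.  The same seed reproduces the
    identical partition.
    """
    if g < 2:
        raise ValueError("at least g=2 replicates are required")
    ann.check_covers(counts)
    meta = ann.table.loc[counts.column_ids]
    mask = (
        (meta["individual_id"].astype(str) == individual)
        & (meta["cell_type"].astype(str) == cell_type)
    ).to_numpy()
    pool = np.flatnonzero(mask)
    n = pool.size
    if n < g:
        raise ValueError(
            f"insufficient cells: {n} available for ({individual!r}, {cell_type!r}), need >= {g}"
        )
    if cells_per_replicate is None:
        cells_per_replicate = n // g
    if cells_per_replicate < 1:
        raise ValueError("cells_per_replicate must be >= 1")
    if g * cells_per_replicate > n:
        raise ValueError(
            f"insufficient cells: need {g * cells_per_replicate}, have {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(pool)[: g * cells_per_replicate]
    groups = chosen.reshape(g, cells_per_replicate)

    values = np.stack(
        [counts.values[:, grp].sum(axis=1, dtype=np.int64) for grp in groups], axis=1
    )
    member_cells = [[counts.column_ids[j] for j in grp] for grp in groups]
    return ReplicateSet(
        values=values,
        gene_ids=list(counts.gene_ids),
        source=(individual, cell_type),
        cells_per_replicate=cells_per_replicate,
        member_cells=member_cells,
        seed=seed,
    )
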