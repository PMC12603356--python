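"""Gamma-Poisson two-condition single-cell count simulator with known DE truth.

The generative model follows the splat-style "group" recipe: per-gene base
expression levels are Gamma distributed; a random subset of genes (``de_prob``)
receives a lognormal fold-factor, applied up or down with equal probability,
in the second condition; per-cell library sizes are lognormal; and observed
counts are Poisson draws of the cell's expected gene shares scaled to its
library size.  Marginally over cells this is an overdispersed (gamma/lognormal
mixed Poisson, i.e. NB-like) count distribution.  Sample-level random effects
are deliberately absent: replicate samples of a condition are exchangeable, so
pseudo-bulk variability is purely technical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import CellAnnotation, CountMatrix
from .pseudobulk import make_pseudobulk

__all__ = ["SimParams", "SimResult", "simulate_sc", "pooled_truth", "downsample_cells"]

CONDITIONS = ("ctrl", "treat")


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    Defaults give ~90% zeros per cell with modest, detectable effects:
    gene means Gamma(shape=0.6, rate=0.3); DE fold-factors lognormal with
    log-mean 0.1 and log-sd 0.4; library sizes lognormal around 10,000 UMIs.
    A quarter of genes are differentially expressed between the two
    conditions; each condition has 3 replicate samples.
    """

    n_genes: int = 2000
    n_cells_per_sample: int = 3000
    n_samples_per_group: int = 3
    de_prob: float = 0.25
    de_factor_loc: float = 0.1
    de_factor_scale: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = float(np.log(1e4))
    lib_scale: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must lie in [0, 1]")
        if not 10 <= self.n_cells_per_sample <= 3000:
            raise ValueError("n_cells_per_sample must lie in [10, 3000]")
        if self.n_samples_per_group < 1 or self.n_genes < 1:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        for name in ("de_factor_scale", "mean_shape", "mean_rate", "lib_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimResult:
    """Simulated counts, annotation, and per-gene ground truth."""

    counts: CountMatrix
    ann: CellAnnotation
    truth: pd.DataFrame  # gene_id, is_de, true_log2fc
    params: SimParams


def simulate_sc(params: SimParams) -> SimResult:
    """Draw a two-condition single-cell dataset with known DE labels.

    ``truth.true_log2fc`` is the log2 fold change of condition ``treat`` over
    ``ctrl`` (zero for non-DE genes).  Fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n_g = params.n_genes

    base = rng.gamma(shape=params.mean_shape, scale=1.0 / params.mean_rate, size=n_g)
    is_de = rng.random(n_g) < params.de_prob
    factors = np.exp(rng.normal(params.de_factor_loc, params.de_factor_scale, size=n_g))
    up = rng.random(n_g) < 0.5
    applied = np.where(is_de, np.where(up, factors, 1.0 / factors), 1.0)
    true_log2fc = np.where(is_de, np.log2(applied), 0.0)

    gene_ids = [f"gene{i:05d}" for i in range(n_g)]
    mean_by_cond = {
        "ctrl": base,
        "treat": base * applied,
    }
    share_by_cond = {c: m / m.sum() for c, m in mean_by_cond.items()}

    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    rows: list[dict] = []
    for cond in CONDITIONS:
        for s in range(params.n_samples_per_group):
            sample = f"{cond}{s + 1}"
            libs = rng.lognormal(params.lib_loc, params.lib_scale, size=params.n_cells_per_sample)
            lam = share_by_cond[cond][:, None] * libs[None, :]
            blocks.append(rng.poisson(lam).astype(np.int32))
            for j in range(params.n_cells_per_sample):
                cid = f"{sample}_c{j:04d}"
                cell_ids.append(cid)
                rows.append(
                    {
                        "cell_id": cid,
                        "individual_id": sample,
                        "cell_type": "simulated",
                        "condition": cond,
                    }
                )
    counts = CountMatrix(np.concatenate(blocks, axis=1), gene_ids, cell_ids, "cell")
    ann = CellAnnotation(pd.DataFrame(rows))
    truth = pd.DataFrame({"gene_id": gene_ids, "is_de": is_de, "true_log2fc": true_log2fc})
    return SimResult(counts=counts, ann=ann, truth=truth, params=params)


def pooled_truth(sim: SimResult) -> CountMatrix:
    """Per-sample sum over all cells: the matched pooled-cell reference.

    Equivalent to pseudo-bulk aggregation with the sample as grouping key; at
    the full simulated cell number this profile serves as ground truth for
    accuracy and DE comparisons.
    """
    pb = make_pseudobulk(sim.counts, sim.ann)
    mat = pb.to_count_matrix()
    # strip the "|cell_type" suffix: columns are samples
    sample_ids = [k[0] for k in pb.group_keys]
    return CountMatrix(mat.values, mat.gene_ids, sample_ids, "sample")


def downsample_cells(sim: SimResult, cells: int, seed: int = 0) -> SimResult:
    """Keep a uniform random subset of ``cells`` cells per sample; truth unchanged."""
    meta = sim.ann.table.loc[sim.counts.column_ids]
    individuals = meta["individual_id"].astype(str).to_numpy()
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for sample in pd.unique(individuals):
        pool = np.flatnonzero(individuals == sample)
        if cells > pool.size:
            raise ValueError(
                f"cannot downsample to {cells} cells: sample {sample!r} has {pool.size}"
            )
        if cells == pool.size:
            keep.extend(pool.tolist())
        else:
            keep.extend(sorted(rng.choice(pool, size=cells, replace=False).tolist()))
    keep = sorted(keep)
    sub_ids = [sim.counts.column_ids[j] for j in keep]
    return SimResult(
        counts=sim.counts.subset_columns(sub_ids),
        ann=sim.ann.subset(sub_ids),
        truth=sim.truth,
        params=sim.params,
    )
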