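"""End-to-end experiment glue: simulate -> pseudo-bulk DE -> reproducibility.

These helpers tie the simulator, the NB-LRT engine and the reproducibility
metrics into the standard synthetic experiment: ground-truth DEGs are called
on pooled full-depth pseudo-bulks, the single-cell analysis is repeated at a
grid of downsampled cell numbers, and the TPR (overall and by effect-size
stratum) plus per-gene SNR are recorded at each grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .de import ReproducibilityResult, nb_lrt, true_positive_rate
from .precision import average_cv
from .pseudobulk import make_pseudobulk
from .simulate import SimParams, SimResult, downsample_cells, pooled_truth, simulate_sc

__all__ = ["ReproducibilityExperiment", "sample_pseudobulk", "run_reproducibility_experiment"]


def sample_pseudobulk(sim: SimResult):
    """Per-sample pseudo-bulk CountMatrix and aligned condition labels."""
    pb = make_pseudobulk(sim.counts, sim.ann)
    samples = [k[0] for k in pb.group_keys]
    cond = (
        sim.ann.table.drop_duplicates("individual_id")
        .set_index("individual_id")["condition"]
        .loc[samples]
        .tolist()
    )
    return pb, cond


@dataclass
class ReproducibilityExperiment:
    truth_table: pd.DataFrame
    results: dict[int, ReproducibilityResult]  # keyed by cells per sample
    cv_table: pd.DataFrame | None
    snr_cells: int | None


def run_reproducibility_experiment(
    params: SimParams,
    cell_grid: list[int],
    fdr_max: float = 0.05,
    lfc_min: float = 0.0,
    snr_cells: int | None = None,
    cv_repeats: int = 25,
) -> ReproducibilityExperiment:
    """Run the standard synthetic reproducibility experiment for one seed.

    Truth DEGs come from NB-LRT on the pooled full-depth per-sample profiles.
    For each value in ``cell_grid`` the simulation is downsampled to that many
    cells per sample, per-sample pseudo-bulks are re-tested, and the TPR
    against the truth set is recorded.  If ``snr_cells`` is given, a technical
    CV table at that cell number (from the first sample, ``cv_repeats`` random
    partitions) is attached so that per-gene SNR accompanies the replication
    flags at that grid point.
    """
    sim = simulate_sc(params)
    pooled = pooled_truth(sim)
    cond_by_sample = (
        sim.ann.table.drop_duplicates("individual_id").set_index("individual_id")["condition"]
    )
    design = cond_by_sample.loc[pooled.column_ids].tolist()
    truth_table = nb_lrt(pooled, design, fdr_max=fdr_max, lfc_min=lfc_min)

    cv_table = None
    if snr_cells is not None:
        first_sample = pooled.column_ids[0]
        cv_table = average_cv(
            sim.counts, sim.ann, first_sample, "simulated",
            g=3, R=cv_repeats, cells_per_replicate=min(snr_cells, params.n_cells_per_sample // 3),
            seed_base=params.seed + 10_000,
        )

    results: dict[int, ReproducibilityResult] = {}
    for cells in sorted(set(int(c) for c in cell_grid)):
        sub = downsample_cells(sim, cells, seed=params.seed + cells)
        pb, cond = sample_pseudobulk(sub)
        test_table = nb_lrt(pb, cond, fdr_max=fdr_max, lfc_min=lfc_min)
        cv = None
        if cv_table is not None and snr_cells == cells:
            cv = cv_table.set_index("gene_id")["mean_cv"]
        results[cells] = true_positive_rate(
            test_table, truth_table, cv=cv,
            strata_log2fc=sim.truth.set_index("gene_id")["true_log2fc"],
        )
    return ReproducibilityExperiment(
        truth_table=truth_table, results=results, cv_table=cv_table, snr_cells=snr_cells
    )
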