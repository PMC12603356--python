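"""Per-gene coefficient of variation over technical replicates and summaries.

The central statistic is CV_i = sd(x_i) / mean(x_i), the sample standard
deviation (n-1 denominator) over the g replicate values of gene i divided by
their mean.  Because one random cell partition is noisy, the partition and CV
computation are repeated R times (default 100) and the per-gene average CV is
reported.  Downsampling the number of cells per replicate traces how precision
improves with sequencing depth per group: for replicates that are sums of m
independent Poisson(lambda) cells the expected CV is ~ 1/sqrt(m*lambda), which
is the quantitative basis of the observed decay-and-plateau curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import CellAnnotation, CountMatrix
from .pseudobulk import ReplicateSet, sample_replicates

__all__ = [
    "DEFAULT_CELL_GRID",
    "PrecisionCurve",
    "SlopeFit",
    "cv_per_gene",
    "average_cv",
    "median_cv",
    "precision_curve",
    "default_cell_grid",
    "min_cells_for_cv",
    "fraction_passing",
    "cv_covariate_correlation",
    "slope_difference_z",
]

#: Candidate cells-per-replicate grid, intersected with [1, floor(n/g)].
DEFAULT_CELL_GRID = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000, 5000)

#: Median-CV threshold recommended for bulk-tissue expression QC.
CV_THRESHOLD = 0.1


@dataclass
class PrecisionCurve:
    """Median CV of detected genes as a function of cells per replicate."""

    source: tuple[str, str]
    points: pd.DataFrame  # columns: cells_per_replicate, median_cv
    R: int
    g: int
    normalize: bool = False

    def __post_init__(self) -> None:
        cells = self.points["cells_per_replicate"].to_numpy()
        if len(cells) == 0:
            raise ValueError("curve must have at least one point")
        if not np.all(np.diff(cells) > 0):
            raise ValueError("cells_per_replicate must be strictly increasing")


class SlopeFit(NamedTuple):
    """A regression slope with its standard error and sample size."""

    b: float
    se: float
    n: int


class CovariateCorrelation(NamedTuple):
    r: float
    r2: float
    p: float
    slope: float


def cv_per_gene(reps: ReplicateSet, normalize: bool = False) -> np.ndarray:
    """CV of each gene across the replicate columns; NaN where the mean is 0.

    With ``normalize=True`` replicate columns are scaled to counts-per-million
    before the CV, removing library-depth differences between replicates.
    """
    if reps.g < 2:
        raise ValueError("CV needs at least 2 replicates")
    x = reps.values.astype(float)
    if normalize:
        lib = x.sum(axis=0)
        if np.any(lib == 0):
            raise ValueError("cannot CPM-normalize an all-zero replicate")
        x = 1e6 * x / lib
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return cv


def average_cv(
    counts: CountMatrix,
    ann: CellAnnotation,
    individual: str,
    cell_type: str,
    g: int = 3,
    R: int = 100,
    cells_per_replicate: int | None = None,
    seed_base: int = 0,
    normalize: bool = False,
) -> pd.DataFrame:
    """Mean per-gene CV over ``R`` independent random cell partitions.

    Repeat ``r`` uses seed ``seed_base + r``.  A gene contributes to the mean
    only in repeats where it is detected (nonzero total across the g
    replicates); genes never detected get ``detected=False`` and NaN CV.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    cv_sum = np.zeros(counts.n_genes)
    n_def = np.zeros(counts.n_genes, dtype=int)
    for r in range(R):
        reps = sample_replicates(
            counts, ann, individual, cell_type,
            g=g, cells_per_replicate=cells_per_replicate, seed=seed_base + r,
        )
        cv = cv_per_gene(reps, normalize=normalize)
        ok = ~np.isnan(cv)
        cv_sum[ok] += cv[ok]
        n_def += ok
    with np.errstate(invalid="ignore"):
        mean_cv = np.where(n_def > 0, cv_sum / np.maximum(n_def, 1), np.nan)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "mean_cv": mean_cv,
            "n_repeats_defined": n_def,
            "detected": n_def > 0,
        }
    )


def median_cv(cv_table: pd.DataFrame) -> float:
    """Median of mean CV over detected genes (the per-sample noise summary)."""
    detected = cv_table.loc[cv_table["detected"], "mean_cv"]
    if detected.empty:
        return float("nan")
    return float(detected.median())


def default_cell_grid(n_cells: int, g: int = 3) -> list[int]:
    cap = n_cells // g
    return [c for c in DEFAULT_CELL_GRID if 1 <= c <= cap]


def precision_curve(
    counts: CountMatrix,
    ann: CellAnnotation,
    individual: str,
    cell_type: str,
    grid: Sequence[int] | None = None,
    g: int = 3,
    R: int = 100,
    seed_base: int = 0,
    normalize: bool = False,
) -> PrecisionCurve:
    """Median CV at each cells-per-replicate value of ``grid``."""
    mask = (
        (ann.table["individual_id"].astype(str) == individual)
        & (ann.table["cell_type"].astype(str) == cell_type)
    )
    n = int(mask.sum())
    if grid is None:
        grid = default_cell_grid(n, g)
    grid = sorted(set(int(c) for c in grid))
    if not grid:
        raise ValueError("empty cell grid")
    if grid[-1] > n // g:
        raise ValueError(
            f"grid value {grid[-1]} exceeds floor(n/g) = {n // g} for this group"
        )
    rows = []
    for cells in grid:
        table = average_cv(
            counts, ann, individual, cell_type,
            g=g, R=R, cells_per_replicate=cells,
            seed_base=seed_base, normalize=normalize,
        )
        rows.append({"cells_per_replicate": cells, "median_cv": median_cv(table)})
    return PrecisionCurve(
        source=(individual, cell_type),
        points=pd.DataFrame(rows),
        R=R,
        g=g,
        normalize=normalize,
    )


def min_cells_for_cv(curve: PrecisionCurve, threshold: float = CV_THRESHOLD) -> int | None:
    """Smallest grid value whose median CV is <= ``threshold``; None if never."""
    pts = curve.points
    ok = pts[pts["median_cv"] <= threshold]
    if ok.empty:
        return None
    return int(ok["cells_per_replicate"].iloc[0])


def fraction_passing(
    cv_tables: Mapping[str, pd.DataFrame] | Iterable[pd.DataFrame],
    threshold: float = CV_THRESHOLD,
) -> float:
    """Proportion of samples whose median CV over detected genes is <= threshold."""
    tables = list(cv_tables.values()) if isinstance(cv_tables, Mapping) else list(cv_tables)
    if not tables:
        raise ValueError("empty input: no CV tables")
    medians = np.array([median_cv(t) for t in tables])
    return float(np.mean(medians <= threshold))


def cv_covariate_correlation(
    sample_median_cvs: Sequence[tuple[str, float]],
    covariate: Sequence[tuple[str, float]],
) -> CovariateCorrelation:
    """Regress per-sample median CV on a sample covariate (e.g., RIN).

    Returns the Pearson r, R^2, two-sided p and slope of the simple linear
    regression of median CV on the covariate, over samples present in both
    inputs.
    """
    cv = dict(sample_median_cvs)
    cov = dict(covariate)
    shared = sorted(set(cv) & set(cov))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 matched samples, have {len(shared)}")
    x = np.array([cov[s] for s in shared], dtype=float)
    y = np.array([cv[s] for s in shared], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance covariate")
    fit = stats.linregress(x, y)
    return CovariateCorrelation(
        r=float(fit.rvalue), r2=float(fit.rvalue**2),
        p=float(fit.pvalue), slope=float(fit.slope),
    )


def slope_difference_z(fit1: SlopeFit, fit2: SlopeFit) -> tuple[float, float]:
    """Two-sample Z-test for equality of two regression slopes.

    diff = (b1 - b2) / sqrt(se1^2 + se2^2), compared against the standard
    normal in a two-tailed manner.  Used to compare the CV-vs-cell-number
    slope between two datasets or annotation resolutions.
    """
    if fit1.se <= 0 or fit2.se <= 0:
        raise ValueError("standard errors must be positive")
    diff = (fit1.b - fit2.b) / float(np.hypot(fit1.se, fit2.se))
    p = 2.0 * stats.norm.sf(abs(diff))
    return float(diff), float(p)
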