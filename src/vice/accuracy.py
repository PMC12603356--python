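"""Per-gene expression accuracy of single-cell pseudo-bulks against matched bulk.

Accuracy is a composite criterion: for each gene, the Pearson correlation
between the reference (pooled-cell/bulk) log2-CPM profile and the single-cell
pseudo-bulk log2-CPM profile across matched samples, together with a
regression through the origin of the single-cell values (y) on the reference
values (x).  The slope is tested against 1; "good accuracy" means r > 0.9 and
slope-test p > 0.05, i.e. strong correlation with no detectable multiplicative
bias.  A simple per-gene location-scale batch adjustment aligns the two
platforms before the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import CellAnnotation, CountMatrix, normalize
from .pseudobulk import make_pseudobulk

__all__ = [
    "PairedExpression",
    "pair_and_normalize",
    "batch_adjust",
    "gene_accuracy",
    "count_good",
    "accuracy_downsampling_curve",
]


@dataclass
class PairedExpression:
    """Gene-aligned log2-CPM matrices for reference bulk (x) and sc pseudo-bulk (y)."""

    genes: list[str]
    x_bulk: np.ndarray
    y_sc: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.x_bulk.shape != self.y_sc.shape:
            raise ValueError("x and y must have identical shape")
        if self.x_bulk.shape != (len(self.genes), len(self.sample_ids)):
            raise ValueError("shape does not match gene/sample ids")
        if not (np.all(np.isfinite(self.x_bulk)) and np.all(np.isfinite(self.y_sc))):
            raise ValueError("paired expression must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def pair_and_normalize(
    sc_pb: CountMatrix,
    bulk: CountMatrix,
    sample_map: Sequence[tuple[str, str]] | dict[str, str],
) -> PairedExpression:
    """Align sc pseudo-bulk and bulk columns by sample and log2-CPM transform both.

    ``sample_map`` maps sc pseudo-bulk column ids to bulk column ids.  Library
    sizes are taken from the full input matrices before restricting to the
    common gene set; pseudo-count 1 is added after CPM scaling.
    """
    pairs = list(sample_map.items()) if isinstance(sample_map, dict) else list(sample_map)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 matched samples, have {len(pairs)}")
    common = [g for g in sc_pb.gene_ids if g in set(bulk.gene_ids)]
    if not common:
        raise ValueError("no genes shared between single-cell and bulk matrices")
    y = normalize(sc_pb, "log2cpm").to_frame().loc[common]
    x = normalize(bulk, "log2cpm").to_frame().loc[common]
    sc_cols = [p[0] for p in pairs]
    bulk_cols = [p[1] for p in pairs]
    return PairedExpression(
        genes=common,
        x_bulk=x[bulk_cols].to_numpy(),
        y_sc=y[sc_cols].to_numpy(),
        sample_ids=sc_cols,
    )


def batch_adjust(pe: PairedExpression) -> PairedExpression:
    """Per-gene location-scale harmonization of the two platforms.

    For each gene, each side is shifted and scaled so that its across-sample
    mean and standard deviation match the grand mean and the pooled
    within-side standard deviation (root mean of the two side variances).
    Sides with zero variance are shifted only.  The map is idempotent.
    """
    if pe.n_samples < 2:
        raise ValueError("batch adjustment needs >= 2 samples per side")

    def _moments(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return a.mean(axis=1), a.std(axis=1, ddof=1)

    mx, sx = _moments(pe.x_bulk)
    my, sy = _moments(pe.y_sc)
    grand = 0.5 * (mx + my)
    pooled = np.sqrt(0.5 * (sx**2 + sy**2))

    def _adjust(a: np.ndarray, m: np.ndarray, s: np.ndarray) -> np.ndarray:
        scale = np.where(s > 0, np.divide(pooled, s, out=np.ones_like(s), where=s > 0), 1.0)
        return (a - m[:, None]) * scale[:, None] + grand[:, None]

    return replace(pe, x_bulk=_adjust(pe.x_bulk, mx, sx), y_sc=_adjust(pe.y_sc, my, sy))


def gene_accuracy(
    pe: PairedExpression, r_min: float = 0.9, p_min: float = 0.05
) -> pd.DataFrame:
    """Per-gene correlation and through-origin slope test of y on x.

    slope b = sum(xy) / sum(x^2); se = sqrt(RSS / ((n-1) * sum(x^2)));
    p_slope is the two-sided t probability of (b - 1)/se on n-1 degrees of
    freedom (one fitted parameter).  ``good`` requires r > r_min and
    p_slope > p_min.  Genes with all-zero reference values get an undefined
    slope and ``good=False``; zero-variance genes on either side get an
    undefined correlation and ``good=False``.
    """
    n = pe.n_samples
    if n < 3:
        raise ValueError("need >= 3 samples")
    x, y = pe.x_bulk, pe.y_sc

    sxx = (x * x).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    ok_x = sxx > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(ok_x, sxy / np.where(ok_x, sxx, 1.0), np.nan)
        resid = y - b[:, None] * x
        rss = (resid**2).sum(axis=1)
        se = np.sqrt(rss / ((n - 1) * np.where(ok_x, sxx, np.nan)))
        t = (b - 1.0) / se
    p_slope = np.where(
        np.isnan(t),
        np.where(np.isclose(b, 1.0), 1.0, 0.0),  # se == 0: exact fit
        2.0 * stats.t.sf(np.abs(np.where(np.isnan(t), 0.0, t)), df=n - 1),
    )
    p_slope = np.where(ok_x, p_slope, np.nan)

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    ok_r = (sx > 0) & (sy > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ok_r, (xc * yc).sum(axis=1) / (sx * sy), np.nan)

    good = ok_x & ok_r & (r > r_min) & (np.nan_to_num(p_slope) > p_min)
    return pd.DataFrame(
        {
            "gene_id": pe.genes,
            "r": r,
            "slope": b,
            "slope_se": se,
            "p_slope": p_slope,
            "good": good,
            "n_samples": n,
        }
    )


def count_good(acc: pd.DataFrame) -> int:
    """Number of genes flagged with good accuracy."""
    if acc.empty:
        return 0
    return int(acc["good"].sum())


def accuracy_downsampling_curve(
    sc_counts: CountMatrix,
    ann: CellAnnotation,
    bulk: CountMatrix,
    cell_grid: Sequence[int],
    seed: int = 0,
    sample_map: Sequence[tuple[str, str]] | None = None,
    r_min: float = 0.9,
    p_min: float = 0.05,
) -> list[tuple[int, int]]:
    """Number of good-accuracy genes as cells per sample are downsampled.

    For each grid value, cells are subsampled without replacement per
    individual, summed into per-individual pseudo-bulks, paired with the bulk
    reference (columns matched by individual id unless ``sample_map`` is
    given), batch-adjusted and scored.  Returns ``[(cells, n_good), ...]``.
    """
    ann.check_covers(sc_counts)
    meta = ann.table.loc[sc_counts.column_ids]
    individuals = meta["individual_id"].astype(str).to_numpy()
    uniq = sorted(set(individuals))
    avail = {u: np.flatnonzero(individuals == u) for u in uniq}
    n_min = min(len(v) for v in avail.values())
    grid = sorted(set(int(c) for c in cell_grid))
    if grid[-1] > n_min:
        raise ValueError(
            f"grid value {grid[-1]} exceeds the {n_min} cells available in the smallest sample"
        )
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int]] = []
    for cells in grid:
        keep_idx = np.concatenate(
            [rng.choice(avail[u], size=cells, replace=False) for u in uniq]
        )
        sub = sc_counts.subset_columns([sc_counts.column_ids[j] for j in sorted(keep_idx)])
        pb = make_pseudobulk(sub, ann).to_count_matrix()
        # pseudobulk column ids are "individual|cell_type"; map to individual
        pb_by_ind = {cid.split("|")[0]: cid for cid in pb.column_ids}
        if sample_map is None:
            pairs = [(pb_by_ind[u], u) for u in uniq if u in set(bulk.column_ids)]
        else:
            pairs = [(pb_by_ind[sc], b) for sc, b in sample_map]
        pe = batch_adjust(pair_and_normalize(pb, bulk, pairs))
        out.append((cells, count_good(gene_accuracy(pe, r_min=r_min, p_min=p_min))))
    return out
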