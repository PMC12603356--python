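"""Count-matrix and annotation I/O, cell/gene quality-control filters, normalization.

The universal expression container is :class:`CountMatrix`, a dense
genes-in-rows integer matrix with string identifiers on both axes.  Cell
metadata travels in :class:`CellAnnotation`, a thin wrapper around a pandas
DataFrame indexed by cell id.  Both are deliberately lightweight; converters
to/from ``AnnData`` are provided for interoperability with the scanpy
ecosystem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CountMatrix",
    "CellAnnotation",
    "NormalizedMatrix",
    "read_counts",
    "read_annotation",
    "write_counts",
    "write_annotation",
    "qc_filter",
    "normalize",
]

COLUMN_KINDS = ("cell", "sample", "pseudobulk")
REQUIRED_ANNOTATION_COLUMNS = ("cell_id", "individual_id", "cell_type")


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what}: {dup!r}")
    return ids


@dataclass
class CountMatrix:
    """Dense non-negative integer expression matrix, genes in rows.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_columns)``; must be integral and >= 0.
    gene_ids, column_ids
        Unique string identifiers for rows and columns.
    column_kind
        What a column represents: ``"cell"``, ``"sample"`` or ``"pseudobulk"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    column_kind: str = "cell"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValueError("counts must be integral")
            values = values.astype(np.int64)
        if values.size and values.min() < 0:
            raise ValueError("counts must be non-negative")
        self.values = values
        self.gene_ids = _check_unique(self.gene_ids, "gene_id")
        self.column_ids = _check_unique(self.column_ids, "column_id")
        if len(self.gene_ids) != values.shape[0]:
            raise ValueError(
                f"dimension mismatch: {len(self.gene_ids)} gene ids for "
                f"{values.shape[0]} rows"
            )
        if len(self.column_ids) != values.shape[1]:
            raise ValueError(
                f"dimension mismatch: {len(self.column_ids)} column ids for "
                f"{values.shape[1]} columns"
            )
        if self.column_kind not in COLUMN_KINDS:
            raise ValueError(f"column_kind must be one of {COLUMN_KINDS}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def subset_columns(self, column_ids: Iterable[str]) -> "CountMatrix":
        idx = pd.Index(self.column_ids)
        pos = idx.get_indexer(list(column_ids))
        if (pos < 0).any():
            missing = [c for c, p in zip(column_ids, pos) if p < 0]
            raise KeyError(f"unknown column ids: {missing[:5]}")
        return CountMatrix(
            self.values[:, pos],
            list(self.gene_ids),
            [self.column_ids[p] for p in pos],
            self.column_kind,
        )

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        idx = pd.Index(self.gene_ids)
        pos = idx.get_indexer(list(gene_ids))
        if (pos < 0).any():
            missing = [g for g, p in zip(gene_ids, pos) if p < 0]
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return CountMatrix(
            self.values[pos, :],
            [self.gene_ids[p] for p in pos],
            list(self.column_ids),
            self.column_kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)

    def to_anndata(self):
        """Return an ``AnnData`` view (cells x genes, the scanpy convention)."""
        import anndata as ad

        return ad.AnnData(
            X=self.values.T.astype(np.float32),
            obs=pd.DataFrame(index=self.column_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )


@dataclass
class CellAnnotation:
    """Per-cell grouping keys and covariates.

    ``table`` is indexed by ``cell_id`` and always carries ``individual_id``
    and ``cell_type``; ``condition`` is optional.  Extra numeric columns are
    exposed through :meth:`covariates` (e.g., RIN on the 1-10 scale), other
    extra columns through :meth:`labels`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "cell_id":
            if "cell_id" in t.columns:
                t = t.set_index("cell_id")
            else:
                raise ValueError("annotation requires a cell_id column")
        for col in ("individual_id", "cell_type"):
            if col not in t.columns:
                raise ValueError(f"annotation missing required column {col!r}")
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate cell_id: {dup!r}")
        if "RIN" in t.columns:
            rin = pd.to_numeric(t["RIN"], errors="coerce").dropna()
            if ((rin < 1) | (rin > 10)).any():
                raise ValueError("RIN values must lie in [1, 10]")
        self.table = t

    @property
    def cell_ids(self) -> list[str]:
        return [str(c) for c in self.table.index]

    @property
    def individual_ids(self) -> pd.Series:
        return self.table["individual_id"]

    @property
    def cell_types(self) -> pd.Series:
        return self.table["cell_type"]

    @property
    def condition(self) -> pd.Series | None:
        return self.table["condition"] if "condition" in self.table.columns else None

    def covariates(self) -> pd.DataFrame:
        extra = self.table.drop(
            columns=[c for c in ("individual_id", "cell_type", "condition") if c in self.table.columns]
        )
        numeric = extra.apply(pd.to_numeric, errors="coerce")
        return numeric.loc[:, numeric.notna().all()]

    def labels(self) -> pd.DataFrame:
        extra = self.table.drop(
            columns=[c for c in ("individual_id", "cell_type", "condition") if c in self.table.columns]
        )
        numeric = extra.apply(pd.to_numeric, errors="coerce")
        return extra.loc[:, ~numeric.notna().all()]

    def subset(self, cell_ids: Iterable[str]) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[list(cell_ids)].copy())

    def check_covers(self, counts: CountMatrix) -> None:
        missing = set(counts.column_ids) - set(self.cell_ids)
        if missing:
            raise ValueError(
                f"{len(missing)} cells in the count matrix lack annotation, "
                f"e.g. {sorted(missing)[:3]}"
            )


@dataclass
class NormalizedMatrix:
    """Library-size normalized (and log-transformed) expression values."""

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    scheme: str
    pseudo_count: float

    def __post_init__(self) -> None:
        if self.scheme not in ("lognorm10k", "log2cpm"):
            raise ValueError("scheme must be 'lognorm10k' or 'log2cpm'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _resolve_triplet(path_spec: str | Path) -> tuple[Path, Path, Path]:
    p = Path(path_spec)
    if p.is_dir():
        return p / "matrix.mtx", p / "features.tsv", p / "barcodes.tsv"
    if p.suffix == ".mtx":
        return p, p.with_name("features.tsv"), p.with_name("barcodes.tsv")
    raise FileNotFoundError(f"cannot resolve MatrixMarket triplet from {path_spec!r}")


def read_counts(path_spec: str | Path, format: str = "dense_tsv") -> CountMatrix:
    """Read a genes x cells count matrix.

    ``mtx_triplet`` expects the 10x-style layout ``matrix.mtx`` (features x
    barcodes) with ``features.tsv`` and ``barcodes.tsv`` sidecars; ``path_spec``
    is the directory or the ``.mtx`` file.  ``dense_tsv`` expects gene ids in
    the first column and a header row of cell ids.
    """
    if format == "dense_tsv":
        path = Path(path_spec)
        if not path.exists():
            raise FileNotFoundError(str(path))
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(
            df.to_numpy(),
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            column_kind="cell",
        )
    if format == "mtx_triplet":
        mtx, feat, barc = _resolve_triplet(path_spec)
        for f in (mtx, feat, barc):
            if not f.exists():
                raise FileNotFoundError(str(f))
        mat = spio.mmread(mtx)
        genes = pd.read_csv(feat, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(barc, sep="\t", header=None)[0].astype(str).tolist()
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"dimension mismatch: matrix is {mat.shape}, sidecars list "
                f"{len(genes)} features x {len(cells)} barcodes"
            )
        return CountMatrix(mat, genes, cells, column_kind="cell")
    raise ValueError(f"unknown format {format!r}")


def write_counts(counts: CountMatrix, path_spec: str | Path, format: str = "dense_tsv") -> None:
    if format == "dense_tsv":
        counts.to_frame().to_csv(path_spec, sep="\t", index_label="gene_id")
        return
    if format == "mtx_triplet":
        outdir = Path(path_spec)
        outdir.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(counts.values))
        pd.Series(counts.gene_ids).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(counts.column_ids).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
        return
    raise ValueError(f"unknown format {format!r}")


def read_annotation(path: str | Path) -> CellAnnotation:
    """Read a cell annotation TSV with header cell_id / individual_id / cell_type."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    for col in REQUIRED_ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annotation missing required column {col!r}")
    return CellAnnotation(df)


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="cell_id")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    counts: CountMatrix,
    ann: CellAnnotation,
    mito_gene_prefix: str = "MT-",
    mito_max: float = 0.10,
    min_genes: int = 200,
    sd_mult: float = 3.0,
    min_cell_fraction: float = 0.001,
) -> tuple[CountMatrix, CellAnnotation, dict]:
    """Apply standard cell and gene quality filters, in a fixed order.

    1. drop cells whose mitochondrial read fraction is >= ``mito_max``
       (mitochondrial genes = ids starting with ``mito_gene_prefix``);
    2. drop cells detecting fewer than ``min_genes`` genes;
    3. drop cells detecting more genes than mean + ``sd_mult`` * sd, with the
       statistics computed over the cells that survived steps 1-2;
    4. drop genes detected (count > 0) in fewer than ``min_cell_fraction`` of
       the retained cells.

    Returns the filtered matrix/annotation and a report dict listing the
    number removed by each rule in that order.  Idempotent: a second pass
    removes nothing.
    """
    ann.check_covers(counts)
    report: dict = {"warnings": []}
    values = counts.values
    keep = np.ones(counts.n_columns, dtype=bool)

    mito_mask = np.array([g.startswith(mito_gene_prefix) for g in counts.gene_ids])
    if not mito_mask.any():
        report["warnings"].append(
            f"no genes match mitochondrial prefix {mito_gene_prefix!r}; mito rule skipped"
        )
        report["mito_removed"] = 0
    else:
        lib = values.sum(axis=0)
        mito_frac = np.divide(
            values[mito_mask].sum(axis=0), lib, out=np.zeros(len(lib)), where=lib > 0
        )
        drop = mito_frac >= mito_max
        report["mito_removed"] = int(drop.sum())
        keep &= ~drop

    detected = (values > 0).sum(axis=0)
    drop = keep & (detected < min_genes)
    report["min_genes_removed"] = int(drop.sum())
    keep &= ~drop

    if keep.any():
        det_kept = detected[keep]
        mean = det_kept.mean()
        sd = det_kept.std(ddof=1) if keep.sum() > 1 else 0.0
        cutoff = mean + sd_mult * sd
        drop = keep & (detected > cutoff)
        report["outlier_removed"] = int(drop.sum())
        keep &= ~drop
    else:
        report["outlier_removed"] = 0

    if not keep.any():
        raise ValueError(f"no cells survive QC; report: {report}")

    kept_values = values[:, keep]
    n_kept = int(keep.sum())
    gene_detected = (kept_values > 0).sum(axis=1)
    gene_keep = gene_detected >= min_cell_fraction * n_kept
    report["genes_removed"] = int((~gene_keep).sum())
    report["cells_retained"] = n_kept
    report["genes_retained"] = int(gene_keep.sum())

    out = CountMatrix(
        kept_values[gene_keep, :],
        [g for g, k in zip(counts.gene_ids, gene_keep) if k],
        [c for c, k in zip(counts.column_ids, keep) if k],
        counts.column_kind,
    )
    return out, ann.subset(out.column_ids), report


def write_qc_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(report), indent=2))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(
    counts: CountMatrix, scheme: str = "lognorm10k", pseudo_count: float = 1.0
) -> NormalizedMatrix:
    """Library-size normalize and log-transform.

    ``lognorm10k``: ln(1 + 1e4 * x / libsize), the scanpy/Seurat default.
    ``log2cpm``: log2(pseudo_count + 1e6 * x / libsize).
    """
    lib = counts.library_sizes().astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"zero library size in column {counts.column_ids[zero[0]]!r}")
    if scheme == "lognorm10k":
        vals = np.log1p(1e4 * counts.values / lib)
    elif scheme == "log2cpm":
        vals = np.log2(pseudo_count + 1e6 * counts.values / lib)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return NormalizedMatrix(
        vals, list(counts.gene_ids), list(counts.column_ids), scheme, pseudo_count
    )
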