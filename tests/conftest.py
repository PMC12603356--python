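import numpy as np
import pandas as pd
import pytest

from vice.io_qc import CellAnnotation, CountMatrix


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 cells, two individuals, two cell types."""
    values = np.array(
        [
            [1, 0, 2, 4],
            [2, 3, 0, 0],
            [5, 5, 1, 1],
        ]
    )
    return CountMatrix(values, ["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def tiny_ann() -> CellAnnotation:
    return CellAnnotation(
        pd.DataFrame(
            {
                "cell_id": ["c1", "c2", "c3", "c4"],
                "individual_id": ["ind1", "ind1", "ind1", "ind2"],
                "cell_type": ["Exc", "Exc", "Oli", "Exc"],
            }
        )
    )


def make_single_group(values: np.ndarray) -> tuple[CountMatrix, CellAnnotation]:
    """Wrap a genes x cells array as one individual / one cell type."""
    n_genes, n_cells = values.shape
    cm = CountMatrix(
        values,
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_cells)],
    )
    ann = CellAnnotation(
        pd.DataFrame(
            {
                "cell_id": cm.column_ids,
                "individual_id": "ind1",
                "cell_type": "T",
            }
        )
    )
    return cm, ann


def nb_counts(mu, alpha, size, rng) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws with mean mu, dispersion alpha."""
    if np.isscalar(alpha) and alpha == 0:
        return rng.poisson(np.broadcast_to(mu, size))
    k = 1.0 / np.asarray(alpha)
    lam = rng.gamma(k, np.asarray(mu) / k, size=size)
    return rng.poisson(lam)
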