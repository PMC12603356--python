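"""Design calculator: expected true-positive rate of a pseudo-bulk DE analysis.

Given the planned number of samples per group, the expected effect size
(|log2FC|), and the technical noise level at the planned cell number (the
per-replicate CV measured or interpolated from a precision curve), the
calculator simulates log-scale expression with multiplicative (lognormal)
replicate noise, runs a Welch t-test per gene with Benjamini-Hochberg control
across genes, and reports the fraction of true DE genes detected.  The
lognormal link sd_ln = sqrt(ln(1 + CV^2)) is exact for multiplicative noise,
so CV is the only noise input needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .de import bh_fdr
from .precision import PrecisionCurve

__all__ = ["PowerSpec", "PowerEstimate", "estimate_tpr", "cv_for_cells"]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the TPR calculator.

    ``cv`` is the technical CV of one pseudo-bulk replicate at the planned
    cell number; ``effect_log2fc`` the anticipated absolute log2 fold change
    of DE genes; ``prop_de`` the anticipated fraction of DE genes (affects
    the BH threshold through the p-value mixture).
    """

    n_per_group: int
    effect_log2fc: float
    cv: float
    n_genes: int = 2000
    prop_de: float = 0.25
    fdr_max: float = 0.05
    n_sims: int = 20
    seed: int = 0
    base_log2_range: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if not 0.0 < self.prop_de < 1.0:
            raise ValueError("prop_de must lie in (0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass
class PowerEstimate:
    tpr: float
    mc_se: float
    spec: PowerSpec


def estimate_tpr(spec: PowerSpec) -> PowerEstimate:
    """Monte-Carlo TPR of a BH-controlled per-gene test under the spec.

    Per simulation: baseline log2 expression ~ Uniform(base_log2_range); a
    ``prop_de`` fraction of genes shifts one group by +-effect_log2fc;
    replicate noise is Gaussian on the log scale with
    sd = sqrt(ln(1 + cv^2)) / ln 2; Welch's t per gene, BH across genes; TPR
    is the detected fraction among true DE genes, averaged over simulations.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    sd_log2 = float(np.sqrt(np.log1p(spec.cv**2)) / np.log(2.0))
    n, m = spec.n_genes, spec.n_per_group
    hits = 0
    trials = 0
    for _ in range(spec.n_sims):
        base = rng.uniform(*spec.base_log2_range, size=n)
        is_de = rng.random(n) < spec.prop_de
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        shift = np.where(is_de, sign * spec.effect_log2fc, 0.0)
        g1 = base[:, None] + rng.normal(0.0, sd_log2, size=(n, m))
        g2 = (base + shift)[:, None] + rng.normal(0.0, sd_log2, size=(n, m))
        t = stats.ttest_ind(g2, g1, axis=1, equal_var=False)
        fdr = bh_fdr(np.nan_to_num(t.pvalue, nan=1.0))
        detected = fdr < spec.fdr_max
        hits += int((detected & is_de).sum())
        trials += int(is_de.sum())
    tpr = hits / trials if trials else float("nan")
    mc_se = float(np.sqrt(tpr * (1.0 - tpr) / trials)) if trials else float("nan")
    return PowerEstimate(tpr=float(tpr), mc_se=mc_se, spec=spec)


def cv_for_cells(curve: PrecisionCurve, cells: int) -> float:
    """Median CV at ``cells`` per replicate, log-log interpolated on the curve.

    Interpolation between measured grid points only; queries outside the grid
    range are refused rather than extrapolated.
    """
    pts = curve.points
    x = pts["cells_per_replicate"].to_numpy(dtype=float)
    y = pts["median_cv"].to_numpy(dtype=float)
    if cells < x[0] or cells > x[-1]:
        raise ValueError(
            f"extrapolation refused: {cells} outside measured range [{int(x[0])}, {int(x[-1])}]"
        )
    if np.any(y <= 0):
        # flat-zero medians cannot be log-interpolated; fall back to linear
        return float(np.interp(cells, x, y))
    return float(np.exp(np.interp(np.log(cells), np.log(x), np.log(y))))
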