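# Methods

## The problem

Single-cell and single-nucleus RNA-seq measure each gene in each cell with
very few reads, so any per-gene expression estimate carries substantial
technical noise. This package quantifies that noise and its downstream
consequences through four linked analyses:

1. **Precision** — how repeatable is a pseudo-bulk expression estimate built
   from a given number of cells?
2. **Accuracy** — how close are single-cell pseudo-bulks to a matched bulk
   (pooled-cell) measurement of the same samples?
3. **DE reproducibility** — what fraction of ground-truth differentially
   expressed genes (DEGs) does a pseudo-bulk DE analysis recover at a given
   cell number, and which genes replicate?
4. **Design** — given a planned cell number (hence noise level), sample size,
   and expected effect size, what true-positive rate should a study expect?

## Precision: CV over randomized technical replicates

For one individual and one cell type, the cells are randomly partitioned into
`g = 3` disjoint, equal-size groups and each group's counts are summed into a
pseudo-bulk technical replicate. Per gene *i*,

    CV_i = sd(x_i) / mean(x_i)

with the sample standard deviation (n−1 denominator) over the g replicate
values. One partition is noisy, so the partition is redrawn `R = 100` times
(repeat *r* uses seed `seed_base + r`) and the per-gene CV is averaged over
the repeats in which the gene is detected (nonzero total across replicates).
The per-sample summary is the **median CV over detected genes**; 0.1 is the
conventional pass threshold carried over from bulk-tissue QC.

Why this decays with cell number: if a replicate sums *m* i.i.d. Poisson(λ)
cells, the replicate total is Poisson(mλ) and E[CV] ≈ 1/√(mλ). The measured
three-replicate CV sits ~11% below this closed form because the sample
standard deviation of three values is biased low (the c₄ ≈ 0.886 correction
factor); the acceptance check allows for exactly this.

Choices that matter:

- CV is computed on raw summed counts (replicates have equal cell numbers by
  construction, so library sizes are comparable); a `normalize=True` flag
  switches to counts-per-million first for unequal-depth settings.
- Remainder cells (n mod g, or cells beyond `g * cells_per_replicate`) are
  discarded, never redistributed: equal replicate sizes keep CV comparable
  across repeats and grid points.
- The downsampling grid defaults to {1, 2, 5, 10, 20, 50, 100, 200, 500,
  1000, 2000, 5000} ∩ [1, floor(n/3)].
- `min_cells_for_cv` reads the smallest grid value whose median CV is at or
  below the threshold; `cv_for_cells` interpolates the curve log-log (CV
  decay is close to a power law, so log-log interpolation is the natural
  scale) and refuses to extrapolate.
- Sample-level covariate relationships (e.g. RNA integrity vs median CV) use
  ordinary simple linear regression; two CV-vs-cells slopes from different
  datasets are compared with the normal two-sample Z statistic
  `(b1 − b2)/√(se1² + se2²)`.

## Accuracy: correlation plus a through-origin slope test

Single-cell pseudo-bulks and the matched reference bulk are both transformed
to log2 CPM (pseudo-count 1, library sizes taken before restricting to the
common gene set). A per-gene location-scale adjustment then aligns the two
platforms: each side is shifted and scaled so its across-sample mean and
standard deviation equal the grand mean and the pooled within-side standard
deviation (root mean of the two side variances — this choice makes the map
exactly idempotent). This is a deliberate simplification of empirical-Bayes
batch correction: with exactly two batches of matched samples, the dominant
batch effect *is* a per-gene shift and scale.

Per gene, with reference values x and single-cell values y over n ≥ 3
matched samples:

- Pearson correlation r(x, y);
- regression through the origin: b = Σxy/Σx², se = √(RSS/((n−1)·Σx²)),
  and a two-sided t test of (b−1)/se on n−1 degrees of freedom (one fitted
  parameter);
- **good accuracy** ⇔ r > 0.9 and slope-test p > 0.05 — strongly correlated
  with no detectable multiplicative bias.

Degenerate cases: all-zero reference → slope undefined, good=false;
zero variance on either side → r undefined, good=false; an exact fit
(se = 0) gives p = 1 when b = 1 and p = 0 otherwise.

## Differential expression: two-stage NB-GLM LRT

Pseudo-bulk counts per sample are modeled as negative binomial with log link
and log effective-library-size offsets; the full model has one mean per
condition, the null a single mean; twice the log-likelihood difference is
referred to χ²(1). Benjamini–Hochberg controls FDR across genes, and DEGs
are called with strict inequalities (fdr < 0.05, |log2FC| > threshold; the
optional threshold 0.1 mirrors the replication analyses of case-control
brain cohorts).

- **Offsets.** Default effective library sizes are DESeq-style
  median-of-ratios size factors. Raw column totals are not
  composition-robust: when a subset of genes changes (or a simulator
  renormalizes expected shares), total-count offsets drag every null gene's
  apparent fold change away from zero, which at pseudo-bulk depth turns the
  entire transcriptome significant. `norm="libsize"` restores plain totals.
- **Dispersion** is estimated once and held fixed during the GLM fits (the
  standard two-stage recipe). The per-gene estimate is a bias-corrected
  method-of-moments value on depth-scaled, group-centered counts,
  α̂ = (v − m)/(m² − v/N). A **common** dispersion comes from the Cox-Reid
  adjusted profile likelihood (the adjustment subtracts half the
  log-determinant of the Fisher information of the fitted means; without it
  the common estimate is biased low at 3 vs 3 samples). Per-gene and common
  estimates are combined with empirical-Bayes weights, d/(d + d₀) on the
  per-gene value with residual df d = N − 2 and prior df d₀ = 20, floored at
  zero. The strong shrinkage is what keeps the LRT calibrated at small n:
  measured null type-I error is ~0.051 at p < 0.05 (3 vs 3, dispersion 0.1),
  against ~0.073 for an unshrunk-leaning 50/50 mix.
- **Fitting.** One mean parameter per group is solved by Fisher scoring on
  the score equation Σ(y − μ)/(1 + αμ) = 0, vectorized across genes; steps
  are clipped to ±2 on the log scale, convergence tolerance 1e−8, at most
  100 iterations; non-converged genes are flagged and assigned p = 1.
  All-zero genes sit at a rate floor of e⁻³⁰ and are exactly null.

## Reproducibility: TPR, strata, and SNR

Given a ground-truth DE table (pooled-cell data, or full-depth pooled
pseudo-bulks in simulation) and a test DE table on the same gene universe,
the true-positive rate is |truth DEGs ∩ test DEGs| / |truth DEGs|. Truth
DEGs are stratified by effect size: high |log2FC| ≥ 2, medium strictly
between 1 and 2, low ≤ 1. By default strata use the truth table's estimated
fold changes (all real data offers); in simulation the generative fold change
is used instead, because estimated fold changes of weakly expressed genes are
noise-inflated and would populate the high stratum with exactly the genes
least able to replicate.

The per-gene signal-to-noise ratio is SNR = |log2FC| / CV, pairing the
effect size with that gene's technical CV at the evaluated cell number;
genes with undefined or zero CV are excluded. Replicated DEGs separate from
non-replicated ones on this metric by orders of magnitude in the synthetic
experiment.

Replication between two independent DEG sets over a shared universe is
scored with the hypergeometric over-representation tail
P(X ≥ overlap), X ~ Hypergeom(universe, |A|, |B|).

## The simulator

A splat-style gamma-Poisson "group" simulation with two conditions and known
truth:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes |
| `n_cells_per_sample` | 3000 | cells per sample (validated range 10–3000) |
| `n_samples_per_group` | 3 | replicate samples per condition |
| `de_prob` | 0.25 | probability a gene is DE |
| `de_factor_loc`, `de_factor_scale` | 0.1, 0.4 | lognormal fold-factor of DE genes (log scale) |
| `mean_shape`, `mean_rate` | 0.6, 0.3 | Gamma base expression means |
| `lib_loc`, `lib_scale` | ln 10⁴, 0.2 | lognormal per-cell library sizes |

Per gene: base mean ~ Gamma(shape, rate); DE genes receive a lognormal
fold-factor applied up or down with probability 1/2 in the second condition
(`true_log2fc` records the signed log2 factor). Per cell: library size
~ lognormal; expected counts are the condition's renormalized gene shares
times the library size; observed counts are Poisson. Marginally over cells
this is a mixed-Poisson (NB-like) overdispersed count model; sparsity arises
from the skewed gamma means and finite libraries, with no separate dropout
layer. The per-condition share renormalization deliberately preserves the
compositional coupling of real libraries (one gene up means every other
gene's share down) — the median-of-ratios offsets in the DE engine exist to
handle exactly this.

What the simulator does **not** emulate: sample-level biological random
effects (samples within a condition are exchangeable, so pseudo-bulk
variation is purely technical — real cohorts are noisier and DE power
correspondingly lower), batch effects, multiple cell types, cell-state
trajectories, and UMI saturation. Green tests therefore establish internal
consistency of the framework under its stated noise model, not field
performance on any particular tissue.

## The power calculator

`estimate_tpr` simulates the planned experiment directly on the log2 scale:
per-gene baselines uniform on [1, 10] log2 units; a `prop_de` fraction of
genes shifted by ±effect in one group; replicate noise Gaussian on the log
scale with σ_ln = √(ln(1 + CV²)) — exact for multiplicative noise, so the
measured CV is the only noise input needed; Welch's t per gene and BH across
genes. The TPR is averaged over `n_sims` simulations with a binomial-style
Monte-Carlo standard error. The internal test is Welch's t rather than the
full NB-LRT for speed; the acceptance suite bounds the approximation by
requiring agreement within 0.1 of the full simulate → downsample → NB-LRT
pipeline on a matched configuration (measured gap ~0.05: the calculator's
single median CV understates the noise of weakly expressed genes, making it
mildly optimistic).

## Numerical conventions

- All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; repeat r of R uses `seed_base + r`.
- Ties and boundaries: DEG calls use strict inequalities; `min_cells_for_cv`
  uses ≤; stratum boundaries are closed exactly as printed (high ≥ 2,
  low ≤ 1).
- BH adjustment delegates to statsmodels (`fdr_bh`) and is cross-checked
  against hand-computed values.
- QC filter order is fixed (mitochondrial fraction → min detected genes →
  detected-genes outlier → gene prevalence), with outlier statistics
  computed on cells surviving the first two rules; the gene rule keeps genes
  detected in at least 0.1% of retained cells. The literal reading of the
  source recipe ("genes with zero expression in more than 1/1000 of cells")
  would remove nearly every gene; the prevalence form is the evident intent.
- Mitochondrial genes are recognized by id prefix (default `MT-`).

## Known limitations

- Two-group designs only; no covariates, no quasi-likelihood F tests.
- The location-scale batch adjustment cannot absorb batch-by-gene rank
  changes the way empirical-Bayes shrinkage across genes can.
- The power calculator treats all DE genes as sharing one effect size and
  one CV; heterogeneous panels should be run stratum by stratum.
- `accuracy_downsampling_curve` assumes one cell type per individual in the
  single-cell matrix (the matched-culture design it models).
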