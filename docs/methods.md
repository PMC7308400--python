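# Methods

## Model and procedure

UMI counts are treated as a gamma-Poisson hierarchy: `X_ij ~
Poisson(s_j λ_i)` per gene i and cell j, with latent expression `λ_i ~
Gamma(α, β_i)`, shape α shared by all genes and cells, and the size factor
`s_j` defined as the cell's total count divided by the mean total across
cells (so `mean(s) = 1` and `E(X_i) = E(X_i / s)`).  The differential
entropy of the latent expression is then `S_i = ln E(X_i) + a` where
`a = α − ln α + ln Γ(α) + (1 − α)·ψ(α)` is gene-independent.  Neither α,
β_i nor `a` is ever computed: they cancel in the residual below, which is
the reason UMI pipelines here run directly on raw counts.

Under the one-component null every gene sits on a smooth curve between
`S` and the log mean expression.  Treating each cell as its own
"cluster" of size one, the plug-in estimate of the average actual entropy
is `mean_j ln(X_ij)`, and the entropy reduction is

```
ds_i = [null-trend entropy at ln E(X_i)] − mean_j ln(X_ij).
```

A pure population gives `ds ≈ 0` for every gene; genes restricted to a
subpopulation have depressed `mean_j ln X` (Jensen gap of the bimodal
distribution) and positive `ds`.

Pipeline order: detection filter → per-gene entropy terms → LOESS null
trend → residuals `ds` → normal-approximation significance with BH
correction → `ROGUE = 1 − Σ_sig ds / (Σ_sig ds + K)`.

## Parameters and defaults

- **Pseudocount `r` = 1.**  `ln X` is undefined at zero counts, so both
  entropy terms use it symmetrically: `obs = mean_j ln(X_ij + r)`,
  `null input = ln(mean_i + r)`.  A gene with identical counts in every
  cell therefore has a raw difference of exactly 0 for any `r > 0`.
- **LOESS: span 0.5, local quadratic, tricube weights, 2 refit
  iterations.**  Variable genes pull the trend toward themselves, so after
  each fit the BH-significant genes (at the same α as the final test) are
  excluded and the curve refit; the final `ds` of *all* genes is taken
  against the final curve.  For more than 500 points the curve is
  evaluated at 500 evenly spaced order-statistic knots and interpolated
  linearly — the standard large-n LOESS strategy; at ≤500 points the fit
  is exact at every point.  Degenerate inputs (all log-means identical,
  or <20 genes) raise rather than guess.
- **Significance: one-sided.**  `p_i` is the upper-tail probability of
  `ds_i` under `Normal(mean(ds), sd(ds))` with moments from all genes;
  negative residuals are never "informative".  `sd(ds) = 0` yields all
  p = 1 with a warning.  BH step-up at **α = 0.05** defines the
  significant set.
- **Reference factor K: 45 (droplet/UMI), 500 (full-length).**  These are
  the established atlas-derived constants; `determine_k` recomputes K as
  half the significant-ds sum of any user-supplied heterogeneous
  reference, and errors when the reference has no significant gene.  The
  ROGUE *ranking* of populations is invariant to K, so moderate changes
  (30–60) only rescale scores.  A score of 0.9 is a reasonable purity
  threshold for droplet data; it is documentation, not behaviour.
- **Filters: genes detected in ≥10 cells, cells with ≥10 detected genes**,
  iterated to a fixed point (a single gene-then-cell pass is not
  idempotent because removing cells can re-expose under-detected genes).
- **Grouped scoring: min 20 cells per (cluster, sample) group.**  Each
  group gets the full pipeline on its own cells — per-sample scores need
  subset-level null trends, not slices of a global fit.  Smaller groups
  are reported missing (NaN), never 0.

## Synthetic data

The generators produce the conditions under which the statistic's
behaviour is established:

- `simulate_nb`: 20,000 genes × 2,000 cells by default; gene means
  log-normal (`μ = 0, σ = 2`), counts `NB(mean = E_i, size = r)` with
  fixed dispersion `r = 10` (midpoint of the 5–20 range characteristic of
  droplet data; variance `E + E²/r`).
- `simulate_zinb`: adds per-gene sigmoid dropout
  `P_i = sigm(−(γ0 + γ1 E_i))`, `γ0 = −1.5`, `γ1 = 1/median(E)` —
  full-length-style technical zeros, decreasing in expression.
- `inject_de_genes`: multiplies the means of a random gene fraction by
  log-normal fold changes (`μ = 0, σ = 2`) inside one shared random cell
  subset and re-draws those entries only.  Ground truth uses the
  *realized* population mean ratio `1 + f(fc − 1)` (affected fraction f)
  with the 1.5-fold rule, so a large sampled fold change diluted by a
  small cell fraction is correctly labelled non-DE.
- `simulate_depth_pair`: replicate 2 redrawn from `means × δ`,
  `δ ∈ {2, …, 100}` — a pure population with an extreme depth confounder.
- `simulate_multitype`: 2–3 types sharing a base mean vector; "major"
  genes separate type A from B/C (σ = 2 fold changes), "minor" genes
  separate the similar subtypes B and C (σ = 1); default 10,000 genes ×
  1,000 cells per type with 500/100 varied genes.

What the simulations do **not** emulate: batch effects, amplification
noise beyond NB dispersion, gene–gene correlation, trajectories/continuous
states, and empirical mean-variance trends estimated from real data.
Passing tests therefore demonstrate the statistic's behaviour under its
own generative assumptions (plus dropout and depth confounders), not
performance on arbitrary real datasets.

## Numerical choices

- Natural logarithms throughout; matrices are genes × cells.
- Gene ranking by `ds` breaks ties lexicographically by gene id, making
  every output deterministic byte-for-byte for a given seed.
- `ds` is exactly invariant to a global count rescaling `X → cX` when the
  pseudocount is expressed in the same units (`r → cr`): both entropy
  terms shift by `ln c` and the shift is absorbed by the trend.  At fixed
  `r = 1` the invariance is approximate (the ranking of strongly
  informative genes is stable; near-zero residuals can permute).
- Silhouette widths use the exact pairwise-distance definition
  `s = (b − a)/max(a, b)`; singleton clusters and `max(a, b) = 0` score 0.
  The default distance space for expression data is Euclidean on
  `ln(count + 1)`, because raw-count distances are depth-dominated by
  construction in the depth experiments.
- DE-recovery AUC uses midrank tie handling (Mann–Whitney); ds ties are
  common at filtered zeros.
- Down-sampling stability draws cells without replacement and correlates
  per-gene entropy over the genes retained by both the full-data and
  subsample filters (symmetric exclusion).
- All randomness flows through `numpy.random.default_rng(seed)`; derived
  seeds come from `SeedSequence.generate_state`.

## Problem sizes used in the checks

Analytic anchors are exact.  The subsample-correlation and depth-pair
checks run at the full benchmark scale (20,000 genes; 2,000 pooled
cells).  The varied-gene monotonicity grid runs at 5,000 genes × 500
cells over 10 seeds, the null-behaviour suite at 2,000 genes × 400 cells
over 50 seeds, and the DE-recovery floor at 4,000 genes × 600 cells over
20 seeds; these sizes keep the whole suite to a few minutes while leaving
every Monte-Carlo margin wide.  Silhouette on depth pools uses 300 cells
per replicate (the estimate is exact on the subsample).

## Known limitations

- The normal approximation for `ds` is slightly light-tailed for
  low-expression genes in small matrices, giving rare false positives
  (~0.2% of genes at 2,000 × 400; ~0.005% at full scale).  Their `ds`
  values are tiny, so ROGUE stays ≥0.99 on pure data.
- Full-length data are scored on the provided values (counts or TPM)
  as-is; whether to library-size normalize them first is left to the
  user (`normalize_library_size` is provided).
- The default K values are atlas-derived constants for mouse droplet /
  full-length data; cross-species use should derive K from a matched
  heterogeneous reference via `determine_k`.
- `inject_de_genes` on a ZINB base reuses each gene's original dropout
  probability for redrawn entries rather than recomputing it from the
  perturbed mean.
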