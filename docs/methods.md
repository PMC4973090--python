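# Methods

## Model

For a gene *i* measured in two conditions A and B the test statistic is
the absolute difference of read-count sums, D_i = |Σ_A c_ij − Σ_B c_ij|.
D_i is discrete and inherits the overdispersion of the count sums, so it
is modelled as negative binomial with mean m and size r (variance
m + m²/r; scipy's success probability is r/(r+m)). The p-value is the
upper tail P(X ≥ D_i) = 1 − CDF(D_i − 1): large absolute differences
relative to the null expectation are evidence of differential
expression, and D_i = 0 gives p = 1 by construction. BH step-up
adjustment yields FDR-controlling q-values.

The null parameters are built from the data in five steps.

1. **Normalization.** Per-sample size factors are either the 0.75
   quantile of the sample's nonzero counts (default) or the
   median-of-ratios against per-gene geometric means. Factors are
   rescaled to geometric mean 1 (average library depth preserved; no
   anchoring convention is canonical, this one keeps counts on their
   original scale) and normalized counts are rounded half-away-from-zero
   back to integers, because every downstream quantity is a count.
2. **Outlier replacement.** On log(c+1), per gene per condition, the
   raw MAD (unscaled — it is blended directly with an SD, so no
   1.4826 consistency constant) is shrunk toward σ₀, the fitted
   log-scale SD at mean count 1: M̂² = (n·M² + n₀σ₀²)/(n + n₀) with
   n₀ = 2 by default. Cells more than 2·M̂ above the condition median
   are replaced by round(exp(median + M̂) − 1). σ₀ is estimated by a
   lowess fit of per-gene log-SD on per-gene log-mean, forced monotone
   non-increasing (dispersion is highest at low expression) and
   evaluated at log 2; degenerate fits fall back to the maximum
   observed per-gene log-SD. One pass of the rule is not idempotent —
   replacing an extreme value shrinks the MAD and can expose a further
   borderline cell — so the rule is iterated to a fixed point, which
   makes the operation idempotent and the flag set well defined.
3. **Dispersion moderation.** The pooled dispersion
   v_i = (s²_A + s²_B − μ_i)/μ_i² (μ_i the larger condition mean) may
   be negative. A lowess fit of √v on μ over the v > 0 genes (span
   0.75; fewer than 10 positive genes degrade to their mean) gives the
   trend v̂_i, clipped at 0 and squared. The penalized dispersion is
   v̄_i = v₀ + v_i + v̂_i/n, floored at 1e-10, with size r̂_i = 1/v̄_i.
   The basic penalty v₀ is the √β quantile (linear-interpolation,
   type 7) of the positive v_i, where β is the fraction of genes with
   v_i < 0 — many underdispersed genes indicate the trend was fitted
   on an unrepresentative subset, and the penalty grows accordingly.
4. **Mean moderation.** θ = sqrt(mean((s²_A + s²_B)/2)) is the
   background uncertainty; each gene receives a pseudocount
   μ₀_i = sqrt((θ/μ_i)·ŝ²_i/(n−1)) with ŝ²_i = μ_i + v̂_i μ_i² the
   smoothed variance, added n times to the larger group sum
   (ĉ_i = c_i + n μ₀_i). A noise term ε_i = sqrt(n·max(s²_A+s²_B, μ_i))
   guards genes whose tiny observed variance would otherwise make the
   test anti-conservative at low expression. The null mean is
   m̂_i = α(ĉ_i + ε_i).
5. **CV estimate.** α is the mean per-gene residual SD of log2(c+1)
   under the two-group-means model with pooled df n_A + n_B − 2
   (log-scale SD ≈ CV on the original scale), floored at 1e-4 so the
   null mean can never collapse to zero; a user-supplied α overrides
   the estimate.

Unequal group sizes would bias D_i toward the larger group, so the
smaller group's sum is compensated with (n_large − n_small)
pseudo-replicates equal to its own mean before differencing; variances
are still computed from the observed replicates only, and the
compensated sums also define c_i and the fold-change sign. In paired
designs the variance term s²_A + s²_B is replaced throughout (v_i, θ,
ε) by the sample variance of per-pair differences. The "n" appearing
in the moderation steps is max(n_A, n_B). Genes with zero counts in
both conditions get p = 1.

## Fold-change shrinkage

|FC_i| = log2(c_i/(c_i − D_i)), signed by the larger condition
(positive = higher in the second condition, B vs A; log2 because fold
changes in this field are reported in doublings). Three variants:
`raw` uses (c_i, D_i) and is infinite for exclusively expressed genes;
`expr` substitutes ĉ_i, taming low-count genes; `full` additionally
replaces D_i by D̂_i, the smallest integer whose NB upper-tail
probability at (m̂_i, r₀) is ≤ p_i, where r₀ = 1/mean(v̄) is the
common size. Moderation applies only to genes with r̂_i < r₀ (higher
than common dispersion) and D̂_i is capped at D_i: below the mean the
thinner common-dispersion tail can push the quantile above the
observed statistic, and the moderation is defined as shrinkage only.
Since p-values are untouched, the significant set is identical before
and after. The quantile inverts the same upper-tail convention as the
p-value, so quantile(pvalue(D)) = D wherever the pmf is positive.

## Simulator

`simulate_counts` emulates the standard two-group NB benchmark:
baseline means lognormal(6, 1.5) (high-expression genes, median ≈ 400
reads), gene dispersions φ(μ) = 0.04 + 0.8/μ scaled by lognormal(0,
0.3) noise — a quadratic mean-variance law with asymptotic CV ≈ 0.2,
typical of good laboratory replicates — and NB counts at those
moments (φ = 0 gives Poisson; `poisson_fraction` reproduces the
half-NB/half-Poisson setting). DE genes (defaults: 625 up + 625 down
of 12,500) scale the B-condition mean by 2^lfc with |lfc| = 1.5 +
Exp(1). Outlier injection selects genes with probability 0.05 and
multiplies one randomly placed count per selected gene by a uniform
5–10× factor. Everything is driven by one `numpy` Generator, so a
seed pins the dataset.

What the generator does *not* emulate: correlated genes, library-
composition biases, sample-quality gradients, low-expression tails
(means are intentionally high, matching the benchmark's gene
filtering) and the very high biological dispersions of human
population samples. Passing tests therefore demonstrate correctness
and robustness of the machinery under the stated regime, not
performance on arbitrary real data.

## Numerical choices and edge cases

- NB tails via `scipy.stats.nbinom.sf`; the quantile uses `isf` plus
  an exact local refinement so it is the true smallest-integer
  inverse.
- lowess (statsmodels) with span 0.75 and delta = 1 % of the x-range
  stands in for the locally fitted trend; the contract is
  constant-function recovery (1e-3) and rank agreement with the true
  trend, not a specific smoother.
- Quantile convention everywhere is numpy's default linear
  interpolation (type 7).
- Rounding is half-away-from-zero wherever scaled counts return to
  integers.
- Degenerate guards: v̄ floored at 1e-10, α at 1e-4; all-zero genes
  get p = 1 and fold change 0; a condition with one sample never
  yields outlier flags (no deviation from its own median); samples
  with all-zero counts are an error for the quantile scheme, as is a
  reference-free matrix for median-of-ratios.
- Evaluation: the AUC is the trapezoid under the sklearn ROC curve,
  which equals the tie-corrected Mann–Whitney probability exactly;
  the type-I error rate uses raw p < 0.05 (strict), matching the
  benchmark protocol.

## Problem sizes

The shipped end-to-end checks run the full benchmark geometry —
12,500 genes, 10 repetitions, n = 5 (null) and n = 10 (DE with
outliers) — which completes in seconds; unit and property tests use
2,000–3,000-gene versions of the same generator settings.

## Known limitations

Two conditions only (no covariates, no >2-group designs, no
transcript-level inference); the quantile normalization uses nonzero
counts only (configurable q); the test is deliberately conservative —
under the simulator's null the minimum p-value across 125,000
gene-tests exceeds 0.2, so power at very small effect sizes is traded
for strong type-I error control; σ₀ estimation on datasets with
near-constant genes falls back to a coarse maximum; the estimated α
on the default DE simulation (~0.32) sits at the upper edge of the
usual 0.1–0.3 band because the generator's lognormal dispersion noise
adds gene-to-gene spread on top of the asymptotic CV.
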