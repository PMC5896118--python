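# Methods

## Model

For a panel of M genes measured as RNA-Seq counts at L ordered time points
(with R replicates per time point), the package learns a first-order dynamic
Bayesian network: each gene's count at time t depends only on the values of
its parent genes at time t−1. Parent sets are learned by one sparse
regression per gene. For gene i with response y = counts at times 2..L and
design X = (transformed) values of the other W = M−1 genes at times 1..L−1,

    y_t ~ NB2( s_t · exp(X_{t−1} β),  ω )

where NB2 denotes the negative binomial with mean μ and variance μ + μ²/ω,
s_t is the per-sample size factor (sequencing depth), β holds W slope
coefficients plus an intercept β_c, and ω is a gene-level dispersion.
Sparsity comes from a horseshoe prior on the slopes:

    β_w ~ N(0, ζ²_w),   ζ_w ~ C⁺(0, τ),   τ ~ C⁺(0, σ),   p(σ²) ∝ 1/σ²

with the half-Cauchy scales represented as two-level inverse-gamma mixtures
(ζ²|a ~ IG(1/2, 1/a), a|τ² ~ IG(1/2, 1/τ²), and likewise for τ²|b, b|σ²),
which makes every scale update conjugate. The intercept gets N(0, 10²) and
the dispersion a weakly informative Gamma(0.01, rate 0.01); both are
configuration, since any choice here is mildly informative at worst for
count data on this scale.

Size factors enter as a fixed offset log s_t added to the linear predictor.
This keeps all variational updates identical to the offset-free algebra
while still normalizing depth. They are estimated by median-of-ratios
(geometric-mean reference per gene, per-sample median of count/reference,
genes containing zeros excluded), with a total-count fallback when no gene
is positive everywhere.

## Inference

The NB2 likelihood is augmented as a Poisson–Gamma mixture: y_t ~
Pois(λ_t), λ_t ~ Gamma(ω, ω e^{−η_t}) with η_t the linear predictor. The
posterior is approximated by the mean field

    q = ∏_t q(λ_t) · q(β) · q(ω) · ∏_w q(ζ²_w) q(a_w) · q(τ²) q(b) q(σ²).

Closed-form coordinate updates exist for every factor except q(β) and q(ω):

- q(λ_t) = Gamma(y_t + E[ω], 1 + E[ω]·E[e^{−η_t}]), with the log-normal
  identity E[e^{−η_t}] = exp(−X_t μ − offset_t + ½ X_t Σ X_tᵀ).
- q(β) = N(μ, Σ) updated by one non-conjugate variational message passing
  (NCVMP) step per sweep: Σ = [E[ω] Xᵀ diag(E[λ]·w) X + M]⁻¹ with
  w = E[e^{−η}] and prior precision M = diag(E[1/ζ²_w]) (1/100 for the
  intercept), then μ ← μ + Σ[E[ω] Xᵀ(E[λ]·w − 1) − Mμ].
- q(ω) is a discrete distribution on a fixed quadrature grid, 200 points
  log-uniform on [10⁻², 10³]; pointwise weights are the expected
  Gamma(λ|·) log-density plus the prior, normalized by log-sum-exp.
- The horseshoe chain updates are inverse-gamma with fixed shapes
  (1, 1, (1+W)/2, 1, 1/2) and scales built from reciprocal expectations
  E[1/·] = shape/scale. (The ζ² scale uses E[1/a_w]: the auxiliary enters
  the chain through its reciprocal, and the plain mean of an IG(1,·) is not
  finite.)

Sweeps run λ → β → ω → horseshoe until the relative ELBO change falls below
10⁻⁶ (or 500 sweeps; non-convergence is flagged and warned, never raised).
NCVMP does not guarantee a monotone bound, so the β step is damped: when the
ELBO drops more than 10⁻⁸, the proposed (μ, Σ) is pulled halfway back toward
the previous Gaussian, up to 8 halvings, keeping the old state if none
helps. The ELBO treats q(ω) as a piecewise-constant density over grid cells
so its entropy is on the continuous scale; with ω or ζ² held fixed
(validation modes) the corresponding terms drop out, making the bound
directly comparable to brute-force evidence for the reduced model.
Exponents in E[e^{−η}] are clipped at ±50 and clip events counted. The fit
is fully deterministic given data and configuration.

## Network assembly and edge calling

Each ordered pair (parent → child), parent ≠ child, receives the child-fit
posterior mean and sd of the parent's coefficient, and the score

    score = 1 − 2 Φ(−|μ_w| / sd_w),

the posterior probability that the coefficient shares the sign of its mean
minus the opposite tail. score > 0.95 holds exactly when zero lies outside
the central 95% credible interval, so the probability cutoff and the
interval criterion select identical edge sets (asserted in the test suite).
The same score ranks edges for the PR/ROC curves. Self-edges are excluded:
each gene's own column is dropped from its design matrix. Betweenness
centrality of the selected digraph is the normalized fraction of all-pairs
directed shortest paths through each node.

### Predictor transform

Raw counts are a poor regressor inside exp(Xβ) when slopes are of order
0.3: a hub parent with counts in the thousands would explode the mean. The
default transform is log(1 + count/s) per predictor, centered and scaled to
unit variance over the design rows ("log-std"); "log" and "raw" modes are
available and recorded in run metadata. Constant predictor columns become
all-zero and are flagged rather than dropped. This transform choice is the
largest open design point in the method and deliberately surfaced in
configuration.

## Synthetic benchmark

The generator reproduces the study conditions used throughout the tests:

- **Structure.** Directed graphs with heavy-tailed out-degree: parent
  propensities from a Pareto(1.2) draw, children uniform, distinct edges
  accumulated to a target of mean in-degree 1.5 per node (density well
  under 10% of ordered pairs at the 25- and 50-node sizes). A breadth-first
  module-extraction path subsamples a user-supplied reference edge list
  instead, for users with a curated network.
- **Coefficients.** Nonzero β from the equally weighted mixture
  N(+0.3, 0.1²) / N(−0.3, 0.1²); 0.1 is read as a standard deviation.
  Tests of strong-signal recovery move the component means to ±0.8.
- **Baselines.** Per-gene (mean, dispersion) pairs drawn with replacement
  from a packaged synthetic table (500 genes, log-normal means with median
  ≈ 20 and a heavy right tail, dispersions log-uniform in [0.05, 5],
  generated from a fixed internal seed). The table emulates the marginal
  moments of a deep multi-tissue RNA-Seq compendium; no download is needed.
- **Dynamics.** Time 1 is drawn per gene from its baseline NB2; afterwards
  gene j at time t is NB2 with log mean = log(baseline mean_j) + Σ_w β_wj
  z_w(t−1) (+ log s_t), within each replicate. The generator's predictor
  value z_w is log(1 + count/s) centered at log(1 + baseline mean_w) with
  unit scale — the same log transform the estimator uses, but with causal
  centering, since a sequential simulator cannot standardize against
  statistics of data it has not yet produced. The estimator's empirical
  standardization then only rescales coefficients, leaving edge identity
  intact. Default design: 20 time points × 3 replicates; size factors
  default to 1, optionally log-normal with sd 0.2 to exercise depth
  normalization.
- Structure, parameter, and count draws use independently spawned streams,
  so each stage is separately reproducible.

What the generator does not emulate: ODE/SDE-style kinetics, measurement
protocols upstream of the count matrix, intra-slice (same-time-point)
dependence, and zero-inflation. Passing benchmarks here therefore
demonstrate correctness of the estimator under its own model class plus
realistic count marginals, not performance on arbitrary real dynamics.

## Evaluation

Directed evaluation over all M(M−1) ordered pairs; (i→j) and (j→i) are
scored separately.

- **MCC** from the 2×2 confusion matrix of the binary calls; 0 (with a
  warning) when a marginal is zero.
- **AUC-PR** with continuous interpolation between operating points: false
  positives accrue linearly with true positives along each segment and
  precision is integrated over recall in closed form, tied scores merged
  into one threshold. A dense numeric integration of the same curve serves
  as the independent oracle in the tests.
- **Partial AUC-ROC** over the high-specificity region (false-positive rate
  ≤ 0.05 for the default cutoff 0.95), McClish-standardized so 0.5 is
  chance and 1 perfect. The cutoff is interpreted as a specificity bound;
  a sensitivity-bound variant is available via a flag.

## Problem sizes and defaults used in checks

The packaged acceptance run uses 25-node networks (20 time points, 3
replicates, 5 repeats) for the full pipeline, 10-node networks for
strong-signal recovery and time-shuffled null checks, 10⁶ Monte-Carlo draws
for the Poisson–Gamma identity, 10⁵ for the half-Cauchy chain identity, and
an 8-observation single-predictor toy (fixed ω and slope-prior variance)
where the exact evidence is computable on a 501² grid. A 50-node run is
supported through the same interfaces.

## Known limitations

- The NCVMP Gaussian underestimates posterior spread, as mean-field
  approximations do; credible intervals are approximate and the 0.95
  cutoff should be read as a ranking device more than a calibrated error
  rate.
- The dispersion grid bounds [10⁻², 10³] are configuration; data truly
  outside that range would need a wider grid (the updater raises a
  diagnostic if all weights underflow).
- Transitions never cross replicate boundaries; replicates are assumed
  exchangeable and time points evenly informative.
- Betweenness is computed on the thresholded digraph with unit weights;
  it inherits the cutoff's arbitrariness.
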