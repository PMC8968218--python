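# Methods

This note documents the statistical machinery implemented in `dissonet`, the
assumptions behind it, the defaults and why they were chosen, and what the
synthetic-data validation does and does not establish.

## Problem setting

The package reimplements a two-stage network analysis of questionnaire data:
twelve psychological constructs (felt-sense-of-anomaly dissociation plus
eleven candidate mechanisms) measured by multi-item Likert scales on a large
online sample. Stage one estimates an undirected Gaussian graphical model
(GGM) whose edges are partial correlations; stage two performs Bayesian
structure learning over directed acyclic graphs (DAGs) and averages causal
summaries over the posterior sample. Because the original participant data
are not distributable, the package ships a synthetic-study generator with
known causal ground truth, and all validation is by parameter recovery and
small-instance exact oracles.

## Synthetic studies

Construct scores follow a linear-Gaussian structural equation model
`X_j = Σ_{k∈pa(j)} w_kj X_k + ε_j` with ε_j ~ N(0, σ_j²); the population
covariance is `(I−W)⁻ᵀ D (I−W)⁻¹`. Each construct then emits its scale's
items as one-factor congeneric indicators: the item latent is
`λ·z + √(1−λ²)·noise` with `z` the standardized construct score, discretized
at equiprobable standard-normal thresholds into the item's response range.
Reverse-keyed items are stored flipped, so scoring must un-flip them.
Missingness is injected MCAR, cell-wise.

Defaults mirror the emulated survey: n = 6161 respondents; the twelve scales
with their published item counts and response ranges (e.g. the dissociation
scale: 35 items scored 0–4, totals 0–140); per-scale loadings λ obtained by
inverting the one-factor Cronbach's-alpha formula
`α = kλ²/(1+(k−1)λ²)` at the published alphas (0.67–0.97), so the generator
reproduces the reported reliabilities to ≈0.03; ages normal with mean 45.6
and SD 14.7, floored at 18; and 2% MCAR cell missingness — the survey's
missingness rate is not published, and 2% is typical of online batteries
while still exercising imputation and the per-measure exclusion rule
(a single missing item on the 4-item body-vigilance scale already exceeds
the 20% threshold).

Equiprobable thresholds keep category frequencies balanced and make alpha
analytically approximable; only MCAR is modelled (no MAR/MNAR, no
differential item functioning). The generator is test scaffolding: nothing
about it is a claim about the study population, so recovery results say the
*pipeline* works, not that the original substantive findings are correct.

## Preprocessing

Exclusions are applied in a fixed priority order, one recorded reason per
row: below the age-inclusion floor (18); more than 20% of the items of any
single measure missing (strict inequality); age strictly above
mean + 2 SD of the age-eligible rows (with mean 45.6 and SD 14.7 this is
75, i.e. "76 or older" is removed). The applied cutoff is recorded in the
exclusion log; a recomputed 2-SD bound is not idempotent on its own output
(it keeps shaving the truncated tail), so re-filtering should pass the
recorded cutoff back.

Missing items are multiply imputed by chained equations with predictive
mean matching: each chain hot-deck-initializes, then cycles over incomplete
columns, regressing observed values on all other (currently completed)
columns by least squares and copying the observed value of one of the k = 5
nearest-prediction donors. Observed cells are never altered and imputed
values stay in the observed support. Defaults m = 5 chains, 10 cycles.
Imputation runs at item level, before scoring, because the reliability
coefficients are item-level quantities.

How m imputed datasets should feed a single network is not fixed by the
emulated protocol; the pipeline estimates one correlation matrix per
completed dataset and averages them for network estimation (m = 1 gives a
single stochastic imputation). Row-level stages that need actual data
matrices — bootstrap resampling and per-DAG coefficient fits — use the
first completed dataset. No Rubin's-rules parameter pooling is attempted.

Scale totals are gaussianized by the rank-based inverse-normal transform:
average ranks for ties, `Φ⁻¹((r−0.5)/n)`, then exact centering/scaling to
mean 0, SD 1. The transform is invariant to monotone transforms of the
input; the 0.5 offset and average-rank tie rule are one standard dialect
(the original tool's exact variant is undocumented).

## Stage one: GGM by EBIC model selection

On the pooled correlation matrix S (data are unit-variance after
gaussianization, so correlation = covariance), candidate sparsity patterns
are proposed along a graphical-lasso path of 100 log-spaced penalties from
max|S_offdiag| down to 1% of it. Each distinct pattern is re-fitted
*without* penalty by constrained maximum likelihood — cyclic
modified-regression updates to tolerance 1e−8, so the implied covariance
reproduces S exactly on edges and the diagonal while the concentration
matrix is exactly zero off-structure — and scored by the extended BIC,
`−2ℓ + E log n + 4γE log p`, γ = 0.5 (the field's customary default; the
original setting is unreported). From the best candidate, a best-first
stepwise search evaluates every single-edge addition/removal per step and
accepts the best strictly improving move; the EBIC trajectory is therefore
strictly decreasing and the whole procedure is deterministic given S.
Edge weights are partial correlations `−K_ij/√(K_ii K_jj)`.

Both hot loops (glasso pattern search, constrained refit) are numba
kernels; a full selection at p = 12, n = 6000 takes ~0.15 s, which is what
makes bootstrapping the entire selection procedure practical.

Centrality: strength = Σ|w|; distances 1/|w| on edges; closeness =
1/Σ(shortest-path distances), computed within components (0 for isolated
nodes) and flagged when the graph is disconnected; betweenness counts
shortest-path memberships with ties split equally.

## Bootstrap accuracy and stability

The nonparametric bootstrap resamples rows with replacement and re-runs the
full model selection with identical settings; absent edges enter the draw
matrix as exact zeros, so per-edge 95% quantile intervals and inclusion
frequencies come from one rectangular matrix. Resampling indices depend
only on (seed, B, n), independent of the estimator. Two edges differ
"significantly" when the 95% quantile interval of their bootstrap weight
difference excludes zero. The case-dropping bootstrap recomputes
centralities on subsamples at drop fractions 0.05–0.75 and reports the
CS coefficient: the largest drop fraction at which the Spearman correlation
with the full-sample centrality is ≥0.7 in ≥95% of replicates. Defaults:
B = 5000 in the full profile, a few hundred in the fast profiles.

Measured calibration under the synthetic generator (p = 8, n = 1000,
B = 200): pooled CI coverage of true partial correlations is within a few
points of nominal, and equal-weight edge pairs are falsely flagged in ~7%
of simulations — the quantile bootstrap under model selection is slightly
anticonservative, a known property of this battery.

## Stage two: Bayesian DAG averaging

Structures are scored by the BGe marginal likelihood (normal–Wishart
conjugate prior) with α_µ = 1, α_w = p + 2, prior scatter
T = t·I, t = α_µ(α_w−p−1)/(α_µ+1), and ν at the sample mean — weakly
informative defaults making the score equivalent across Markov-equivalent
DAGs (verified to 1e−8 over covered-edge reversals). Local scores are
memoized by (node, parent-set) bitmask. The structure prior is uniform
over DAGs; an optional per-edge log-penalty keeps the prior modular, so
every sampler and oracle below remains exact under it.

Two samplers target this posterior:

* **edge_mh** — Metropolis–Hastings over single-edge add/delete/reverse
  with acyclicity rejection and the exact Hastings ratio of the
  pair-then-action proposal.
* **partition** — moves on ordered node partitions (the canonical layering
  of a DAG, which partitions DAG space), with per-node parent-set sums
  precomputed by subset-zeta tables; node-relocation and node-swap moves
  are exactly symmetric; DAGs are drawn from the exact conditional at each
  retained iteration. Because single-node partition moves cross between
  Markov-equivalent orientation modes slowly at large n, the sampler
  interleaves (2% of iterations) an invariance-preserving excursion: draw
  a DAG from the partition conditional, take 2p single-edge MH steps
  (including score-neutral covered-edge reversals), and re-project to the
  canonical layering. Each component preserves the target, so the
  composite kernel is exact; with it, two independent p = 12 chains agree
  on all edge frequencies to ~0.02.

Defaults: burn-in 20% of iterations, thinning set to retain 2000 DAGs
(50,000 in the full profile, which mirrors the emulated analysis' 10M
iterations). Every retained structure passes a topological-sort assertion.
Convergence is reported as the max-abs difference in per-edge inclusion
frequencies between two chains with different seeds (flagged above 0.05).

Two exact oracles validate the samplers. Under the uniform DAG prior, the
sink-layer inclusion–exclusion recursion
`H(S) = Σ_{∅≠T⊆S} (−1)^{|T|+1} H(S\T) Π_{j∈T} A_j(S\T)` sums every DAG's
weight exactly once (~3ᵖ work, practical to p ≈ 10); the alternating signs
preclude log-space evaluation, and concentrated posteriors underflow
doubles, so it runs in extended precision (mpmath) over log-space
parent-set tables. A Koivisto-style forward–backward dynamic program over
node subsets (2ᵖ, to p = 14) computes the posterior under an
order-modular prior (uniform over topological orders, which weights DAGs
by their linear-extension counts). The samplers match the *uniform*-prior
oracle — that is the distribution partition MCMC actually targets; pairing
it with the order-modular DP would compare two different posteriors. Both
oracles are themselves validated against brute-force enumeration at p = 4.

## Causal-effect summaries

Each sampled DAG is turned into a weighted linear SEM by OLS of every node
on its parents, on unit-variance (gaussianized) data, so coefficients are
standardized ("z-score") effects; rank-deficient parent sets fall back to
the minimum-norm solution with a warning. Coefficients are refit per
sampled structure rather than drawn from a parameter posterior — the
simplest estimator consistent with the reported pipeline. The total effect
of x on y is the (x, y) entry of `(I−W)⁻¹ − I`, equal to the sum over
directed paths of coefficient products (verified against exhaustive path
enumeration to 1e−10).

Per source–target pair the posterior summary reports: the percentage of
all sampled DAGs containing a directed pathway; the mean total effect and
equal-tailed 5th–95th percentile interval *over pathway-present DAGs only*;
the percentage of pathway-present DAGs containing the direct edge; and the
mean direct-edge coefficient (with its own 90% interval) over DAGs
containing that edge. Credible intervals reflect variation across sampled
DAGs only, not across imputations. Mediator shares count, among
pathway-present DAGs, those in which the source reaches the mediator and
the mediator reaches the target (in a DAG this is equivalent to a directed
path through the mediator). The mixed graph keeps an edge if it appears in
strictly more than 50% of all sampled DAGs (both orientations pooled) and
arrows it only if one orientation accounts for strictly more than 90% of
its appearances.

## Pipeline, profiles and reproducibility

A YAML config drives simulate → preprocess → ggm (+ bootstrap) → dag →
effects → report. Every stage's RNG seed is a stable hash of
(master seed, stage name), so skipping or re-running stages never shifts
another stage's stream; re-running a config byte-identically reproduces
all numeric artifacts. Two presets exist: `full` mirrors the emulated
analysis' scale (B = 5000, 10M iterations, 50,000 DAGs, n = 6161) and
`test` is a minutes-scale configuration (6 constructs, n = 1200, B = 150,
150k iterations) used by the demo, the test suite and the acceptance
script. The numbered `analysis/` drivers use an intermediate configuration
(all 12 constructs, n = 6161, B = 500, 400k iterations, 5000 retained
DAGs) that completes in a few minutes on one CPU.

Validation problem sizes were likewise chosen to keep a complete run in
the minutes range: GGM recovery at p = 12, n = 6000 over 10 seeds;
sampler-vs-oracle at p ∈ {4,5,6}, n = 300, 200k iterations with 20,000
retained DAGs (retaining fewer leaves pure Monte-Carlo noise of the same
order as the 0.05 agreement band); effect recovery at p = 6, n = 5000;
bootstrap calibration over 60 simulations of p = 8, n = 1000 with B = 200.

## Known limitations

* Ordinal data are treated via scale totals and rank-gaussianization, not
  polychoric/ordinal likelihoods.
* The BGe hyperparameters, burn-in, thinning and structure prior of the
  original analysis are unreported; all are configurable and recorded in
  output metadata rather than asserted as the original settings.
* Orientation frequencies of covered (Markov-equivalent) edges are the
  slowest-mixing functionals of the partition sampler; the hybrid kernel
  addresses this, and the two-chain diagnostic will flag residual
  disagreement.
* Bootstrap difference tests are mildly anticonservative under model
  selection (measured ~7% size at nominal 5%).
* The synthetic generator's one-factor items, MCAR missingness and
  linear-Gaussian construct model are idealizations; passing recovery
  tests demonstrates the estimators work under their own assumptions, not
  that real questionnaire data satisfy them.
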