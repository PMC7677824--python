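# Methods

## Problem setting

Input is a partially observed bipartite association network: a 0/1
indicator matrix `A` over n_m miRNAs and n_d diseases whose 1-entries are
curated associations and whose 0-entries are *unknown*, not negative,
plus one or two similarity matrices per entity type with values in
[0, 1]. Multiple similarity sources per side are integrated by their
elementwise arithmetic mean (sources missing a pair contribute 0 for that
pair — "no evidence of similarity"). The goal is a complete score matrix
whose within-column ranking prioritizes candidate miRNAs per disease.

## Model and objective

The completed matrix is the orthogonal tri-factorization `Ã = P D Qᵀ`
(`PᵀP = I`, `QᵀQ = I`, `D` of size r_m x r_d), found by minimizing

    ‖R_Ω(A − P D Qᵀ)‖²_F + λ₁ tr(Pᵀ L_m P) + λ₂ tr(Qᵀ L_d Q) + λ₃ ‖D‖_*

over the two Stiefel manifolds. The Laplacians are unnormalized,
`L = diag(S·1) − S`, so `tr(FᵀLF) = ½ Σ_ij S_ij ‖F_i − F_j‖²` penalizes
feature differences between similar entities; this is the only channel
through which an entity with no observed associations acquires a
meaningful score, so it is what makes the new-disease and held-out-miRNA
protocols work at all. The nuclear norm is the convex surrogate for
rank of the core.

**The observed set Ω.** The curated 1-entries are positive-only, and the
model's notation suggests restricting the data-fit term to them. Doing so
makes completion degenerate: the core can interpolate the observed 1s
(at a modest nuclear-norm cost) while the unconstrained remainder of the
matrix carries no ranking signal — row-held-out CV then scores at chance.
All evaluation protocols in the field operate by *zeroing* entries of `A`
and re-applying the model, which implicitly treats zeros as (weak)
negatives. `fit` therefore defaults to Ω = every entry of the training
matrix; the positive-only reading remains available
(`fit(..., observed="positives")`) and the projection operator
`masked_project` is fully general. On the default synthetic benchmark the
two readings give pooled CV AUCs of 0.86 and 0.52 respectively — the
figure the test suite reproduces qualitatively.

## Optimization

One outer sweep updates `D`, then `P`, then `Q`, each by an accelerated
proximal gradient (APG) scheme with momentum
`Y_k = X_k + γ_k(γ_{k−1}^{−1} − 1)(X_k − X_{k−1})`,
`γ_{k+1} = (√(γ_k⁴ + 4γ_k²) − γ_k²)/2`, started at `γ₀ = 1` with the
first momentum term vanishing.

* **Core update.** The prox of `(λ₃/s)‖·‖_*` is singular-value
  soft-thresholding, computed by a full SVD of the r_m x r_d argument
  (problem sizes are at most a few hundred per side, so the closed form
  is cheaper and exactly testable against its optimality conditions).
* **Factor updates.** The smooth masked loss supplies the gradient step;
  the resulting proximity sub-problem
  `min λ tr(FᵀLF) + (s/2)‖F − B‖²  s.t. FᵀF = I`
  is solved by a Cayley-transform curvilinear search: with Euclidean
  gradient `G` and skew matrix `W = GFᵀ − FGᵀ`, the curve
  `F(τ) = (I + τ/2 W)⁻¹(I − τ/2 W)F` stays on the manifold for every τ.
  `W` has rank at most 2r, so the update is evaluated through the
  Sherman–Morrison–Woodbury identity as a 2r x 2r solve. Steps start from
  a Barzilai–Borwein estimate and are halved under an Armijo test; the
  directional derivative along the curve at τ = 0 is `−½‖W‖²_F`. Numerical
  drift off the manifold is monitored at every accepted iterate (it stays
  below 1e−8; a QR re-orthonormalization triggers above 1e−10).
* **Proximal parameter.** `s = "auto"` uses the exact Lipschitz bounds of
  the smooth gradients — 2 for the core (P, Q orthonormal and the mask a
  contraction), `2σ_max(D)²` for the factors — and doubles `s` whenever
  the quadratic upper model is violated, which guarantees descent also
  for user-supplied values.
* **Monotonicity.** Momentum methods are not per-step monotone, so every
  block solver returns its best-sub-objective iterate; the outer objective
  trace is then non-increasing by construction, and `fit` raises if a
  sweep ever increases it beyond 1e−9 (a genuine implementation fault).

**Initialization** is the SVD warm start: `P`/`Q` from the leading
singular vectors of the zero-filled `A` (column signs fixed by making the
largest-magnitude entry positive, for platform determinism), `D = PᵀAQ`.
Rank requests beyond the numerical rank are padded with a seeded random
orthonormal completion. A Laplacian-eigenvector start was also evaluated;
both converge to the same optimum on the benchmark, so the cheaper SVD
start is kept.

**Stopping.** Inner APG loops stop at relative-change 1e−5 or 100
iterations; the Cayley search at relative objective decrease or gradient
reduction below 1e−8 or 50 iterations; the outer alternation at relative
objective decrease below 1e−4 or 50 sweeps. On the default benchmark a
fit converges in 5–6 sweeps (~2 s).

## Defaults and their meaning

| parameter | default | meaning |
|---|---|---|
| λ₁, λ₂ | 10 | weight of miRNA / disease similarity smoothing |
| λ₃ | 1 | nuclear-norm (rank) penalty on the core |
| r_m, r_d | n/6, round half up | factor ranks (368 → 61, 383 → 64) |
| folds | 5 | CV folds over *miRNAs* |
| repeats | 50 | CV repeats (re-randomized fold assignment) |

## Evaluation protocols

* **Cross-validation** folds miRNAs, not pairs: every association in the
  test-fold rows is zeroed for training, and all test-row pairs are
  scored; positives are the held-out knowns, negatives all other
  test-row pairs; scores are pooled across folds within a repeat and one
  AUC computed per repeat (an internal assertion guarantees no test-row
  positive is visible at training time). AUC is the Mann–Whitney
  statistic with half credit for ties; the PR curve carries one point per
  distinct threshold; per-repeat AUC vectors are compared by the paired
  t-test (degenerate zero-variance differences are rejected, not given a
  p-value).
* **New-disease recovery** masks one disease column at a time, refits,
  and records the ranks (average-rank ties) of the masked true miRNAs;
  the top-*t* CDF is the fraction of records with rank ≤ t.
* **Ablation** replaces one input with a random matrix of the same type —
  symmetric uniform[0,1] with unit diagonal for similarities, an exactly
  density-matched uniform 0/1 matrix for associations — and re-runs CV
  unchanged.

## Synthetic benchmark

`generate_scenario` draws orthonormal latent factors P*, Q* (QR of seeded
Gaussians), a linearly decreasing positive spectrum scaled so the
noiseless score matrix `Z = P* D* Q*ᵀ` has unit entry variance (so
`noise_sd` reads as relative noise), adds Gaussian noise, and thresholds
the top quantile of `Z` — sized at 10·min(n_m, n_d) pairs, roughly ten
true associations per entity on the smaller side, mimicking curated-
database sparsity — into hidden positives. Each positive is revealed with
probability `density`; similarities are affine rescalings of the factor
Gram matrices P*P*ᵀ / Q*Q*ᵀ to [0, 1] (unit diagonal), blended with a
random similarity by weight `sim_noise`. Defaults: 120 x 100, rank 8,
density 0.6, noise 0.05, sim_noise 0.2, seed 7.

What this emulates: low-rank association structure, positive-only
observation, similarity networks consistent with the latent factors (the
regime the Laplacian regularizer assumes), and a dial (`sim_noise`) to
switch that consistency off as a negative control. What it does not:
MeSH-style hierarchical disease structure, sequence-derived similarity
statistics, hub/degree heterogeneity of curated databases, or database
identifier noise — so passing protocol tests demonstrates correctness of
the machinery and the intended qualitative behaviour (similarity helps;
miRNA similarity contributes most), not field performance on any real
database.

Problem sizes in the test suite and acceptance script (120 x 100 with 10
CV repeats; smaller instances for solver-contract checks) are chosen so a
full run completes in minutes on one CPU while every protocol still runs
end to end.

## Known limitations

* Zeros enter the loss unweighted, so class imbalance is handled only by
  the regularizers, not by a weighting scheme.
* The alternating scheme converges to a local optimum; the SVD warm start
  makes it deterministic but carries no global guarantee.
* The similarity average gives equal weight to each source; no learned
  weighting is attempted.
* Scores are not probabilities; only their within-column ranking is
  meaningful.
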