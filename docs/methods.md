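# Methods

## Model

Expression of gene *k* in sample *j* of batch *i* is modelled on the log
scale as a location–scale decomposition

    Y_ijk = (X β_x)_jk + (C β_c)_jk + α_k + γ_ik + δ_ik ε_ijk ,

where X encodes the desired biological design (culture condition, strain,
growth phase, …), C encodes known unwanted covariates, α is a per-gene
intercept, γ_ik and δ_ik are the additive and multiplicative batch effects,
and ε is standard Gaussian noise. Batch effects are constant across samples
within a batch. Correction estimates (γ, δ) per batch and gene, removes
them, and restores the modelled means.

The procedure has four stages:

1. **Location fit.** Per gene, minimize

       ||Y_k − X̃ b_k||² + λ₁‖b_pen‖₁ + λ₂‖b_pen‖₂²

   over the stacked design X̃ = [batch one-hots | X | C]. Only the covariate
   coefficients (β_x, β_c) are penalized; the batch block and intercept are
   not, because shrinking the batch coefficients would bias exactly the
   quantities the empirical-Bayes stage is built to shrink in a principled
   way. With λ₁ = λ₂ = 0 this is OLS and requires a full-rank design; any
   λ₂ > 0 makes the problem strictly convex on singular designs, which is
   the regime the method exists for. The per-gene intercept is recovered
   from the constraint Σᵢ (nᵢ/N) b_ik = 0 on the batch coefficients.

2. **Standardization.** Z = (Y − α̂ − Xβ̂_x − Cβ̂_c)/σ̂, with σ̂_k the SD of
   the *full*-model residuals (batch term included) pooled over all N
   samples with divisor N. Z then carries γ/σ̂ plus unit-scale noise.

3. **Parametric empirical Bayes.** Per batch, the per-gene means γ̂_ik of Z
   and the per-gene sample variances are pooled across genes into
   moment-matched priors — Normal(γ̄ᵢ, τᵢ²) for the additive effects,
   InverseGamma(λ̄ᵢ, θ̄ᵢ) for the variances (shape = (V̄²+2S)/S,
   scale = (V̄³+V̄S)/S from the across-gene mean V̄ and variance S of the
   sample variances). Posterior estimates are the fixed point of

       γ*  = (nᵢ τ² γ̂ + δ²* γ̄) / (nᵢ τ² + δ²*)
       δ²* = (θ̄ + ½ Σ_j (Z − γ*)²) / (nᵢ/2 + λ̄ − 1) ,

   initialized at the naive estimates and iterated to a max-absolute-change
   tolerance of 1e-6 (max 1000 iterations; non-convergence is flagged, the
   last iterate returned with a warning).

4. **Adjustment.** Ỹ = (σ̂/δ*)(Z − γ*) + α̂ + Xβ̂_x + Cβ̂_c. The biological
   design is restored. By default C β̂_c is restored as well — correction
   removes batch effects only; `drop_unwanted=True` (CLI `--drop-unwanted`)
   omits it for users who want known nuisance covariates regressed out.
   Whether to restore C is genuinely open (the model separates unwanted
   covariates from batch terms but a user may want both gone); restoring is
   the default because it is the behavior that changes nothing except batch
   terms.

## Design encoding and singularity

Categorical covariates and the batch labels are expanded to *full* one-hot
blocks — no reference level is dropped, and levels are ordered
lexicographically for reproducibility. Every full block's rows sum to one,
so a full batch block plus any full categorical covariate block is already
rank-deficient; singularity is the normal case, handled by regularization
rather than by encoding tricks. Numeric covariates are z-scored so the
penalties act on comparable scales. Numerical rank is measured by SVD with
the standard tolerance max(n, m)·eps relative to the largest singular
value, and the smallest right singular vector is reported as a witness of
the dependency.

Consequence worth knowing: an OLS (λ = 0) fit is only possible when
categorical covariates are declared numeric (binary 0/1 columns) or absent;
the tests exercising the OLS path do exactly that.

## Solvers and numerical choices

* **λ₁ = 0** — generalized ridge in closed form: one symmetric solve of
  (X̃ᵀX̃ + λ₂ D) B = X̃ᵀY shared by all genes, D diagonal with ones on
  penalized columns. For duplicated columns the strictly convex objective
  is symmetric under swapping them, so they receive equal coefficients (to
  solver precision, which degrades as λ₂ → 0 since the condition number is
  ~1/λ₂).
* **λ₁ > 0** — the unpenalized batch block is profiled out exactly
  (Frisch–Waugh: one-hot blocks make the projection per-batch
  mean-centering), then cyclic coordinate descent runs on the projected,
  all-penalized subproblem, vectorized across genes; batch coefficients are
  recovered afterwards as per-batch means of the partial residuals. Each
  coordinate update is an exact univariate minimizer, so the objective is
  non-increasing.
* **Stopping rule.** Convergence is declared when either the largest raw
  coefficient update falls below `tol` (default 1e-7), or the largest
  deviance-scale impact of an update, maxⱼ ‖xⱼ‖²(Δbⱼ)², falls below
  `tol · mean_k ‖y_k‖²` — the criterion glmnet uses. The second test is
  essential on singular designs: directions in the design null space have
  curvature equal to λ₂ only, so raw coefficient changes decay at rate
  ≈ (1 − λ₂/‖xⱼ‖²) and would never cross an absolute threshold at feasible
  iteration counts, while the fit itself (and its deviance) has long
  converged. Exceeding `max_iter` (default 10 000) raises an error that
  reports the last objective change and suggests stronger regularization.
* Default regularization is λ₁ = 0, λ₂ = 1e-9: a vanishing ridge that
  leaves well-conditioned fits numerically unchanged (relative coefficient
  difference to OLS < 1e-4, tested) while making every singular design
  solvable.
* Genes whose pooled residual SD falls below 1e-12 are excluded from
  standardization and empirical Bayes and passed through the adjustment
  unchanged, with a warning listing them.
* Batches of size 1 are a hard error (their sample variance is undefined).
  Batches whose per-gene variances have zero spread across genes get a
  degenerate-prior flag and keep their naive estimates unshrunk.

## Synthetic data

The simulator draws directly from the forward model above, with the same
distributional families the parametric empirical-Bayes stage assumes, so
parameter recovery is well-posed:

* the biological design is a set of binary categorical features; each of
  the `n_zero_hops` distinct feature rows defines a Zero-Hop (samples
  sharing the exact experimental design), assigned to samples in a balanced
  way;
* batches are assigned at random with at least two samples each (so
  variance estimates exist downstream);
* β_x entries ~ Normal(0, s²) with s = disturbance_ratio ×
  additive_batch_sd, implementing the relative disturbance size of the
  biology to the batch effects; α_k ~ Normal(0, 1);
* additive effects: γ̄ᵢ ~ Normal(0, sd²) per batch and γ_ik ~ Normal(γ̄ᵢ,
  sd²) per gene, with sd = `additive_batch_sd` serving as both the
  between-batch and the within-batch (across-gene) scale — one knob, two
  levels of the same hierarchy;
* multiplicative effects: δ²_ik ~ InverseGamma(shape, scale); setting
  `multiplicative_scale = 0` pins δ² ≡ 1 exactly, and
  `additive_batch_sd = 0` switches additive effects off exactly, so the
  no-batch-effect condition is reachable without sampling artifacts;
* the ground-truth matrix keeps the noise term (X β_x + α + ε): perfect
  correction means agreeing with the noisy batch-free data, not impossible
  denoising;
* `singular_design=True` duplicates one feature under a second name so the
  encoded design gains an extra exact dependency.

Defaults (500 samples, 10 batches, 10 Zero-Hops, 5 features, 200 genes,
additive SD 2 against unit noise) are a moderately hard integration
problem: batch labels are perfectly classifiable before correction and the
biology is strong enough to be fully retained after it. What the simulator
does *not* emulate: count-level noise (everything is Gaussian on the log
scale), gene–gene correlation, batch effects that interact with biology,
and missing metadata. Passing tests therefore demonstrate correctness of
the algorithm under its own model assumptions, not robustness to real-data
violations of them.

## Evaluation metrics

All metrics operate on Euclidean distances in the full expression space (no
PCA pre-reduction) and report their settings alongside their values.

* **Classifier scores** — stratified 10-fold cross-validated balanced
  accuracy (logistic regression with fixed L2 strength 1.0, or LDA), plus
  macro-F1 for the logistic classifier. Batch as target: lower is better
  correction; Zero-Hop as target: higher is better biology retention.
  Singleton classes are dropped; classes smaller than the fold count are
  merged into an `other` stratum; the fold count is capped at the smallest
  class size.
* **kNN entropy** — per-sample Shannon entropy (base 2) of the label
  distribution among the k = 15 nearest neighbors (self excluded),
  normalized by log₂(#classes). Distance ties straddling the k-th neighbor
  receive fractional weight, which makes the score independent of sample
  ordering.
* **Cluster purity / Gini impurity** — size-weighted over k-means clusters
  (10 restarts, seeded).
* **Minimum separation number** — the smallest k at which k-means isolates
  two sample groups into disjoint cluster sets; small k means strong
  separation.
* **Distance ratio score** — within each Zero-Hop spanning several
  batches, mean between-batch over mean within-batch pairwise distance;
  ≈ 1 means mixed. Zero within-batch distances are flagged degenerate
  rather than divided by.
* **Baseline correctors** for comparison: global per-gene z-scoring;
  marker-gene elimination (drop the q genes with the largest one-way
  batch-ANOVA F); PC elimination (remove the p principal components whose
  scores have the highest R² against batch membership). These are standard
  operational forms chosen for the package; simple, deliberately weak
  comparators.

A caution observed in the package's own benchmark output: after correction
the *cross-validated* batch accuracy routinely falls below chance (even to
zero). The correction removes batch means estimated on all samples, so a
batch's training-fold residual mean and its test-fold residual mean are
slightly anti-correlated, and the classifier anti-predicts. "At or below
chance" is the correct reading of that score, not "exactly chance".

## Known limitations

* Mean absolute change introduced on data with *no* batch effects is about
  0.06 under the default conditions (10 batches of 50 samples, unit
  noise): spurious per-batch means of pure noise have sd 1/√50 ≈ 0.14 and
  empirical-Bayes shrinkage (correctly estimating τ² ≈ 1/nᵢ) halves rather
  than eliminates them, and the variance posterior rescales by a few
  percent. This floor shrinks with larger batches; it is a property of the
  location–scale EB approach itself (the Bioconductor reference
  implementation measures the same value on identical data).
* Non-parametric empirical Bayes, reference-batch mode and mean-only
  adjustment are not provided.
* The elastic-net decomposition of signal between batch block and
  covariates is not identifiable on singular designs; the penalty selects
  the minimum-norm representative, so coefficient values (unlike fitted
  means) should be interpreted with care when the design is singular.
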