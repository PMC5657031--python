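# Methods

This note documents the models, protocols, defaults and numerical choices in
`consortium-lite`, and what the synthetic experiments do and do not
demonstrate.

## The consortium model

A *consortium* is an ordered set of sites, each holding a private table
(observations × features, optional response), plus one master that holds no
subject-level data. Computation proceeds in synchronous rounds: the master
broadcasts shared state, every site computes on its local data in ascending
`site_id` order, the master aggregates the uploads and tests a stopping rule.
Every round is recorded in a `RoundTranscript`; `audit_transcript` flags any
upload that equals a contiguous row-slice of a site's raw data (in either
orientation) or that has the raw table's exact shape. The transcript is the
package's privacy argument: not a cryptographic guarantee, but a structural
proof that only aggregates crossed the wire. Differential-privacy noise,
real networking, asynchrony and stragglers are out of scope.

Reproducibility contract: aggregation is pairwise summation in ascending
`site_id` order; each site's RNG stream is seeded `master_seed + site index`,
so a fixed seed gives bit-identical transcripts across runs, and appending a
site does not perturb existing sites' draws. Permuting site identifiers
changes the transcript but moves final states only at the level of
floating-point summation order (≲1e-9 relative).

## Multi-shot ridge regression

Model: `y = Xβ + ε` with an unpenalized intercept; ridge penalty `λ‖β̃‖²`
(λ = 0 is ordinary least squares). Sites upload the gradient of their local
residual sum of squares, `−2 X_pᵀ(y_p − X_p w)`, and their local objective;
the master **sums** gradients (summing rather than averaging makes the
decentralized gradient exactly the pooled one regardless of unequal site
sizes), adds `2λw̃` once, normalizes by the global N, and steps.

Numerical choices:

* **Internal standardization.** Covariates *and* response are z-scored using
  decentralized global moments, computed in two passes (means first, then
  squared deviations about the broadcast means — the one-pass
  `E[x²]−E[x]²` form loses about four digits on ROI volumes near 5·10⁴).
  Coefficients are de-standardized for reporting. On the standardized scale
  the Hessian is O(1), so the default step size 0.25 contracts the error
  geometrically; an unstandardized fit of raw volumes would need absurdly
  small steps.
* **Backtracking.** If the global objective rises, the step is halved and
  retried from the last accepted iterate, so the accepted objective history
  is non-increasing. A step is "accepted" when the objective is at most the
  previous value times (1 + 1e-12): the relative slack keeps the
  accept/reject branch identical across site splits, whose summation orders
  differ at machine precision — without it, split-invariance of the iterate
  sequence breaks down near convergence.
* **Stopping.** Gradient norm below `tolerance` (default 1e-6) or
  `max_iterations` (default 25, the platform UI default; convergence-grade
  runs in the tests and acceptance script use 300 with tolerance 1e-10).

Single-shot mode solves the closed-form ridge locally at each site and
returns the N_p-weighted average — a meta-analysis. On homogeneous splits it
is close to the pooled solution; on heterogeneous splits it differs, which is
exactly the gap the multi-shot mode closes. Weighting by N_p (rather than
inverse variance) was an open choice and is flagged as such.

## Decentralized inference (R², t, p)

R² takes exactly two rounds: (Ȳ_p, N_p) up, global Ȳ down, then (SST_p about
the global mean, SSE_p) up; `R² = 1 − ΣSSE_p/ΣSST_p`. t-values take one
round: sites upload the *uncentered* Gram matrix `X_pᵀX_p` including the
intercept column — only Gram aggregation reconstructs the pooled `(XᵀX)⁻¹`
exactly; a centered covariance could not recover the intercept's standard
error. Degrees of freedom are `N − k` with k counting the intercept.
p-values are two-tailed Student-t tails via scipy. For λ > 0 the same OLS
formulas are applied to the ridge coefficients and the report marks them
approximate; no ridge-specific inference is attempted. The report table
lists the global block first, then one locally-refit block per site (a site
with `N_p ≤ k` gets an "insufficient data" marker); whether per-site blocks
should instead apply the global β locally was ambiguous, and the local-refit
reading was chosen (the global-β-applied-locally numbers are recoverable via
`decentralized_r_squared`'s per-site values).

## Decentralized t-SNE

Each site holds private points X_p; a public reference X_s is known to all.
A site computes one affinity matrix over its union X_p ∪ X_s (per-point
bandwidths bisected to match `log₂ perplexity` bits of conditional entropy,
then symmetrized), so the reference points' affinities legitimately differ
between sites — that is the channel through which private structure
influences the shared frame. Per round, a site takes one Student-t-kernel
gradient step on its union embedding, applies the private part to Y_p
locally, and uploads only the reference part; the master averages these with
equal weight (one vote per site) and updates Y_s. Y_s is therefore identical
at every site after each broadcast.

Optimizer defaults are the classic schedule: early exaggeration ×4 for 100
iterations, momentum 0.5 switching to 0.8 at iteration 250, learning rate
100, adaptive per-coordinate gains, 1000 iterations, Gaussian(0, 1e-4)
initialization. The centralized baseline shares the kernels and update rule,
so a consortium of one site with no private points reproduces it bit for
bit. Private embeddings stay at their sites until the final output step.

## Decentralized MLP

A multilayer perceptron (logistic hidden units by default, ReLU optional;
softmax + cross-entropy output) trained by mini-batch SGD in which one batch
is one sample per site. Gradients are **averaged** over sites (matching the
one sample each contributed — contrast with regression's sum over all
subjects), the average is broadcast, and every site applies the same update
to its replica, which therefore stay bit-identical. An epoch is one pass of
the largest site; smaller sites recycle through reshuffled orders from their
own seed streams. Under a matched assembly of batches, the trajectory equals
centralized mini-batch SGD to machine precision.

## Decentralized joint ICA

Infomax with a single global unmixing pair (W, b): sources `Z_p = W X̃_p + b`,
sigmoid transform Y_p, natural-gradient pieces
`G_p = (N_p I + (1−2Y_p)Z_pᵀ)W`, `h_p = Σ(1−2Y_p)` summed at the master and
normalized by the global sample count — the implicit temporal concatenation
of all sites' data. The step size ρ (default 0.1, chosen for robustness
across mixing draws; annealing halves it with rollback whenever the
aggregated entropy objective `log|det W| + mean log y'(z)` decreases) keeps
the accepted objective non-decreasing. Whitening is decentralized-global by
default (sites upload second moments; the master broadcasts one pooled
whitening transform), which is what makes the trajectory exactly
split-invariant; site-local whitening is available as the degraded variant.
Dimension reduction uses the same aggregated-moment eigendecomposition.
Separation quality is scored by the Moreau–Amari index of `W_eff·A`,
normalized to [0, 1], zero iff a scaled permutation. The index is invariant
to source permutations; row rescaling preserves its zero but not its general
value.

## Decentralized IVA

IVA with a multivariate-Laplace source prior over K datasets, each with its
own unmixing W_k, datasets distributed over sites. Cost:

    J = Σ_n (1/T) Σ_t sqrt(Σ_k s_n^[k](t)²) − Σ_k log|det W_k|

The coupling term depends only on the matrix of norms
`C[n,t] = Σ_k s_n^[k](t)²`, which is additive over sites: sites upload
`C_p` and their determinant contribution `d_p`; the master forms C and the
global cost and broadcasts C; sites apply the score
`φ_n(t) = s_n(t)/sqrt(C[n,t])` (floored at 1e-8 against division blow-ups)
in the relative gradient `G_k = (I − (1/T)φ sᵀ)W_k` and upload only squared
gradient norms, from which the master maintains one global step size α
(start 0.1; kept while the cost decreases, halved with rollback on an
increase, abort after 20 consecutive halvings). Sites keep their previous
accepted (W_k, G_k) locally so a rollback needs no recomputation. Datasets
are whitened locally; W_k starts at identity in the whitened basis and
`effective_unmixing` folds the whitening back in. Because every exchanged
quantity is a global sum or a maximum, dataset placement across sites
changes the communication pattern but not one bit of the trajectory (sums
are grouped pairwise so contiguous power-of-two placements agree exactly).
Joint ISI — the Amari confusion of the averaged `|W_k A_k|` — is zero iff
all datasets share one scaled permutation, so it penalizes per-dataset
permutation inconsistency.

## Synthetic data: what it emulates, what it does not

* `simulate_freesurfer_volumes` — an aseg-style table (subject_id, age,
  isControl, one ROI volume) built around a fixed intercept of 48466.3 mm³
  with per-subject age effects U[−300, −100] mm³/yr, group effects
  U[500, 1000] mm³ and noise scales U[1800, 2200] mm³ on standard normal
  draws. "Per subject" is taken literally (each subject gets its own effect
  draws; the population regression then targets the interval midpoints);
  a once-per-run variant is exposed because the alternative reading is
  defensible. Age is uniform on [18, 65] and isControl balanced 50/50 —
  values a cohort simulation would call unremarkable; neither is critical to
  any tested property.
* `simulate_gaussian_clusters` — isotropic unit-variance blobs with centers
  at pairwise distance ≥ separation; labels returned for ARI scoring.
* `simulate_ica_mixtures` — a well-conditioned (condition < 20) global
  mixing matrix applied to unit-variance Laplace sources or to a
  GARCH(1,1)-style variance recursion `h_t = ω + 0.1 x²_{t−1} + 0.8 h_{t−1}`
  with ω set for unit unconditional variance (excess kurtosis ≈ 0.35). The
  pooled source matrix is drawn from one stream and sliced contiguously per
  site, so site count does not change the pooled data.
* `simulate_iva_scv_datasets` — the n-th source across K datasets shares a
  common Gaussian factor (loading √ρ) and a common variance driver, giving
  cross-dataset correlation ≈ ρ within a source component vector and
  independence across vectors.
* `simulate_labeled_features` — Gaussian class-conditional features with
  identical class distributions at every site.

None of these reproduce real fMRI spatiotemporal structure, scanner/batch
effects, site-level covariate shift, or missing data. Passing tests
therefore establish the *algorithmic* claims — pooled equivalence, split
invariance, privacy of the transcript, correct inference formulas, metric
trends with sample size — not clinical-scale performance on real multi-site
cohorts.

## Pipelines

A computation schema declares typed inputs/outputs (types: number, boolean,
string, matrix_csv, column_selector); validation returns violations with
JSON-path locations. Pipelines are linear; wiring is type-checked end to end
before anything executes. Local steps transform each site's table in place
(e.g. site-local z-scoring); decentralized steps run through the same round
runner as the direct API, so pipeline composition equals manual composition
exactly. Step outputs are cached by content hash of (computation, bindings,
controller settings, input digest). Docker-style containerization is
replaced by an in-process registry keyed by schema name@version; the schema
format would survive a move to containers. The model-combination expansion
enumerates, per dependent variable, every nonempty subset of independent
variables (singletons first), `n_dep · (2^n_indep − 1)` models in total.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the measured
properties statistically unambiguous: regression at 400–1000 subjects;
dSNE at 10 clusters × 24–30 points in 50 dimensions with ~40–50 reference
points and 400–1000 iterations; ICA at 4 channels and 512–8192 total
samples (5 seeds per size for the median Amari trend); IVA at K = 4,
m = 3, T = 512–2048 (3 seeds per size). Larger sizes change runtimes, not
conclusions, for the properties asserted.

## Known limitations

* Exact pooled equivalence is a property of full-batch deterministic
  gradients plus global whitening/standardization; stochastic or site-local
  variants (provided for comparison) lose it by design.
* OLS-style t/p under λ > 0 are approximations, flagged in the report.
* The privacy audit is structural (shape and content matching), not a formal
  privacy accounting; small aggregates over tiny sites can still leak in
  principle (e.g. a one-row site's mean is the row) — the audit will catch
  that specific case, but no differential-privacy noise is added.
* Synchronous rounds only; a slow site stalls the consortium.
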