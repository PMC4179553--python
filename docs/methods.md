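# Methods

## Model

Expression data are modeled feature-by-sample as

    X = B·S + Γ·G + U

where `X` is m features × n samples, `S` (p₁ × n) is the known outcome
design (intercept plus K−1 reference-coded class indicators), `G` (p₂ × n)
is an unknown low-rank matrix whose rows parameterize residual dependence
across samples — batch and any other unmeasured confounders — `B` and `Γ`
are per-feature coefficient matrices, and `U` is independent noise. In a
training database the classes are known, so `S` is fixed and `B`, `Γ`, `G`
are estimated; in deployment, new samples arrive one at a time with both
class and batch unknown, which is the problem the frozen correction solves.

## Surrogate-variable estimation (training)

`irwsva_fit` alternates two steps for a fixed budget of iterations
(default `n_iter = 5`, no convergence test — bounded, deterministic
runtime):

1. **Empirical-Bayes feature weights** (`eb_probability_weights`). For each
   feature, an ordinary F-test of the surrogate rows (`[S; Ĝ]` vs `S`)
   yields a p-value for surrogate association, and an F-test of the
   non-intercept outcome rows (`[S; Ĝ]` vs `[intercept; Ĝ]`) yields one for
   outcome association. Each p-value vector is converted to a posterior
   association probability as 1 − localFDR, where the local FDR is
   π₀ / f(p): π₀ from the smoother method (natural estimates on the grid
   λ = 0, 0.05, …, 0.90, cubic least-squares fit extrapolated to λ → 1,
   clipped to (0, 1]), and f from a Gaussian KDE of logit-transformed
   p-values mapped back through the Jacobian 1/(p(1−p)). The local FDR is
   clipped to [0, 1] and made monotone non-decreasing in p by a running
   maximum. The SVD row weight is π_w = (1 − π_b)·π_γ — the probability a
   feature is confounder-driven but not outcome-driven.
2. **Weighted SVD** (`weighted_svd`). A thin SVD of diag(π_w)·X; the
   leading `n_sv` right singular vectors become the new surrogate estimate
   Ĝ. A deterministic sign convention (the dominant entry of each left
   singular vector is made positive, ties to the lowest index) makes
   repeated fits bit-identical.

Ĝ⁰ is initialized from the unweighted SVD of the residuals of X on S — the
weight step needs a starting surrogate, and the residual SVD is the natural
unweighted choice. After the final round, `B̂` and `Γ̂` come from per-feature
least squares on the stacked design `[S; Ĝ]`, and the training set is
cleaned as `X_clean = X − Γ̂·Ĝ`.

F-statistics are ordinary least-squares statistics without variance
moderation. Zero-variance features (undefined F-statistics) receive all-zero
weights and are excluded from the density estimation. A stacked design
whose smallest singular value falls below 1e−8 of its largest is rejected
as confounded — this triggers only on (near-)exact collinearity of Ĝ with
S, so fits at high-but-imperfect batch–outcome correlation still run, they
just help less, which is the scientifically expected behavior.

### Number of surrogate variables

`estimate_num_sv` implements a permutation (parallel-analysis) estimator:
residualize X on S, measure the proportion of variance carried by each
right singular vector, rebuild a null by independently permuting each
feature's residuals and re-residualizing (default `n_perm = 20`), and count
leading components whose observed share exceeds the 1−α null quantile
(default α = 0.05), stopping at the first non-significant component. The
stock simulations contain a single latent batch factor, so benchmark code
uses `n_sv = 1`; the CLI accepts `--n-sv auto` to delegate to the
estimator.

## Frozen correction of new samples

Exact mode (`fsva_exact_one`) appends the single new sample to the retained
training matrix, recomputes the weighted SVD of diag(π_w)·[X | x] with the
*frozen* training weights, and reads the sample's surrogate values off the
augmented right singular vectors. Samples are never appended jointly: a
joint decomposition would latch onto similarity among the new samples
instead of similarity to the database. Because the augmented singular
vectors carry an arbitrary sign and a slightly different scale than the
training ones, each augmented component is rescaled by the least-squares
scalar c_k = argmin‖c·Ĝ_aug[k, :n] − Ĝ[k]‖ fit on the n training columns
(`align_surrogates`) before the frozen `Γ̂` is applied; without this, a
sign flip would *add* batch signal rather than remove it.

Fast mode (`fsva_fast`) avoids any new decomposition. Since V is
orthonormal, Vᵀ = D⁻¹UᵀWX, so the operator P = D⁻¹·Uᵀ·W projects any
column onto the training right singular vectors; P·x estimates a new
sample's surrogate values in one matrix–vector product. Components with
singular value below 1e−10 of the largest are dropped before inverting D.
The corrected sample is x − Γ̂·ĝ in both modes. Fast mode is an
approximation — its projection is built from the training samples only —
and converges to exact mode as the database grows; columns are corrected
strictly independently (one BLAS gemv per sample), so a sample's corrected
values are bit-identical regardless of which other samples share the
matrix.

Feature spaces are aligned by feature ID with reordering; missing or extra
features are an error rather than being imputed, since imputation would
silently corrupt the frozen coefficients.

## Synthetic data

`simulate_dataset` draws X = B·outcomeᵀ + Γ·batchᵀ + U with balanced binary
outcome and batch labels. The database's batch–outcome phi correlation ρ is
set by the joint cell count a = round(n(1+ρ)/4), giving realized
correlation 4a/n − 1 (within 2/n of the target); new samples are always
generated with ρ = 0 so each batch×outcome combination fills a quarter of
them, mimicking samples accruing one at a time. The intercept is zero —
it is absorbed by the design's intercept row and affects no method.
Coefficients are Gaussian, gated by binary affectedness masks assigned via
a seeded permutation. The three stock scenarios (see `fsva.SCENARIOS`)
combine a subtle outcome (sd 1) with a strong batch effect (sd 3–4) over
noise sd 2–3, with 50–80% of features batch-affected. Scenario 3's printed
margins (80% batch, 80% outcome, 50% both) are jointly infeasible — their
union exceeds the feature count — so the generator honors the batch margin
and the overlap exactly and truncates the outcome-only block to the
remaining features (m = 1000 → 800 batch, 500 both, 700 outcome, 0 null),
deterministically.

What the generator does *not* emulate: feature–feature correlation beyond
the two latent factors, non-Gaussian noise or heavy-tailed effect sizes,
more than two batches, continuous outcomes, or platform artifacts like
intensity-dependent variance. Passing tests therefore demonstrate the
estimation and correction machinery under the stated generative model, not
robustness to every property of real microarray or sequencing data.

## Classifier and benchmark

`nsc_train` implements nearest shrunken centroids: class-centroid offsets
from the overall centroid are standardized by m_k·(s_i + s₀) with
m_k = √(1/n_k − 1/n), pooled within-class sd s_i, and the fudge constant
s₀ = median(s); offsets are soft-thresholded, and prediction minimizes the
standardized squared distance to the shrunken centroid minus 2·log prior,
with ties to the lexicographically first class. The threshold is chosen by
stratified 5-fold cross-validation over 30 evenly spaced values on
[0, max|d|), ties resolved to the largest threshold. The grid excludes the
fully-shrunk endpoint, which is a degenerate prior-only classifier.

`run_benchmark` evaluates, per simulated replicate, four arms on identical
data: `none` (model trained on the raw database, applied to raw new
samples), `sva_db_only` (model trained on the cleaned database, raw new
samples), and `fsva_exact` / `fsva_fast` (cleaned-database model applied to
frozen-corrected new samples). Replicates whose surrogate fit fails are
recorded with a failure flag rather than dropped. The whole benchmark is a
pure function of its seed: every replicate's generator and fold seeds
derive from one `SeedSequence`.

## Problem sizes and numerical choices

Tests and the acceptance script run the benchmark at m = 1000 features and
100 database + 100 new samples — the simulation's sample layout at a
feature count chosen to keep the full suite fast while leaving the
batch-to-noise structure (and hence every qualitative conclusion)
unchanged; the generator defaults remain m = 10000. Tolerances: weighted-SVD
reconstruction and the projection identity hold to 1e−8 relative error
(observed ~1e−14); p-values are clipped to [1e−15, 1−1e−15] before the
logit; singular-value inversion uses the 1e−10 relative cutoff. Model
serialization writes floats as %.17g, which round-trips IEEE doubles
exactly; reloaded models reproduce corrections bit-for-bit (the projection
operator is stored-layout-canonicalized because BLAS summation order
depends on array strides).

## Known limitations

* Near-perfect confounding (ρ → 1) is uncorrectable in principle; the fit
  either degrades gracefully or, at exact collinearity, raises a
  confounded-design error.
* The empirical-Bayes realization (smoother π₀, logit-KDE density) is a
  standard choice but not the only one; weights for weakly-loaded features
  are intermediate rather than crisp.
* Exact mode costs one m×(n+1) SVD per new sample; fast mode is O(m·r) per
  sample but inherits a one-sample-out approximation error that grows as
  the database shrinks.
* The residual (noise) matrix is not serialized; models reloaded from disk
  expose `noise=None`.
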