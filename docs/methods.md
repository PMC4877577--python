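# Methods

## Model

At each calibration location *i* among N areal units the outcome is modelled
by a spatially varying-coefficient logistic regression: y_j ∈ {0, 1},
logit μ_j = β_i0 + Σ_k x_jk β_ik.  With N locations and N(p+1) free
coefficients the model is unidentifiable without borrowing strength from
neighbours, so observations enter location *i*'s likelihood with Gaussian
distance-decay weights

    w_ij = exp(−½ (d_ij / θ)²),

the standard geographically-weighted-regression kernel.  d is Euclidean by
default; Manhattan, general Minkowski and great-circle (haversine, km)
distances are supported.  The ½ convention is the one used throughout the
GWR literature; the package exposes the variant without the ½ factor
(`half=False`), which is identical up to a √2 rescaling of θ, because both
conventions circulate and any bandwidth selected by cross-validation is
internally consistent with whichever form is used.

The local fit minimizes the weight-normalized penalized negative
log-likelihood

    f(β_i) = Σ_j w̃_ij ℓ(y_j, η_j) + λ [ α‖β_i‖₁ + (1−α)/2 ‖β_i‖₂² ],

with w̃ the kernel weights normalized to sum to one, ℓ(y, η) =
log(1+e^η) − yη, and the intercept unpenalized (standard lasso practice).
α = 1 (the default) is the lasso; α < 1 gives the elastic net.

**Why normalize by Σw:** the raw weighted sum's scale varies across
calibration points (a location in a dense cluster has far more effective
kernel mass than an isolated one), so a single λ on that scale penalizes
different locations by different effective amounts.  Dividing the loss by
Σw makes λ location-independent; a penalty on the raw-sum scale corresponds
to λ_raw = λ · Σ_j w_ij at each location.

## Inner solver

Cyclic coordinate descent on the IRLS quadratic approximation (the glmnet
algorithm), with:

- working-variance floor 1e-5 (affects only the step, not the fixed point,
  since the working residual times the working weight is exactly the score);
- convergence at max coefficient change < 1e-7 per full cycle, cap of 1e5
  coordinate updates; non-convergence sets a flag rather than raising;
- coefficients below 1e-10 in magnitude snapped to exact zero for sparsity
  accounting;
- warm starts along descending λ paths, so a whole path costs little more
  than one cold fit;
- λ_max(design) = max_k |Σ_j w̃_j x_jk (y_j − ȳ_w)|, the smallest penalty at
  which the KKT conditions admit the all-zero-slope solution.

**Degenerate local designs.** When every observation with positive weight
has the same outcome the local MLE is infinite.  The solver then returns an
intercept-only fit at logit((Σ w y + ½)/(Σ w + 1)) — a half-observation
pseudo-count shrink — flagged `degenerate=True`, so the CV and final-fit
loops always complete and callers can count or inspect the affected
locations.  During CV such locations contribute their null-model criterion;
they are never silently dropped.

## Hyperparameter selection

Stage one evaluates the LOO-CV criterion on an S × T grid: for each
bandwidth candidate the weight matrix is computed once, and for each unit
*i* the local model is fitted on the other N−1 observations with weights
W[i, −i] over the whole descending λ path (warm-started), then scored on
the held-out unit.  The default criterion is the summed held-out binomial
deviance −2[y log μ̂ + (1−y) log(1−μ̂)] with probabilities clipped to
[1e-10, 1−1e-10]; deviance is the standard CV loss for penalized logistic
models and is smooth in λ.  A misclassification count is available.  Cost
is exactly S·N path fits (instrumented in `CVGrid.n_path_fits`); the
distance matrix is computed once and shared.

Ties at the minimum break to the smallest θ, then the largest λ — the
simpler, sparser model.  `search_mode="golden"` replaces the θ scan by a
golden-section search between the smallest and largest candidates, under a
unimodality assumption on the CV profile; the exhaustive grid remains the
default because it is reproducible and the profile need not be unimodal.

The `auto_lambda_grid` helper builds a glmnet-style geometric path over T
points from an anchor to 1e-3 × anchor, the anchor being λ_max at the
location whose kernel row has the largest total mass under the widest
bandwidth considered.

Stage two refits all N locations at (θ̂, λ̂) with full weight rows.  In the
θ → ∞, λ = 0 limit every row of the resulting coefficient field equals the
global unpenalized logistic MLE (asserted against an independent Newton
oracle in the tests).

Covariates are z-scored once, globally, before any fitting; the LOO step
removes unit *i* from the weighting only, not from the standardization.
Re-standardizing per leave-one-out split would change every local design by
O(1/N) and make λ values non-comparable across splits.

## Coverage index

Given the fitted field, each unit's raw score is the odds-ratio-weighted
sum of the covariates its local lasso retained:

    raw_i = Σ_{m : β̂_im ≠ 0} exp(β̂_im) · x_im .

Covariates with zero coefficients contribute exactly zero (the
implementation masks them before exponentiating, so exp(0)=1 never leaks
in).  Raw scores are min-max normalized to [0, 1] by default — under this
choice the maximum index value equals k, consistent with published uses of
this construction; `normalization="none"` skips it.  Negative values (which
z-scored covariates can produce under `none`) are clipped to zero: the
index is interpreted as a nonnegative coverage measure.  Finally

    k = target_average · Σ h_i / Σ h_i · raw̃_i ,   ind_i = k · raw̃_i ,

so the household-weighted mean of the index equals the supplied population
average exactly; with no household counts, uniform weights are used and a
warning logged.  Doubling the target doubles k and every index value.

Validation is Spearman rank correlation against external series, average
ranks for ties, two-sided p-value from the t approximation, except N ≤ 9
where the exact N!-permutation distribution is enumerated.

## Co-clustering

The N × (p+1) coefficient matrix (intercept column included) is summarized
by a latent block model: row clusters of areas and column clusters of
coefficients, each block (g, h) emitting cells i.i.d. N(μ_gh, σ²_gh) with a
variance floor of 1e-6.  Fitting is classification EM — alternate hard
reassignment of rows, then columns, with exact M-steps — whose
complete-data log-likelihood is non-decreasing by construction; the trace
is kept for auditing.  Initialization is separate k-means on rows and
columns; 20 restarts by default (later restarts perturb 10% of the k-means
labels), best final likelihood wins; restarts that empty a cluster are
discarded.  Everything is deterministic given the seed.  A Bernoulli
emission option clusters the binary nonzero pattern instead of the values,
for when selection rather than magnitude is of interest.  G = 10 × 10 is
the conventional default for census-scale matrices; any G up to the matrix
dimensions may be requested.

## Synthetic data

`generate_dataset` emulates the target setting: units on a unit-spaced grid
(or uniform-random layout), covariates jointly Gaussian with equicorrelation
ρ then z-scored, a random subset of `n_active` covariates given coefficient
surfaces drawn exactly (Cholesky) from a Gaussian process with
squared-exponential covariance, scaled by `effect_scale`; outcomes
Bernoulli(logistic(η)).  Household counts are lognormal (median ≈ 3000),
a skewed size distribution typical of municipalities.
`generate_rates_dataset` adds Gaussian noise to the true probabilities,
clips to [0, 1], and median-binarizes, exercising the full preprocessing
path.

Default conditions used across the test suite: N=200, p=10, n_active=3,
grid layout, lengthscale 4 (≈ a third of the 15 × 14 grid extent — regional
rather than parcel-level variation), effect scale 2 (strong but plausible
log-odds amplitude per z-scored covariate), ρ=0.2, seed 20160524.  An
optional `prevalence` parameter solves for a constant logit offset so the
mean true probability hits a target.

**What this does not emulate:** the joint distribution of real census
covariates (91 heterogeneous, often heavily skewed variables), polygon
geometry and shared-border adjacency, spatially structured covariates
(here only the *coefficients* are spatial), and measurement error in the
outcome beyond Bernoulli sampling.  Passing tests therefore demonstrate
correctness of the algorithms and recoverability under controlled
heterogeneity, not performance guarantees on any particular census.

## Numerical choices and limitations

- Probabilities are clipped at 1e-10 in deviances and logits; IRLS
  variances floored at 1e-5; lasso zeros snapped below 1e-10; latent-block
  variances floored at 1e-6.
- Degenerate CV points and final fits are flagged, counted and logged,
  never dropped.
- Problem sizes throughout the suite (N=200, p=10; 5 × 10 CV grids) are
  desk-scale choices that keep a full two-stage run around a minute while
  leaving the N × N kernel algebra and the S·N·T path structure identical
  to larger studies; the estimation code itself is O(S·N·(path fit)) and
  has been exercised at N=1743, p=91 (the I/O round-trip test).
- LOO-CV is the only bandwidth selector provided (no k-fold, no AICc); the
  lasso estimates are shrunk, not debiased; no standard errors are reported
  for local coefficients — inference on them is a known open problem.
- With spherical inputs the haversine distance is great-circle km on a
  spherical Earth (radius 6371.0088 km); no geodesic ellipsoid corrections.
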