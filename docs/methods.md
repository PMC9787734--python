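# Methods

## The procedure

`qsarval` quantifies how the three aspects of regression-model validation —
goodness of fit, robustness and predictivity — depend on training-set size
and model family.  The protocol, per dataset and model specification:

1. For each sample size in a configured series, draw many random subsets of
   the dataset without replacement (repetition is not allowed within one
   subset).
2. Split each subset into training and test parts with an 80/20 ratio
   (random split by default; deterministic Kennard–Stone max-min splitting
   available for comparison).
3. Fit the model on the training part; record R² and RMSE on the training
   set, Q²_LOO / Q²_LMO / RMSE_LOO from cross-validation of the training
   set, and Q²_F2 / RMSE_test on the test set.
4. Summarize per size by the median (robust against the badly-modelled
   draws that drag means), giving one learning curve per metric.
5. Optionally repeat the whole sweep on randomized (null) copies of each
   drawn subset to measure chance correlation, and compute Spearman rank
   correlations between the validation parameters, pooled or per class.

All metric definitions are the unadjusted ones: R² = 1 − RSS/TSS,
RMSE = √(RSS/n) (divide by n, not n − p), Q²_F2 with the test-set mean in
the denominator.  MSS is computed about the mean of the modelled responses,
so RSS + MSS = TSS is asserted only for OLS-with-intercept fits, where it
is exact.  For multi-response PLS2 every metric is computed per response
and retained per response; averaging across responses is a reporting
convenience only.

## Model adapters

The four families share a uniform fit/predict contract with the
diagnostics the analysis needs:

* **MLR** — ordinary least squares on all predictors with a free intercept
  (numpy QR/lstsq); parameter count p.  Rank-deficient or underdetermined
  designs are errors.
* **PLS2** — two-block partial least squares (NIPALS, scikit-learn),
  latent pairs extracted sequentially on residual matrices under a maximal
  covariance criterion; optional standardization of X and Y (predictions
  return on the original scale).  The latent-variable count is a required
  user choice: the package exposes per-n_latent validation curves rather
  than an automatic selector, because internal and external validation
  generally disagree about the optimum and the compromise is a judgement
  call.
* **ANN** — one hidden layer (scikit-learn MLPRegressor) with logistic /
  tanh / relu activations and lbfgs / adam / sgd optimizers.  The default
  hidden-layer size follows a weight-budget rule: the largest H whose
  (p+1)·H + (H+1) weights do not exceed the case count at the smallest
  sweep size.  Non-convergence is flagged, not raised.  Stochastic fits are
  reproducible through the rng threaded into every fit.
* **SVR** — ε-insensitive support vector regression with an RBF kernel
  (scikit-learn/libsvm).  The support-vector count and fraction are always
  reported: a fraction approaching 1 means the model is memorizing the
  training set, and its goodness of fit certifies nothing.

ANN and SVR adapters standardize predictors and response internally with
training-set statistics (ε is therefore interpreted on the standardized
response scale); this is exposed as a `scale` hyperparameter.
Hyperparameter grids are reduced to at most 25 combinations per family;
full scans remain possible by constructing specs directly.

## Cross-validation and the n_fitted axis

Q²_LOO for linear models uses the hat-matrix identity
yᵢ − ŷᵢ/ᵢ = eᵢ/(1 − hᵢᵢ), which reproduces explicit n-refit PRESS to
floating-point accuracy at the cost of a single fit; nonlinear families are
refitted explicitly.  Leave-many-out uses one random partition into m
balanced folds (sizes differing by at most 1) drawn once per training set —
never re-drawn — and reports n_fitted as the mean of (n_train − fold size)
over folds.  TSS in Q²_LMO uses the full training-set mean, not per-fold
means.  With m = n_train the scheme reduces to LOO exactly (fold
complements preserve row order, so even libsvm fits are bit-identical).

`rescale_to_fitted` re-indexes every cross-validation curve by n_fitted and
measures the gap between each LMO point and the linearly interpolated LOO
curve; points outside the LOO n_fitted range are excluded rather than
extrapolated.

Replicated measurements break plain LOO: replicates of a held-out sample
remain in the fit and leak information.  `grouped_cv` provides
leave-sample-out (whole replicate groups omitted at once) and
LOO-on-group-means; replicate groups are likewise atomic in sampling and
splitting.

## Randomization nulls

Three schemes: y-scrambling permutes the response rows (multiset preserved
exactly); y-randomization draws responses independently from the response
distribution; x-randomization draws every predictor cell independently from
its column distribution, destroying inter-predictor as well as
predictor–response correlation.  "From the distribution" is implemented as
empirical resampling with replacement by default — distribution-free — with
a fitted-normal option, and a per-column permutation mode for
x-randomization that preserves column multisets exactly.  Randomization is
applied after the subset is drawn and before splitting, so train and test
are both null.  For OLS with intercept the permutation expectation of the
null R² is exactly p/(n − 1) for any response vector (the numerator's
projection has rank p and the denominator is permutation-invariant), which
the tests verify both by Monte Carlo and by exhaustive enumeration of all
permutations at n = 8.

## Rank correlations

Spearman rho (average ranks on ties — the standard convention; the
procedure is about monotone association, not linear) over the 15 unordered
pairs of the six metrics.  Two pooling levels: overall per model family
(one rho per pair over all records; pooling across datasets requires
standardized responses so RMSE-like metrics are commensurable, and mixed
standardization is an error), and intra-class (rho across the repeated
models of one dataset × spec × size cell, emitted as size-indexed curves;
classes with a constant metric are flagged degenerate, not dropped).  No
significance tests are attached — the magnitudes are the object of study.

## The synthetic generator

Real benchmark datasets in this field are external downloads; the generator
instead produces tables with the structural features the analysis depends
on, so every stage is testable offline:

* standardized Gaussian predictors with pairwise equicorrelation 0.5 by
  default (descriptor sets are typically inter-correlated); configurable in
  [0, 1);
* response structures: `linear` (y = Xβ + ε, β ~ N(0, coef_scale²)),
  `nonlinear_smooth` (2·sin(x₁) + x₂² + x₃ + ε — misspecified for MLR,
  learnable by small ANN/SVR), and `latent_factor_multiresponse`
  (q responses sharing k < p latent factors, predictor noise 0.05 so the
  factor directions stay recoverable and k latent pairs suffice — the PLS2
  use case);
* i.i.d. Gaussian response noise, sd 1.0 by default;
* optional badly-modellable cases: a fraction of responses shifted by a
  constant, producing the allocation effect when samples nearly exhaust the
  dataset;
* optional replicates: each case duplicated with independent within-group
  noise and group labels, for the leakage comparisons.

True parameters are returned in a separate truth dict, not on the Dataset.
What the generator does **not** emulate: heavy-tailed or skewed responses,
discrete/one-hot descriptor blocks (supported in the loader, not
generated), heteroscedastic noise, and the idiosyncratic redundancy
structure of real descriptor sets.  Passing tests therefore demonstrate the
machinery's correctness and the qualitative phenomena (overfitting at small
n, LOO/LMO overlay, null decay, allocation-driven anticorrelation), not
quantitative transfer to any particular real dataset.

## Numerical and design choices

* 80/20 split size uses round-half-to-even on ratio·size; recorded per
  record as n_train/n_test.
* Random number architecture: one master seed spawns an independent child
  stream per (size index, repetition) via `SeedSequence(entropy, spawn_key)`,
  so any repetition is reproducible in isolation and results are
  independent of execution order.
* Failed fits are logged with their (size, repetition, spec, scheme) and
  skipped; a sweep aborts only if more than half the fits at one size fail.
* Default repetition count is 500 per size.  The bundled analysis scripts
  use 2 000 draws for null means, 200 repetitions for large-n convergence
  (per-repetition Q²_F2 scatter ≈ 0.02, so the median's Monte-Carlo error
  ≈ 0.002, an order below the 0.01 comparisons made on it), 300 for the
  allocation study and 200 paired simulations for the leakage sign test.
* Overall rank tables that pool heterogeneous datasets are computed on
  three generator variants differing in noise sd (0.5 / 1 / 2): within a
  single homogeneous dataset, subset-to-subset TSS variation decorrelates
  R² from RMSE, whereas the cross-dataset design — the setting the overall
  table is meant for — spans different attainable fit qualities.
* Oracle-equality tolerances are 1e−8 relative (double-precision
  closed-form algebra); Kennard–Stone ties break toward the lowest row
  index and an all-duplicate input is logged, not fatal.

## Known limitations

Hyperparameter grids are deliberately small; no automatic n_latent
selection for PLS2; no bootstrap robustness or repeated double
cross-validation; permutation nulls are used as curves, not as p-values
for individual models; plotting is limited to CSV curve export.
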