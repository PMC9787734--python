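# qsarval

Sample-size-dependent validation of regression models: goodness of fit,
robustness and predictivity in one sweep.

Regulatory QSAR practice (and tabular regression modelling generally)
validates a model along three aspects: **goodness of fit** — how well the
model reproduces the responses it was trained on (R², RMSE); **robustness**
— stability under internal resampling, measured by cross-validation
(Q²_LOO, Q²_LMO, RMSE_LOO); and **predictivity** — performance on an
external test set never used in parameter optimization (Q²_F2, RMSE_test).
How much independent information these parameters carry, and how strongly
each is distorted by small samples and by chance correlation, depends on
the training-set size and the model family. `qsarval` makes those
dependencies measurable: it sweeps random subsamples of a dataset over a
grid of sample sizes, fits MLR, PLS2, single-hidden-layer ANN and ε-SVR
(RBF) models on 80/20 train/test splits, records every validation
parameter per repetition, and summarizes the learning curves, null
(randomized) curves, the LOO↔LMO rescaling, and rank correlations between
the parameters.

## The quantities

For a training set of n cases with responses y, model values ŷ:

    RSS = Σ(yᵢ − ŷᵢ)²          TSS = Σ(yᵢ − ȳ)²        R² = 1 − RSS/TSS
    RMSE = √(RSS/n)
    PRESS = Σ(yᵢ − ŷᵢ/ᵢ)²                               Q²_LOO = 1 − PRESS/TSS
    Q²_LMO = 1 − Σ(yᵢ − ŷᵢ/ⱼ)² / TSS                    RMSE_LOO = √(PRESS/n)
    Q²_F2 = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ_test)²   (test set; mean of test y)
    RMSE_test as RMSE on the test set

where ŷᵢ/ᵢ is the response of case i predicted by a model fitted without
case i.  For linear least squares PRESS needs no refitting: with hat-matrix
diagonal h, the leave-one-out residual is eᵢ/(1 − hᵢᵢ).  Q²_LMO from a
single random m-fold subdivision overlays the Q²_LOO curve when both are
plotted against n_fitted, the mean number of cases fitted per sub-model —
so whichever cross-validation scheme is computationally cheaper for a model
family can stand in for the other.  Chance correlation is estimated by
y-scrambling (permuting responses), y-randomization and x-randomization
nulls; for OLS with intercept the permutation expectation of the null R²
is exactly p/(n − 1).

## Worked example

```python
from qsarval import (SyntheticConfig, make_dataset, mlr_spec, run_sweep,
                     standardize_responses, summarize_sweep)

dataset, _ = make_dataset(SyntheticConfig(n=2000, p=5, noise_sd=1.0, seed=0))
dataset = standardize_responses(dataset)
sweep = run_sweep(dataset, [mlr_spec()], sizes=[30, 100, 500],
                  n_repeats=200, mfold_ms=(5,), seed=0)
medians = summarize_sweep(sweep, "median")
print(medians[["size", "r2", "q2_loo", "q2_lmo_m5", "q2_f2", "rmse_test"]].round(3))
```

prints

```
   size     r2  q2_loo  q2_lmo_m5  q2_f2  rmse_test
0    30  0.904   0.828      0.812  0.775      0.401
1   100  0.878   0.857      0.855  0.835      0.380
2   500  0.865   0.861      0.860  0.862      0.369
```

Reading the
table: the goodness-of-fit median `r2` *decreases* with sample size — small
training sets flatter the model (overfitting), so a higher R² from a
smaller sample is never by itself evidence of a better model.  The
robustness (`q2_loo`, `q2_lmo_m5`) and predictivity (`q2_f2`) medians
*increase* with size, and all three aspects converge toward a common limit
on this well-specified linear problem.  The 5-fold `q2_lmo_m5` trails
`q2_loo` slightly at each size because its sub-models fit fewer cases; on
the n_fitted axis the two curves coincide (`rescale_to_fitted`).

A YAML-driven CLI wraps the same machinery:

```sh
qsarval simulate --out data.csv --n 500 --p 5 --seed 1
qsarval run --config study.yaml --seed 1 --out study_out
qsarval summarize --records study_out/records.csv --out reanalysis
```

`run` writes `records.csv` (one row per fitted model), `summary.csv`,
rank-correlation tables, the LOO/LMO overlay-gap table and a `manifest.json`
that makes the run bit-reproducible.

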