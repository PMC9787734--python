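"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the shape of tabular regression benchmarks used in
QSAR-style validation studies: continuous, mutually correlated predictors
and one or several continuous responses with linear or smooth nonlinear
dependence plus i.i.d. noise.  Optional extras reproduce the phenomena the
validation machinery is designed to expose: badly-modellable outlier cases
(allocation effects) and replicated measurements (leakage under
leave-case-out cross-validation).

The true coefficients / latent structure are returned in a separate truth
dictionary, not on the :class:`~qsarval.resampling.Dataset`, so pipeline
code cannot accidentally consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .resampling import Dataset

__all__ = ["SyntheticConfig", "make_dataset", "add_replicates"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``predictor_correlation`` is the pairwise equicorrelation of the
    standardized Gaussian predictors (0.5 by default — molecular descriptors
    are typically substantially inter-correlated).  ``noise_sd`` is the
    response noise standard deviation in response units.  ``structure`` is
    one of ``linear`` (y = Xβ + ε), ``nonlinear_smooth`` (a sine/quadratic
    mix of 2–3 predictors, learnable by small ANN/SVR but misspecified for
    MLR) or ``latent_factor_multiresponse`` (q responses sharing
    ``n_factors`` < p latent factors, the PLS2 use case).
    """

    n: int = 500
    p: int = 5
    q: int = 1
    structure: str = "linear"
    predictor_correlation: float = 0.5
    noise_sd: float = 1.0
    coef_scale: float = 1.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    n_factors: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.predictor_correlation < 1.0:
            raise ValueError("predictor_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.outlier_fraction <= 0.2:
            raise ValueError("outlier_fraction must be in [0, 0.2]")
        if self.structure not in (
            "linear", "nonlinear_smooth", "latent_factor_multiresponse"
        ):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "latent_factor_multiresponse":
            if not 1 <= self.n_factors < self.p:
                raise ValueError("need 1 <= n_factors < p")
        elif self.structure == "nonlinear_smooth" and self.p < 3:
            raise ValueError("nonlinear_smooth needs p >= 3")


def _correlated_predictors(rng, n, p, rho) -> np.ndarray:
    # equicorrelated Gaussian: common factor + independent remainder
    z = rng.standard_normal((n, p))
    common = rng.standard_normal((n, 1))
    return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * z


def make_dataset(config: SyntheticConfig) -> tuple[Dataset, dict]:
    """Generate a dataset and its ground truth, reproducibly from the seed.

    Returns ``(dataset, truth)`` where ``truth`` holds the true
    coefficients (linear), the noiseless response surface values
    (nonlinear), or the latent factors and loadings (multiresponse), plus
    the injected outlier indices.
    """
    rng = np.random.default_rng(config.seed)
    n, p, q = config.n, config.p, config.q
    truth: dict = {"config": config}

    if config.structure == "latent_factor_multiresponse":
        k = config.n_factors
        T = rng.standard_normal((n, k))
        A = rng.normal(0.0, 1.0, size=(k, p))
        B = rng.normal(0.0, config.coef_scale, size=(k, q))
        # predictor noise kept small so the k factor directions remain
        # recoverable from X and k latent pairs suffice for the signal
        X = T @ A + 0.05 * rng.standard_normal((n, p))
        Y = T @ B + config.noise_sd * rng.standard_normal((n, q))
        truth.update(factors=T, x_loadings=A, y_loadings=B)
    else:
        X = _correlated_predictors(rng, n, p, config.predictor_correlation)
        if config.structure == "linear":
            beta = rng.normal(0.0, config.coef_scale, size=(p, q))
            intercept = rng.normal(0.0, config.coef_scale, size=q)
            signal = X @ beta + intercept
            truth.update(beta=beta, intercept=intercept)
        else:  # nonlinear_smooth
            signal = (
                2.0 * np.sin(X[:, 0]) + X[:, 1] ** 2 + X[:, 2]
            )[:, None] * np.ones((1, q)) * config.coef_scale
            truth.update(signal=signal.copy())
        Y = signal + config.noise_sd * rng.standard_normal((n, q))

    outlier_idx = np.array([], dtype=int)
    if config.outlier_fraction > 0 and config.outlier_shift != 0:
        n_out = int(round(config.outlier_fraction * n))
        outlier_idx = rng.choice(n, size=n_out, replace=False)
        Y[outlier_idx] += config.outlier_shift
    truth["outlier_idx"] = outlier_idx

    return (
        Dataset(X=X, Y=Y, name=f"synthetic-{config.structure}"),
        truth,
    )


def add_replicates(
    dataset: Dataset,
    replicates_per_case: int,
    within_noise_sd: float,
    rng: np.random.Generator,
) -> Dataset:
    """Duplicate every case with independent within-group response noise.

    Each original case becomes one replicate group of size
    ``replicates_per_case`` sharing the same predictor row; group labels are
    attached.  Emulates repeated measurements on the same sample (e.g.
    triplicate analytical determinations), the situation where
    leave-case-out cross-validation leaks information.
    """
    if replicates_per_case < 2:
        raise ValueError("replicates_per_case must be >= 2")
    r = replicates_per_case
    idx = np.repeat(np.arange(dataset.n), r)
    X = dataset.X[idx]
    Y = dataset.Y[idx] + within_noise_sd * rng.standard_normal(
        (dataset.n * r, dataset.q)
    )
    groups = idx.copy()
    import dataclasses

    return dataclasses.replace(dataset, X=X, Y=Y, groups=groups)
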