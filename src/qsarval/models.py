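"""Uniform fit/predict adapters for the four regression families.

The families are multivariate linear regression (MLR, ordinary least
squares on all predictors), two-block partial least squares (PLS2, latent
variables in both predictor and response space, NIPALS), a single-hidden-
layer feed-forward neural network (ANN), and epsilon-support-vector
regression with a Gaussian RBF kernel (SVR).

Each ``fit_*`` function returns a :class:`FittedModel` exposing a uniform
``predict`` contract plus the diagnostics the downstream analysis needs:
the optimized-parameter count ``p_params`` (without the intercept), the
latent-variable count for PLS2, the support-vector count and fraction for
SVR, and a convergence flag for the ANN.  The estimators themselves are the
standard numpy/scikit-learn implementations; this module owns the adapter
contract, the diagnostics and the hyperparameter grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Any, Callable, Mapping

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import (
    DegenerateInputError,
    SingularDesignError,
    UnderdeterminedError,
)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "mlr_spec",
    "pls2_spec",
    "ann_spec",
    "svr_spec",
    "ann_hidden_for_budget",
    "fit_mlr",
    "fit_pls2",
    "fit_ann",
    "fit_svr",
    "fit_model",
    "default_grid",
]

FAMILIES = ("mlr", "pls2", "ann", "svr")


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameters.

    ``params`` must be complete for the family; stochastic fits (ANN with
    adam/sgd, and weight initialization generally) are reproducible given
    the ``rng`` passed to the fit function.
    """

    family: str
    params: Mapping[str, Any] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.name:
            object.__setattr__(self, "name", self._auto_name())

    def _auto_name(self) -> str:
        if not self.params:
            return self.family
        items = ",".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.family}({items})"


@dataclass
class FittedModel:
    """A fitted predictor with the diagnostics used by the validation sweep."""

    spec: ModelSpec
    predict: Callable[[np.ndarray], np.ndarray]
    p_params: int
    n_train: int
    diagnostics: dict = field(default_factory=dict)


def mlr_spec() -> ModelSpec:
    return ModelSpec("mlr")


def pls2_spec(n_latent: int, standardize: bool = True) -> ModelSpec:
    if n_latent < 1:
        raise ValueError("n_latent must be >= 1")
    return ModelSpec("pls2", {"n_latent": n_latent, "standardize": standardize})


def ann_spec(
    n_hidden: int,
    activation: str = "tanh",
    solver: str = "lbfgs",
    tol: float = 1e-4,
    max_iter: int = 500,
    scale: bool = True,
    **solver_params,
) -> ModelSpec:
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if activation not in ("logistic", "tanh", "relu"):
        raise ValueError(f"unsupported activation {activation!r}")
    if solver not in ("lbfgs", "adam", "sgd"):
        raise ValueError(f"unsupported solver {solver!r}")
    params = {
        "n_hidden": n_hidden,
        "activation": activation,
        "solver": solver,
        "tol": tol,
        "max_iter": max_iter,
        "scale": scale,
    }
    params.update(solver_params)
    return ModelSpec("ann", params)


def svr_spec(
    gamma: float | str = "scale",
    epsilon: float = 0.1,
    C: float = 1.0,
    shrinking: bool = True,
    tol: float = 1e-3,
    scale: bool = True,
) -> ModelSpec:
    if isinstance(gamma, (int, float)) and gamma <= 0:
        raise ValueError("gamma must be positive")
    if C <= 0:
        raise ValueError("C must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    return ModelSpec(
        "svr",
        {
            "gamma": gamma,
            "epsilon": epsilon,
            "C": C,
            "shrinking": shrinking,
            "tol": tol,
            "scale": scale,
        },
    )


def ann_hidden_for_budget(p: int, n_cases: int) -> int:
    """Hidden-layer size whose weight count roughly matches ``n_cases``.

    A single-hidden-layer network with H neurons on p inputs optimizes
    (p+1)*H + (H+1) weights; the default sizing rule picks the largest H
    whose weight count does not exceed the number of independent cases at
    the smallest sample size of the sweep.
    """
    h = (n_cases - 1) // (p + 2)
    return max(1, h)


def ann_n_params(p: int, n_hidden: int) -> int:
    return (p + 1) * n_hidden + (n_hidden + 1)


# ---------------------------------------------------------------------------
# fitting


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _check_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("inputs must be finite (no NaN/inf)")


def fit_mlr(X, y) -> FittedModel:
    """Ordinary least squares on all predictors, non-zero intercept allowed.

    ``p_params`` is the number of predictors (intercept not counted).
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    n, p = X.shape
    if p < 1:
        raise ValueError("MLR needs at least one predictor")
    if n <= p + 1:
        raise UnderdeterminedError(f"need n_train > p+1 (n={n}, p={p})")
    D = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(D) < p + 1:
        raise SingularDesignError("design matrix (with intercept) is rank deficient")
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)

    def predict(Xnew, coef=coef):
        Xnew = _as_2d(Xnew)
        return np.column_stack([np.ones(Xnew.shape[0]), Xnew]) @ coef

    return FittedModel(
        spec=mlr_spec(),
        predict=predict,
        p_params=p,
        n_train=n,
        diagnostics={"coef": coef[1:], "intercept": coef[0]},
    )


def fit_pls2(X, Y, spec: ModelSpec) -> FittedModel:
    """Two-block PLS with sequential latent-pair extraction (NIPALS).

    Latent predictor/response vector pairs are extracted sequentially on
    residual matrices under a maximal-covariance criterion; optional
    standardization of X and Y (predictions always return on the original
    response scale).  ``Y`` may have one or several columns.
    """
    X = _as_2d(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    _check_finite(X, Y)
    n, p = X.shape
    n_latent = int(spec.params["n_latent"])
    standardize = bool(spec.params.get("standardize", True))
    if n_latent > min(p, n - 1):
        raise ValueError(
            f"n_latent={n_latent} exceeds min(p, n_train-1)={min(p, n - 1)}"
        )
    if standardize and (np.any(X.std(axis=0) == 0) or np.any(Y.std(axis=0) == 0)):
        raise DegenerateInputError("zero-variance column cannot be standardized")
    est = PLSRegression(n_components=n_latent, scale=standardize)
    est.fit(X, Y)

    def predict(Xnew, est=est, q=Y.shape[1]):
        out = est.predict(_as_2d(Xnew))
        return out[:, 0] if q == 1 else out

    # q regression weights per latent pair, plus the x-loadings actually
    # optimized; report the regression-coefficient count as the parameter
    # count the sweep uses for sizing.
    return FittedModel(
        spec=spec,
        predict=predict,
        p_params=p * Y.shape[1],
        n_train=n,
        diagnostics={"n_latent": n_latent, "x_weights": est.x_weights_},
    )


def fit_ann(X, y, spec: ModelSpec, rng: np.random.Generator | None = None) -> FittedModel:
    """Single-hidden-layer regression network.

    Inputs (and the response) are standardized with training-set statistics
    when ``scale`` is set.  Non-convergence is not an error: the fitted model
    carries a ``converged`` flag.  Reproducible given ``rng``.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    _check_finite(X, y)
    n, p = X.shape
    params = dict(spec.params)
    n_hidden = int(params.pop("n_hidden"))
    scale = bool(params.pop("scale", True))
    solver = params.pop("solver")
    activation = params.pop("activation")
    tol = params.pop("tol", 1e-4)
    max_iter = int(params.pop("max_iter", 500))
    rng = rng or np.random.default_rng(0)
    random_state = int(rng.integers(0, 2**31 - 1))

    if scale:
        xsc = StandardScaler().fit(X)
        Xs = xsc.transform(X)
        y_mean, y_sd = y.mean(), y.std()
        y_sd = y_sd if y_sd > 0 else 1.0
        ys = (y - y_mean) / y_sd
    else:
        xsc, y_mean, y_sd = None, 0.0, 1.0
        Xs, ys = X, y

    est = MLPRegressor(
        hidden_layer_sizes=(n_hidden,),
        activation=activation,
        solver=solver,
        tol=tol,
        max_iter=max_iter,
        random_state=random_state,
        **params,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        est.fit(Xs, ys)
    converged = est.n_iter_ < max_iter

    def predict(Xnew, est=est, xsc=xsc, y_mean=y_mean, y_sd=y_sd):
        Xnew = _as_2d(Xnew)
        if xsc is not None:
            Xnew = xsc.transform(Xnew)
        return est.predict(Xnew) * y_sd + y_mean

    return FittedModel(
        spec=spec,
        predict=predict,
        p_params=ann_n_params(p, n_hidden),
        n_train=n,
        diagnostics={"converged": converged, "n_iter": int(est.n_iter_)},
    )


def fit_svr(X, y, spec: ModelSpec) -> FittedModel:
    """Epsilon-SVR with an RBF kernel; deterministic for fixed data and spec.

    The support-vector count and fraction are reported as diagnostics: a
    fraction approaching 1 signals that the model is memorizing rather than
    generalizing (chance-correlation warning).  ``epsilon`` is interpreted on
    the standardized response scale when ``scale`` is set.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    _check_finite(X, y)
    n, p = X.shape
    params = dict(spec.params)
    scale = bool(params.pop("scale", True))
    if scale:
        xsc = StandardScaler().fit(X)
        Xs = xsc.transform(X)
        y_mean, y_sd = y.mean(), y.std()
        y_sd = y_sd if y_sd > 0 else 1.0
        ys = (y - y_mean) / y_sd
    else:
        xsc, y_mean, y_sd = None, 0.0, 1.0
        Xs, ys = X, y
    est = SVR(kernel="rbf", **params)
    est.fit(Xs, ys)
    n_sv = int(est.support_.size)

    def predict(Xnew, est=est, xsc=xsc, y_mean=y_mean, y_sd=y_sd):
        Xnew = _as_2d(Xnew)
        if xsc is not None:
            Xnew = xsc.transform(Xnew)
        return est.predict(Xnew) * y_sd + y_mean

    return FittedModel(
        spec=spec,
        predict=predict,
        p_params=max(1, n_sv),  # one dual coefficient per support vector
        n_train=n,
        diagnostics={"n_support_vectors": n_sv, "sv_fraction": n_sv / n},
    )


def fit_model(
    spec: ModelSpec, X, Y, rng: np.random.Generator | None = None
) -> FittedModel:
    """Dispatch to the family-specific fit function."""
    if spec.family == "mlr":
        return fit_mlr(X, Y)
    if spec.family == "pls2":
        return fit_pls2(X, Y, spec)
    if spec.family == "ann":
        return fit_ann(X, Y, spec, rng)
    if spec.family == "svr":
        return fit_svr(X, Y, spec)
    raise ValueError(f"unknown family {spec.family!r}")


def default_grid(family: str, p: int = 5, n_min: int = 30) -> list[ModelSpec]:
    """A reduced hyperparameter grid (<= 25 combinations) per family.

    Full-scale scans remain possible by constructing specs directly; these
    grids cover the reasonable corner of each family's hyperparameter space
    for the sweep studies.
    """
    if family == "mlr":
        return [mlr_spec()]
    if family == "pls2":
        return [pls2_spec(k) for k in range(1, min(p, 5) + 1)]
    if family == "ann":
        h = ann_hidden_for_budget(p, n_min)
        return [
            ann_spec(n_hidden=h, activation=a, solver=s)
            for a, s in product(("tanh", "relu", "logistic"), ("lbfgs", "adam"))
        ]
    if family == "svr":
        return [
            svr_spec(gamma=g, epsilon=e, C=c)
            for g, e, c in product(("scale", 1.0), (0.01, 0.1, 0.5), (1.0, 10.0))
        ]
    raise ValueError(f"unknown family {family!r}")
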