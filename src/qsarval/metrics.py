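"""Validation parameters for regression models.

Three aspects of model validation are quantified:

* goodness of fit -- how well a model reproduces the responses it was
  trained on (R², RMSE on the training set);
* robustness -- stability under internal resampling, here summarized by
  PRESS, the sum of squared cross-validated residuals (the cross-validation
  drivers live in :mod:`qsarval.crossval`);
* predictivity -- performance on an external test set (Q²_F2, RMSE_test).

Conventions: R² = 1 - RSS/TSS without any degrees-of-freedom adjustment,
RMSE = sqrt(RSS/n) (divide by n, not n - p), and Q²_F2 uses the mean of the
*test-set* observations in its denominator.  For an OLS fit with intercept
the decomposition RSS + MSS = TSS holds exactly and 0 <= R² <= 1; for
nonlinear models R² <= 1 is the only guaranteed bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateInputError,
    SingularDesignError,
    UndefinedLOOError,
    UnderdeterminedError,
)

__all__ = [
    "FitSummary",
    "ExternalSummary",
    "goodness_of_fit",
    "external_validation",
    "press_hat_matrix",
    "hat_diagonal",
    "ols_loo_residuals",
]


@dataclass(frozen=True)
class FitSummary:
    """Training-set sums of squares and derived goodness-of-fit metrics.

    ``rss``, ``mss`` and ``tss`` are in squared response units, ``rmse`` in
    response units, ``r2`` dimensionless.  ``mss`` is computed about the mean
    of the *modelled* responses, so ``rss + mss == tss`` is exact only for an
    OLS-with-intercept fit.
    """

    rss: float
    mss: float
    tss: float
    r2: float
    rmse: float
    n: int


@dataclass(frozen=True)
class ExternalSummary:
    """External-test-set predictivity metrics.

    ``q2_f2 <= 1`` always; it can be arbitrarily negative when predictions
    are worse than predicting the test-set mean.
    """

    q2_f2: float
    rmse_test: float
    n_test: int


def _validated_pair(y_obs, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_obs.shape != y_hat.shape:
        raise ValueError(
            f"observed and modelled responses differ in length: "
            f"{y_obs.size} vs {y_hat.size}"
        )
    if y_obs.size < 2:
        raise ValueError("need at least 2 cases")
    if not (np.all(np.isfinite(y_obs)) and np.all(np.isfinite(y_hat))):
        raise ValueError("responses must be finite")
    return y_obs, y_hat


def goodness_of_fit(y_obs, y_hat) -> FitSummary:
    """Training-set R², RMSE and the RSS/MSS/TSS decomposition.

    Parameters
    ----------
    y_obs, y_hat
        Observed and modelled responses for the cases the model was fitted
        on; equal length >= 2, finite.

    Raises
    ------
    DegenerateInputError
        If the observed responses have zero variance (TSS = 0 makes R²
        undefined).
    """
    y_obs, y_hat = _validated_pair(y_obs, y_hat)
    n = y_obs.size
    tss = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if tss <= 0.0:
        raise DegenerateInputError("zero-variance responses: R² is undefined")
    rss = float(np.sum((y_obs - y_hat) ** 2))
    mss = float(np.sum((y_hat - y_hat.mean()) ** 2))
    return FitSummary(
        rss=rss,
        mss=mss,
        tss=tss,
        r2=1.0 - rss / tss,
        rmse=float(np.sqrt(rss / n)),
        n=n,
    )


def external_validation(y_test, y_pred) -> ExternalSummary:
    """Q²_F2 and RMSE on an external test set.

    Q²_F2 = 1 - sum((y - yhat)²) / sum((y - mean(y_test))²), with the mean
    taken over the test-set observations only.  A value of 0 means the model
    carries as much information as the test-set mean; negative values mean
    less.
    """
    y_test, y_pred = _validated_pair(y_test, y_pred)
    n_test = y_test.size
    denom = float(np.sum((y_test - y_test.mean()) ** 2))
    if denom <= 0.0:
        raise DegenerateInputError("zero-variance test responses: Q²_F2 is undefined")
    num = float(np.sum((y_test - y_pred) ** 2))
    return ExternalSummary(
        q2_f2=1.0 - num / denom,
        rmse_test=float(np.sqrt(num / n_test)),
        n_test=n_test,
    )


def _design_with_intercept(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(X.shape[0]), X])


def hat_diagonal(X) -> np.ndarray:
    """Diagonal of the OLS hat (projection) matrix for a design with intercept.

    Computed from the thin QR factorization of [1 | X]: h_ii = sum_k Q_ik².
    """
    D = _design_with_intercept(X)
    n, pp1 = D.shape
    if n <= pp1:
        raise UnderdeterminedError(f"need n > p+1 cases (n={n}, p+1={pp1})")
    if np.linalg.matrix_rank(D) < pp1:
        raise SingularDesignError("design matrix (with intercept) is rank deficient")
    Q, _ = np.linalg.qr(D)
    return np.einsum("ij,ij->i", Q, Q)


def ols_loo_residuals(X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS residuals, leverages and leave-one-out residuals e_i / (1 - h_ii).

    Returns ``(residuals, leverages, loo_residuals)``.  The identity
    ``y_i - yhat_{i/i} = e_i / (1 - h_ii)`` makes an explicit n-refit
    leave-one-out loop unnecessary for linear least squares.
    """
    D = _design_with_intercept(X)
    y = np.asarray(y, dtype=float).ravel()
    h = hat_diagonal(X)
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    one_minus_h = 1.0 - h
    if np.any(one_minus_h <= 1e-12):
        raise UndefinedLOOError("a leverage of 1 makes the LOO residual undefined")
    return resid, h, resid / one_minus_h


def press_hat_matrix(X, y) -> float:
    """PRESS for an OLS-with-intercept fit via the hat-matrix shortcut.

    PRESS = sum_i (e_i / (1 - h_ii))² where e_i are the ordinary residuals
    and h_ii the hat-matrix diagonal; equal to the explicit leave-one-out
    refitting PRESS up to floating-point error.
    """
    _, _, loo_resid = ols_loo_residuals(X, y)
    return float(np.sum(loo_resid**2))
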