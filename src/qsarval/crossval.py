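"""Cross-validation schemes and the LOO/LMO rescaling to the n_fitted axis.

Leave-one-out (LOO) omits cases one by one; leave-many-out (LMO) is an
m-fold scheme with a single random, balanced partition per training set.
Both report Q² = 1 - PRESS/TSS with TSS taken about the full training-set
mean, and an RMSE analogue sqrt(PRESS/n).  ``n_fitted`` — the mean number
of cases actually fitted per sub-model — is the abscissa on which LOO and
LMO curves of the same model family overlay.

For replicated measurements, grouped schemes either omit whole replicate
groups at once (leave-sample-out) or first collapse each group to its mean
row; leave-case-out on replicated rows leaks information between train and
held-out replicates of the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, EmptyOverlapError
from .metrics import ols_loo_residuals
from .models import ModelSpec, fit_model

__all__ = ["CVResult", "loo_cv", "mfold_cv", "grouped_cv", "rescale_to_fitted"]


@dataclass
class CVResult:
    """Cross-validated Q², its RMSE analogue, and the scheme bookkeeping.

    ``predictions`` holds the cross-validated response of every case in the
    original row order (shape (n,) or (n, q)).  ``n_fitted`` is the mean
    number of cases fitted per sub-model: n-1 for LOO, n - fold size
    averaged over folds for m-fold.
    """

    q2: float | np.ndarray
    rmse_cv: float | np.ndarray
    press: float | np.ndarray
    n_train: int
    n_fitted: float
    scheme: str
    predictions: np.ndarray


def _q2_from_predictions(y: np.ndarray, pred: np.ndarray):
    """Q² = 1 - PRESS/TSS per response column; TSS about the full-set mean."""
    y2 = y if y.ndim == 2 else y[:, None]
    p2 = pred if pred.ndim == 2 else pred[:, None]
    tss = np.sum((y2 - y2.mean(axis=0)) ** 2, axis=0)
    if np.any(tss <= 0):
        raise DegenerateInputError("zero-variance responses: Q² is undefined")
    press = np.sum((y2 - p2) ** 2, axis=0)
    q2 = 1.0 - press / tss
    rmse = np.sqrt(press / y2.shape[0])
    if y.ndim == 1:
        return float(q2[0]), float(rmse[0]), float(press[0])
    return q2, rmse, press


def loo_cv(
    spec: ModelSpec, X, y, rng: np.random.Generator | None = None
) -> CVResult:
    """Leave-one-out cross-validation.

    For MLR the hat-matrix shortcut yields every leave-one-out residual from
    a single fit; other families are refitted n times.  Stochastic families
    draw one child seed per sub-fit from ``rng`` so the result is
    reproducible.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if spec.family == "mlr" and y.ndim == 1:
        _, _, loo_resid = ols_loo_residuals(X, y)
        pred = y - loo_resid
    else:
        rng = rng or np.random.default_rng(0)
        pred = np.empty_like(y, dtype=float)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            try:
                fm = fit_model(spec, X[mask], y[mask], rng)
            except Exception as exc:  # annotate which case broke the sub-fit
                raise type(exc)(f"LOO sub-fit failed leaving out case {i}: {exc}") from exc
            pred[i] = np.asarray(fm.predict(X[i : i + 1]))[0]
    q2, rmse, press = _q2_from_predictions(y, pred)
    return CVResult(q2, rmse, press, n, float(n - 1), "loo", pred)


def _balanced_folds(n: int, m: int, rng: np.random.Generator) -> list[np.ndarray]:
    """One random partition into m folds whose sizes differ by at most 1."""
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, m)]


def mfold_cv(spec: ModelSpec, X, y, m: int, rng: np.random.Generator) -> CVResult:
    """Leave-many-out via a single random subdivision into m balanced folds.

    The partition is drawn once (never repeated with another subdivision);
    each fold is predicted by a model fitted on the remaining folds.  With
    m = n this is exactly LOO.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if not 2 <= m <= n:
        raise ValueError(f"fold count m={m} must satisfy 2 <= m <= n_train={n}")
    folds = _balanced_folds(n, m, rng)
    pred = np.empty_like(y, dtype=float)
    fitted_sizes = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        fitted_sizes.append(int(mask.sum()))
        fm = fit_model(spec, X[mask], y[mask], rng)
        pred[fold] = fm.predict(X[fold])
    q2, rmse, press = _q2_from_predictions(y, pred)
    return CVResult(
        q2, rmse, press, n, float(np.mean(fitted_sizes)), f"mfold({m})", pred
    )


def grouped_cv(
    spec: ModelSpec,
    X,
    y,
    groups,
    scheme: str = "leave_sample_out",
    rng: np.random.Generator | None = None,
) -> CVResult:
    """Cross-validation honouring replicate groups.

    ``leave_sample_out`` omits entire replicate groups at once, so no
    replicate of a held-out sample remains in the fit.  ``loo_on_group_means``
    first collapses each group to its mean predictor/response row and then
    runs plain LOO on the collapsed set.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    n = X.shape[0]
    uniq = pd.unique(groups)
    if uniq.size < 3:
        raise ValueError("need at least 3 replicate groups")
    if uniq.size == 1 or any((groups == g).sum() == n for g in uniq):
        raise ValueError("a group equal to the whole set cannot be left out")

    if scheme == "loo_on_group_means":
        Xm = np.vstack([X[groups == g].mean(axis=0) for g in uniq])
        ym = np.array([y[groups == g].mean() for g in uniq])
        res = loo_cv(spec, Xm, ym, rng)
        return CVResult(
            res.q2, res.rmse_cv, res.press, res.n_train, res.n_fitted,
            "loo_on_group_means", res.predictions,
        )
    if scheme != "leave_sample_out":
        raise ValueError(f"unknown grouped scheme {scheme!r}")

    rng = rng or np.random.default_rng(0)
    pred = np.empty(n, dtype=float)
    fitted_sizes = []
    for g in uniq:
        mask = groups != g
        fitted_sizes.append(int(mask.sum()))
        fm = fit_model(spec, X[mask], y[mask], rng)
        pred[~mask] = fm.predict(X[~mask])
    q2, rmse, press = _q2_from_predictions(y, pred)
    return CVResult(
        q2, rmse, press, n, float(np.mean(fitted_sizes)), "leave_sample_out", pred
    )


def rescale_to_fitted(curves: pd.DataFrame) -> pd.DataFrame:
    """Overlay LMO curves on the LOO curve using n_fitted as the abscissa.

    ``curves`` needs columns ``scheme``, ``n_fitted`` and ``q2`` (typically
    median Q² per sweep size).  Rows with scheme ``"loo"`` define the
    reference curve; for every other scheme, each point whose n_fitted falls
    inside the LOO n_fitted range is compared against the linearly
    interpolated LOO value.  Returns one row per comparable point with the
    absolute gap; empty if only a LOO curve is supplied.
    """
    required = {"scheme", "n_fitted", "q2"}
    if not required.issubset(curves.columns):
        raise ValueError(f"curves must have columns {sorted(required)}")
    loo = curves[curves["scheme"] == "loo"].sort_values("n_fitted")
    others = curves[curves["scheme"] != "loo"]
    if others.empty:
        return pd.DataFrame(
            columns=["scheme", "n_fitted", "q2", "q2_loo_interp", "gap"]
        )
    if loo.empty:
        raise EmptyOverlapError("no LOO reference curve supplied")
    lo, hi = loo["n_fitted"].min(), loo["n_fitted"].max()
    rows = []
    for scheme, grp in others.groupby("scheme", sort=False):
        inside = grp[(grp["n_fitted"] >= lo) & (grp["n_fitted"] <= hi)]
        for _, r in inside.iterrows():
            interp = float(np.interp(r["n_fitted"], loo["n_fitted"], loo["q2"]))
            rows.append(
                {
                    "scheme": scheme,
                    "n_fitted": float(r["n_fitted"]),
                    "q2": float(r["q2"]),
                    "q2_loo_interp": interp,
                    "gap": abs(float(r["q2"]) - interp),
                }
            )
    if not rows:
        raise EmptyOverlapError("no LMO point falls inside the LOO n_fitted range")
    return pd.DataFrame(rows)
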