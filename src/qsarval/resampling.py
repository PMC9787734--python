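"""Sample-size sweep engine: draw → split → fit → validate, repeated.

The central protocol: for each sample size, draw many random subsets of the
dataset without replacement, split each 80/20 into training and test sets,
fit every configured model on the training part, and record goodness of
fit (R², RMSE on the training set), robustness (Q²_LOO / Q²_LMO and
RMSE_LOO on the training set) and predictivity (Q²_F2, RMSE_test on the
held-out test set).  Medians over the repetitions at a given size form the
learning curves; their sample-size trends carry the study's conclusions.

Splitting is random by default; a deterministic Kennard–Stone max-min
split is available for comparison.  Replicate groups, when present, are
atomic: they are sampled and split as whole units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SweepAbortedError, UnderdeterminedError
from .crossval import loo_cv, mfold_cv
from .metrics import external_validation, goodness_of_fit
from .models import ModelSpec, fit_model

__all__ = [
    "Dataset",
    "SweepResult",
    "draw_sample",
    "random_split",
    "kennard_stone_split",
    "run_sweep",
    "summarize_sweep",
    "standardize_responses",
]

logger = logging.getLogger("qsarval")

#: metrics summarized and rank-correlated downstream
METRIC_COLUMNS = ["r2", "rmse", "q2_loo", "rmse_loo", "q2_f2", "rmse_test"]


@dataclass(frozen=True)
class Dataset:
    """An n×p predictor matrix with n×q responses and optional replicate IDs."""

    X: np.ndarray
    Y: np.ndarray
    groups: np.ndarray | None = None
    x_names: tuple[str, ...] = ()
    y_names: tuple[str, ...] = ()
    name: str = "dataset"
    y_standardized: bool = False

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if Y.ndim == 1:
            Y = Y[:, None]
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("dataset contains non-finite values")
        if not self.x_names:
            object.__setattr__(
                self, "x_names", tuple(f"x{j + 1}" for j in range(X.shape[1]))
            )
        if not self.y_names:
            object.__setattr__(
                self, "y_names", tuple(f"y{j + 1}" for j in range(Y.shape[1]))
            )
        if self.groups is not None:
            g = np.asarray(self.groups)
            if g.shape[0] != X.shape[0]:
                raise ValueError("groups length differs from row count")
            object.__setattr__(self, "groups", g)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    @property
    def y(self) -> np.ndarray:
        """First response column as a 1-D vector."""
        return self.Y[:, 0]

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return replace(
            self,
            X=self.X[idx],
            Y=self.Y[idx],
            groups=None if self.groups is None else self.groups[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {name: self.X[:, j] for j, name in enumerate(self.x_names)}
        data.update({name: self.Y[:, j] for j, name in enumerate(self.y_names)})
        if self.groups is not None:
            data["group"] = self.groups
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        """Write as CSV; %.17g keeps doubles round-trip exact."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def standardize_responses(dataset: Dataset) -> Dataset:
    """Z-score every response column; used when pooling RMSE-like metrics
    across datasets whose responses have different magnitudes."""
    Y = dataset.Y
    sd = Y.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance response cannot be standardized")
    return replace(dataset, Y=(Y - Y.mean(axis=0)) / sd, y_standardized=True)


# ---------------------------------------------------------------------------
# sampling and splitting


def draw_sample(dataset: Dataset, size: int, rng: np.random.Generator) -> Dataset:
    """Uniform random subset without replacement, order randomized.

    With replicate groups present, sampling is by whole groups: shuffled
    groups are added until at least ``size`` rows are reached (the result may
    overshoot by part of one group, never split one).
    """
    if size > dataset.n:
        raise ValueError(f"size {size} exceeds dataset size {dataset.n}")
    if dataset.groups is None:
        idx = rng.choice(dataset.n, size=size, replace=False)
        return dataset.subset(idx)
    uniq = pd.unique(dataset.groups)
    order = rng.permutation(uniq.size)
    picked: list[np.ndarray] = []
    total = 0
    for gi in order:
        rows = np.flatnonzero(dataset.groups == uniq[gi])
        picked.append(rows)
        total += rows.size
        if total >= size:
            break
    return dataset.subset(np.concatenate(picked))


def _train_size(size: int, ratio: float) -> int:
    # round-half-to-even on ratio*size (Python's banker's rounding)
    n_train = int(round(ratio * size))
    return min(max(n_train, 1), size - 1)


def random_split(
    subset: Dataset, ratio: float, rng: np.random.Generator
) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive random train/test split (default ratio 0.8).

    Replicate groups never straddle the boundary: whole groups are assigned
    to the training side until its target size is reached.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = subset.n
    n_train = _train_size(n, ratio)
    if n_train >= n:
        raise ValueError("split leaves an empty test set")
    if subset.groups is None:
        perm = rng.permutation(n)
        return subset.subset(perm[:n_train]), subset.subset(perm[n_train:])
    uniq = pd.unique(subset.groups)
    order = rng.permutation(uniq.size)
    train_rows: list[np.ndarray] = []
    test_rows: list[np.ndarray] = []
    count = 0
    for gi in order:
        rows = np.flatnonzero(subset.groups == uniq[gi])
        if count < n_train:
            train_rows.append(rows)
            count += rows.size
        else:
            test_rows.append(rows)
    if not test_rows:  # every group landed in train; move the last one over
        test_rows.append(train_rows.pop())
    return (
        subset.subset(np.concatenate(train_rows)),
        subset.subset(np.concatenate(test_rows)),
    )


def kennard_stone_split(subset: Dataset, ratio: float) -> tuple[Dataset, Dataset]:
    """Deterministic max-min-distance (Kennard–Stone) train/test split.

    Predictors are standardized internally for the Euclidean distances.  The
    training set is seeded with the two mutually most distant points; each
    further point added is the one maximizing its minimum distance to the
    current training set.  Ties break toward the lowest row index.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = subset.n
    n_train = _train_size(n, ratio)
    X = subset.X
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    # full pairwise squared distances; the sweep sizes keep n modest
    sq = np.sum(Z**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    np.fill_diagonal(d2, -np.inf)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    if d2[i, j] <= 0:
        logger.warning("kennard_stone_split: all pairwise distances are 0; "
                       "selection degenerates to index order")
    train = [min(i, j), max(i, j)]
    np.fill_diagonal(d2, 0.0)
    min_d2 = np.minimum(d2[:, train[0]], d2[:, train[1]])
    in_train = np.zeros(n, dtype=bool)
    in_train[train] = True
    while len(train) < n_train:
        cand = np.where(in_train, -np.inf, min_d2)
        nxt = int(np.argmax(cand))  # argmax takes the lowest index on ties
        train.append(nxt)
        in_train[nxt] = True
        min_d2 = np.minimum(min_d2, d2[:, nxt])
    test = np.flatnonzero(~in_train)
    return subset.subset(np.array(train)), subset.subset(test)


# ---------------------------------------------------------------------------
# the sweep


@dataclass
class SweepResult:
    """All validation records of one sweep plus the configuration that made it."""

    records: pd.DataFrame
    config: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def summarize(self, statistic: str = "median") -> pd.DataFrame:
        return summarize_sweep(self, statistic)


def _rep_rng(seed: int, size_index: int, rep: int) -> np.random.Generator:
    """Independent, order-free child stream per (size, repetition)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(size_index, rep))
    )


def _evaluate_split(
    spec: ModelSpec,
    train: Dataset,
    test: Dataset,
    cv_schemes,
    mfold_ms,
    rng: np.random.Generator,
) -> list[dict]:
    """Fit one spec on one split and compute every configured metric.

    Returns one row per response column (PLS2 models all responses jointly;
    the other families use the first response).
    """
    multi = spec.family == "pls2" and train.q > 1
    Ytr = train.Y if multi else train.y
    fm = fit_model(spec, train.X, Ytr, rng)
    pred_tr = np.atleast_2d(np.asarray(fm.predict(train.X), dtype=float).T).T
    pred_te = np.atleast_2d(np.asarray(fm.predict(test.X), dtype=float).T).T
    if pred_tr.ndim == 1:
        pred_tr = pred_tr[:, None]
    if pred_te.ndim == 1:
        pred_te = pred_te[:, None]

    loo = loo_cv(spec, train.X, Ytr, rng) if "loo" in cv_schemes else None
    lmos = {m: mfold_cv(spec, train.X, Ytr, m, rng) for m in mfold_ms}

    q = train.q if multi else 1
    rows = []
    for j in range(q):
        fit = goodness_of_fit(train.Y[:, j], pred_tr[:, j])
        ext = external_validation(test.Y[:, j], pred_te[:, j])
        row = {
            "response": train.y_names[j],
            "n_train": train.n,
            "n_test": test.n,
            "p_params": fm.p_params,
            "r2": fit.r2,
            "rmse": fit.rmse,
            "q2_f2": ext.q2_f2,
            "rmse_test": ext.rmse_test,
            "q2_loo": np.nan,
            "rmse_loo": np.nan,
            "n_fitted_loo": np.nan,
        }
        if loo is not None:
            q2 = np.atleast_1d(loo.q2)[j if multi else 0]
            rmse = np.atleast_1d(loo.rmse_cv)[j if multi else 0]
            row.update(q2_loo=float(q2), rmse_loo=float(rmse),
                       n_fitted_loo=loo.n_fitted)
        for m, res in lmos.items():
            q2 = np.atleast_1d(res.q2)[j if multi else 0]
            rmse = np.atleast_1d(res.rmse_cv)[j if multi else 0]
            row[f"q2_lmo_m{m}"] = float(q2)
            row[f"rmse_lmo_m{m}"] = float(rmse)
            row[f"n_fitted_m{m}"] = res.n_fitted
        for key in ("n_support_vectors", "sv_fraction", "n_latent", "converged"):
            if key in fm.diagnostics:
                row[key] = fm.diagnostics[key]
        rows.append(row)
    return rows


def run_sweep(
    dataset: Dataset,
    specs: list[ModelSpec],
    sizes: list[int],
    n_repeats: int = 500,
    ratio: float = 0.8,
    split_method: str = "random",
    cv_schemes: tuple[str, ...] = ("loo",),
    mfold_ms: tuple[int, ...] = (),
    transform=None,
    scheme_tag: str = "none",
    seed: int = 0,
    max_failure_fraction: float = 0.5,
) -> SweepResult:
    """The sample-size sweep: draw → (transform) → split → fit → validate.

    ``transform`` is an optional callable ``(subset, rng) -> subset`` applied
    to every drawn sample before splitting (used for the randomization null
    schemes); ``scheme_tag`` labels its records.  Each (size, repetition)
    gets an independent child rng spawned from the master seed, so results
    do not depend on execution order.  Failed fits are logged, not fatal,
    unless more than ``max_failure_fraction`` of the fits at one size fail.
    """
    sizes = list(sizes)
    if any(s > dataset.n for s in sizes):
        raise ValueError("a requested size exceeds the dataset size")
    min_train = _train_size(min(sizes), ratio)
    for spec in specs:
        if spec.family == "mlr" and min_train <= dataset.p + 1:
            raise UnderdeterminedError(
                f"smallest training size {min_train} cannot fit MLR with "
                f"p={dataset.p}"
            )
        if spec.family in ("ann", "svr") and min_train <= dataset.p + 1:
            logger.warning(
                "spec %s may be underdetermined at the smallest training size %d",
                spec.name, min_train,
            )
    rows: list[dict] = []
    failures: list[dict] = []
    for si, size in enumerate(sizes):
        n_fail = 0
        for rep in range(n_repeats):
            rng = _rep_rng(seed, si, rep)
            sub = draw_sample(dataset, size, rng)
            if transform is not None:
                sub = transform(sub, rng)
            if split_method == "random":
                train, test = random_split(sub, ratio, rng)
            elif split_method == "kennard_stone":
                train, test = kennard_stone_split(sub, ratio)
            else:
                raise ValueError(f"unknown split method {split_method!r}")
            for spec in specs:
                try:
                    for row in _evaluate_split(
                        spec, train, test, cv_schemes, mfold_ms, rng
                    ):
                        row.update(
                            dataset=dataset.name,
                            scheme=scheme_tag,
                            family=spec.family,
                            spec=spec.name,
                            size=size,
                            repetition=rep,
                            y_standardized=dataset.y_standardized,
                        )
                        rows.append(row)
                except Exception as exc:
                    n_fail += 1
                    failures.append(
                        {"size": size, "repetition": rep, "spec": spec.name,
                         "scheme": scheme_tag, "error": str(exc)}
                    )
                    logger.warning(
                        "fit failed (size=%d rep=%d spec=%s scheme=%s): %s",
                        size, rep, spec.name, scheme_tag, exc,
                    )
        if n_fail > max_failure_fraction * n_repeats * len(specs):
            raise SweepAbortedError(
                f"{n_fail} of {n_repeats * len(specs)} fits failed at size {size}"
            )
    records = pd.DataFrame(rows)
    config = {
        "dataset": dataset.name,
        "specs": [s.name for s in specs],
        "sizes": sizes,
        "n_repeats": n_repeats,
        "ratio": ratio,
        "split_method": split_method,
        "cv_schemes": list(cv_schemes),
        "mfold_ms": list(mfold_ms),
        "scheme": scheme_tag,
        "seed": seed,
    }
    return SweepResult(records=records, config=config, failures=failures)


def summarize_sweep(sweep: SweepResult, statistic: str = "median") -> pd.DataFrame:
    """Per (dataset, scheme, spec, response, size) summaries of every metric.

    ``statistic`` is one of ``median`` (default, the robust choice), ``mean``
    or ``quartiles`` (q1/median/q3 in long form).
    """
    records = sweep.records
    if records.empty:
        raise ValueError("no records to summarize")
    keys = ["dataset", "scheme", "family", "spec", "response", "size"]
    value_cols = [
        c for c in records.columns
        if c in METRIC_COLUMNS
        or c.startswith(("q2_lmo_m", "rmse_lmo_m", "n_fitted"))
        or c in ("sv_fraction", "n_support_vectors")
    ]
    grouped = records.groupby(keys, sort=True)[value_cols]
    if statistic == "median":
        return grouped.median().reset_index()
    if statistic == "mean":
        return grouped.mean().reset_index()
    if statistic == "quartiles":
        out = grouped.quantile([0.25, 0.5, 0.75]).reset_index()
        return out.rename(columns={f"level_{len(keys)}": "quantile"})
    raise ValueError(f"unknown statistic {statistic!r}")
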