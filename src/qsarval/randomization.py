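"""Chance-correlation null schemes: y-scrambling, y- and x-randomization.

Apparent model performance on information-free data measures chance
correlation.  Three null schemes are provided:

* ``y_scramble`` — a uniform random permutation reassigns the response rows
  to other cases; the response multiset is preserved exactly.
* ``y_random`` — each response is drawn independently from the empirical
  distribution of the true responses (bootstrap by default, or a fitted
  normal).
* ``x_random`` — every predictor cell is drawn independently from its
  column's distribution, destroying both inter-predictor and
  predictor–response correlation.

Randomization is applied to each drawn sample *before* the train/test
split, so both sides of the split are null.
"""

from __future__ import annotations

import numpy as np

from .resampling import Dataset, SweepResult, run_sweep

__all__ = ["SCHEMES", "randomize", "chance_correlation_sweep"]

SCHEMES = ("none", "y_scramble", "y_random", "x_random")


def randomize(
    dataset: Dataset,
    scheme: str,
    rng: np.random.Generator,
    mode: str = "bootstrap",
) -> Dataset:
    """Return a null copy of the dataset under the given scheme.

    ``mode`` selects how y_random / x_random draw from "the distribution of"
    a variable: ``"bootstrap"`` resamples the observed values with
    replacement (distribution-free, the default), ``"normal"`` draws from a
    normal fitted to the column, and for x_random ``"permutation"``
    independently permutes each column (preserving every column multiset
    exactly while still destroying all correlations).
    """
    import dataclasses

    if scheme == "none":
        return dataset
    if scheme == "y_scramble":
        perm = rng.permutation(dataset.n)
        return dataclasses.replace(dataset, Y=dataset.Y[perm])
    if scheme == "y_random":
        Y = np.empty_like(dataset.Y)
        for j in range(dataset.q):
            col = dataset.Y[:, j]
            if mode == "normal":
                Y[:, j] = rng.normal(col.mean(), col.std(), size=dataset.n)
            else:
                Y[:, j] = rng.choice(col, size=dataset.n, replace=True)
        return dataclasses.replace(dataset, Y=Y)
    if scheme == "x_random":
        X = np.empty_like(dataset.X)
        for j in range(dataset.p):
            col = dataset.X[:, j]
            if mode == "normal":
                X[:, j] = rng.normal(col.mean(), col.std(), size=dataset.n)
            elif mode == "permutation":
                X[:, j] = col[rng.permutation(dataset.n)]
            else:
                X[:, j] = rng.choice(col, size=dataset.n, replace=True)
        return dataclasses.replace(dataset, X=X)
    raise ValueError(f"unknown randomization scheme {scheme!r}")


def chance_correlation_sweep(
    dataset: Dataset,
    specs,
    sizes,
    n_repeats: int = 500,
    schemes: tuple[str, ...] = ("y_scramble",),
    mode: str = "bootstrap",
    seed: int = 0,
    **sweep_kwargs,
) -> SweepResult:
    """The sample-size sweep on randomized (null) data, one run per scheme.

    Each drawn sample is randomized before splitting, so training R² on the
    null measures chance correlation and test-set Q²_F2 measures spurious
    generalization.  Records are tagged with the scheme; schemes share the
    seed tree, so scheme ``"none"`` reproduces a plain sweep exactly.
    """
    results = []
    config = None
    failures: list = []
    for scheme in schemes:
        if scheme not in SCHEMES:
            raise ValueError(f"unknown randomization scheme {scheme!r}")
        transform = (
            None
            if scheme == "none"
            else (lambda sub, rng, s=scheme: randomize(sub, s, rng, mode))
        )
        res = run_sweep(
            dataset,
            specs,
            sizes,
            n_repeats=n_repeats,
            transform=transform,
            scheme_tag=scheme,
            seed=seed,
            **sweep_kwargs,
        )
        results.append(res.records)
        failures.extend(res.failures)
        config = res.config
    import pandas as pd

    config = dict(config or {})
    config["schemes"] = list(schemes)
    config["randomization_mode"] = mode
    return SweepResult(
        records=pd.concat(results, ignore_index=True),
        config=config,
        failures=failures,
    )
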