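"""Study orchestration: config, dataset I/O, full runs, artifact export.

A study is described by one declarative config (YAML or a dict): a dataset
source (CSV or synthetic), model specs, the size series, repetition count,
split and cross-validation settings, optional randomization null schemes,
and a master seed.  ``run_study`` executes the whole protocol — sweep,
null sweeps, LOO/LMO overlay, summaries and rank correlations — and writes
flat CSV artifacts plus a JSON manifest that (together with the package
version) fully determines every output byte.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import rescale_to_fitted
from .models import ModelSpec, ann_spec, mlr_spec, pls2_spec, svr_spec
from .randomization import SCHEMES, chance_correlation_sweep
from .rankcorr import intraclass_rank_curves, overall_rank_table, rank_table_wide
from .resampling import (
    Dataset,
    SweepResult,
    run_sweep,
    standardize_responses,
    summarize_sweep,
)
from .synthetic import SyntheticConfig, make_dataset

__all__ = ["StudyConfig", "load_csv_dataset", "build_dataset", "run_study"]

logger = logging.getLogger("qsarval")


def load_csv_dataset(
    path,
    predictors: list[str],
    responses: list[str],
    group: str | None = None,
    categorical: list[str] | None = None,
    name: str | None = None,
) -> Dataset:
    """Load a numeric CSV table into a :class:`Dataset`.

    Declared categorical predictor columns are one-hot encoded (one 0/1
    column per level).  Rows with missing values in any used column are
    dropped and the count is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    categorical = categorical or []
    used = list(predictors) + list(responses) + ([group] if group else [])
    missing_cols = [c for c in used if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path.name}: {missing_cols}")
    sub = df[used]
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.info("dropped %d rows with missing values from %s", n_dropped, path.name)
    if sub.empty:
        raise ValueError(f"no complete rows left in {path.name}")

    x_parts = []
    x_names: list[str] = []
    for col in predictors:
        if col in categorical:
            dummies = pd.get_dummies(sub[col], prefix=col, dtype=float)
            x_parts.append(dummies.to_numpy())
            x_names.extend(dummies.columns)
        else:
            vals = pd.to_numeric(sub[col], errors="coerce")
            if vals.isna().any():
                row = int(vals.index[vals.isna()][0])
                raise ValueError(
                    f"non-numeric cell in column {col!r} at row {row} of {path.name}"
                )
            x_parts.append(vals.to_numpy(dtype=float)[:, None])
            x_names.append(col)
    X = np.hstack(x_parts)
    Y = sub[list(responses)].apply(pd.to_numeric).to_numpy(dtype=float)
    groups = sub[group].to_numpy() if group else None
    return Dataset(
        X=X,
        Y=Y,
        groups=groups,
        x_names=tuple(x_names),
        y_names=tuple(responses),
        name=name or path.stem,
    )


_SPEC_BUILDERS = {
    "mlr": lambda params: mlr_spec(),
    "pls2": lambda params: pls2_spec(**params),
    "ann": lambda params: ann_spec(**params),
    "svr": lambda params: svr_spec(**params),
}


def _spec_from_dict(d: dict) -> ModelSpec:
    family = d["family"]
    if family not in _SPEC_BUILDERS:
        raise ValueError(f"unknown model family {family!r}")
    return _SPEC_BUILDERS[family](dict(d.get("params", {})))


@dataclass
class StudyConfig:
    """Declarative description of one study run."""

    dataset: dict
    models: list[dict]
    sizes: list[int]
    n_repeats: int = 500
    split_ratio: float = 0.8
    split_method: str = "random"
    cv_loo: bool = True
    mfold_ms: list[int] = field(default_factory=list)
    randomization: list[str] = field(default_factory=list)
    randomization_mode: str = "bootstrap"
    standardize_responses: bool = False
    summary_statistic: str = "median"
    seed: int = 0
    out_dir: str = "study_out"

    def __post_init__(self):
        if sorted(self.sizes) != list(self.sizes):
            raise ValueError("sizes must be sorted ascending")
        if self.split_method not in ("random", "kennard_stone"):
            raise ValueError(f"unknown split method {self.split_method!r}")
        for s in self.randomization:
            if s not in SCHEMES:
                raise ValueError(f"unknown randomization scheme {s!r}")
        if not self.models:
            raise ValueError("at least one model spec is required")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def specs(self) -> list[ModelSpec]:
        return [_spec_from_dict(d) for d in self.models]


def build_dataset(source: dict) -> Dataset:
    """Materialize the dataset a config refers to (CSV path or synthetic)."""
    if "csv" in source:
        kw = {k: source[k] for k in ("group", "categorical", "name") if k in source}
        return load_csv_dataset(
            source["csv"], source["predictors"], source["responses"], **kw
        )
    if "synthetic" in source:
        dataset, _ = make_dataset(SyntheticConfig(**source["synthetic"]))
        return dataset
    raise ValueError("dataset source must contain a 'csv' path or a 'synthetic' block")


def run_study(config: StudyConfig) -> dict:
    """Execute a full study and write its artifacts.

    Writes under ``config.out_dir``: ``records.csv`` (one row per fitted
    model and response), ``summary.csv``, ``rank_overall.csv`` (+ a wide
    pair-by-family variant), ``rank_intraclass.csv``, ``overlay_gap.csv``
    (LOO/LMO overlay gaps, when both schemes are configured) and
    ``manifest.json``.  Returns a mapping of artifact names to paths plus a
    ``status`` key (``ok`` or ``partial`` when some fits failed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = build_dataset(config.dataset)
    if config.standardize_responses:
        dataset = standardize_responses(dataset)
    specs = config.specs()
    cv_schemes = ("loo",) if config.cv_loo else ()
    common = dict(
        sizes=config.sizes,
        n_repeats=config.n_repeats,
        ratio=config.split_ratio,
        split_method=config.split_method,
        cv_schemes=cv_schemes,
        mfold_ms=tuple(config.mfold_ms),
        seed=config.seed,
    )
    sweep = run_sweep(dataset, specs, **common)
    failures = list(sweep.failures)
    records = [sweep.records]
    null_schemes = [s for s in config.randomization if s != "none"]
    if null_schemes:
        null = chance_correlation_sweep(
            dataset, specs,
            schemes=tuple(null_schemes),
            mode=config.randomization_mode,
            **common,
        )
        records.append(null.records)
        failures.extend(null.failures)
    all_records = pd.concat(records, ignore_index=True)
    combined = SweepResult(records=all_records, config=sweep.config, failures=failures)

    artifacts: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False)
        artifacts[name] = str(path)

    _write("records.csv", all_records)
    summary = summarize_sweep(combined, config.summary_statistic)
    _write("summary.csv", summary)

    plain = combined.records[combined.records["scheme"] == "none"]
    rank_overall = overall_rank_table(
        plain, rmse_standardized=config.standardize_responses
    )
    _write("rank_overall.csv", rank_overall)
    rank_table_wide(rank_overall).to_csv(out / "rank_overall_wide.csv")
    artifacts["rank_overall_wide.csv"] = str(out / "rank_overall_wide.csv")
    _write("rank_intraclass.csv", intraclass_rank_curves(combined))

    if config.cv_loo and config.mfold_ms:
        med = summarize_sweep(SweepResult(records=plain), "median")
        curves = [
            med[["n_fitted_loo", "q2_loo"]]
            .rename(columns={"n_fitted_loo": "n_fitted", "q2_loo": "q2"})
            .assign(scheme="loo")
        ]
        for m in config.mfold_ms:
            curves.append(
                med[[f"n_fitted_m{m}", f"q2_lmo_m{m}"]]
                .rename(columns={f"n_fitted_m{m}": "n_fitted", f"q2_lmo_m{m}": "q2"})
                .assign(scheme=f"mfold({m})")
            )
        try:
            _write("overlay_gap.csv", rescale_to_fitted(pd.concat(curves)))
        except Exception as exc:
            logger.warning("overlay computation skipped: %s", exc)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "n_records": int(len(all_records)),
        "n_failures": len(failures),
        "versions": {
            "qsarval": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    artifacts["manifest.json"] = str(out / "manifest.json")
    artifacts["status"] = "partial" if failures else "ok"
    return artifacts
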