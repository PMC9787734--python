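"""Spearman rank correlations between validation parameters.

Rank correlation emphasizes the monotone (not necessarily linear) relation
between two validation parameters.  Two pooling levels are used:

* overall — one rho per metric pair per model family, pooled over every
  record (all datasets, sizes and hyperparameters); when pooling across
  datasets the RMSE-like metrics must be computed on standardized responses
  so their magnitudes are comparable;
* intra-class — rho across the repeated models of one class, where a class
  is one (dataset, model spec, sample size) cell; plotted against sample
  size these curves expose the allocation effect near full dataset size.

The full pair set is the 15 unordered pairs over the six metrics
{R², RMSE, Q²_LOO, RMSE_LOO, Q²_F2, RMSE_test}.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError
from .resampling import METRIC_COLUMNS, SweepResult

__all__ = ["spearman", "metric_pairs", "overall_rank_table", "intraclass_rank_curves"]


def spearman(a, b) -> float:
    """Spearman rho: Pearson correlation of average-ranked vectors.

    Ties receive average ranks.  Raises if either vector has zero rank
    variance (constant input), where the correlation is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise UndefinedCorrelationError("constant vector: rank variance is zero")
    return float(stats.spearmanr(a, b).statistic)


def metric_pairs(metrics=tuple(METRIC_COLUMNS)) -> list[tuple[str, str]]:
    """All unordered metric pairs (15 for the default six metrics)."""
    return list(combinations(metrics, 2))


def overall_rank_table(
    records: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    rmse_standardized: bool = False,
) -> pd.DataFrame:
    """Pooled rank correlations, one rho per metric pair per model family.

    ``records`` is the flat record table of one or more sweeps.  When it
    pools several datasets, ``rmse_standardized`` must be set and every
    record must come from standardized responses, otherwise the RMSE-like
    entries would mix incomparable units.
    """
    pairs = pairs or metric_pairs()
    if records.empty:
        raise ValueError("no records")
    n_datasets = records["dataset"].nunique() if "dataset" in records else 1
    if n_datasets > 1:
        if not rmse_standardized:
            raise ValueError(
                "pooling across datasets requires standardized responses "
                "(rmse_standardized=True)"
            )
        if "y_standardized" in records and not records["y_standardized"].all():
            raise ValueError(
                "records mix standardized and unstandardized responses"
            )
    rows = []
    for family, grp in records.groupby("family", sort=True):
        for a, b in pairs:
            sub = grp[[a, b]].dropna()
            rows.append(
                {
                    "family": family,
                    "metric_a": a,
                    "metric_b": b,
                    "rho": spearman(sub[a].to_numpy(), sub[b].to_numpy()),
                    "n_models": len(sub),
                }
            )
    return pd.DataFrame(rows)


def rank_table_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot an overall rank table to pair-by-family form for export."""
    t = table.assign(pair=table["metric_a"] + "/" + table["metric_b"])
    return t.pivot(index="pair", columns="family", values="rho")


def intraclass_rank_curves(
    sweep: SweepResult,
    pairs: list[tuple[str, str]] | None = None,
    min_repeats: int = 3,
) -> pd.DataFrame:
    """Rank correlations across the repeated models of each class.

    A class is one (dataset, scheme, spec, response, size) cell; rho is
    computed across its repetitions for every metric pair.  Degenerate
    classes (a metric constant across repetitions) are flagged with
    ``degenerate=True`` and rho = NaN rather than dropped.
    """
    pairs = pairs or metric_pairs()
    records = sweep.records
    keys = ["dataset", "scheme", "family", "spec", "response", "size"]
    rows = []
    for key, grp in records.groupby(keys, sort=True):
        for a, b in pairs:
            sub = grp[[a, b]].dropna()
            row = dict(zip(keys, key))
            row.update(metric_a=a, metric_b=b, n_models=len(sub))
            if len(sub) < min_repeats:
                continue
            try:
                row.update(rho=spearman(sub[a].to_numpy(), sub[b].to_numpy()),
                           degenerate=False)
            except UndefinedCorrelationError:
                row.update(rho=np.nan, degenerate=True)
            rows.append(row)
    return pd.DataFrame(rows)
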