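"""Sample/feature QC statistics, filters and exploratory summaries.

Dropout rate (fraction of zero entries per sample) and detected-feature
counts are the workhorse single-cell QC quantities; filters act either on
explicit ID lists or on expression/quality criteria and are recorded as
replayable operations on the data map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .matrix import ExpressionMatrix
from .normalize import SizeFactors

__all__ = [
    "FilterCriteria",
    "sample_qc_stats",
    "filter_features",
    "filter_samples",
    "rank_frequency",
    "mean_variability",
    "feature_query",
]

logger = logging.getLogger(__name__)


def sample_qc_stats(
    matrix: ExpressionMatrix, sf: SizeFactors | None = None
) -> pd.DataFrame:
    """Per-sample totals, detected features, dropout rate, optional size factor.

    ``detected_features + zero_count == n_features`` and
    ``dropout_rate = zero_count / n_features`` for every sample.
    """
    counts = matrix.values.to_numpy()
    detected = (counts > 0).sum(axis=0)
    nf = matrix.n_features
    stats = pd.DataFrame(
        {
            "total_counts": counts.sum(axis=0),
            "detected_features": detected,
            "dropout_rate": (nf - detected) / nf if nf else np.nan,
        },
        index=pd.Index(matrix.sample_ids, name="sample"),
    )
    if sf is not None:
        stats["size_factor"] = sf.for_samples(matrix.sample_ids)
    return stats


@dataclass
class FilterCriteria:
    """Feature- and sample-side filtering thresholds and ID lists.

    Feature side: minimum mean expression, a count threshold ``min_count``
    required in at least ``min_samples`` samples, and keep/drop lists (the
    keep list overrides expression criteria).  Sample side: ranges on total
    counts, detected features, dropout rate and size factor, plus explicit
    keep/drop lists.  Unknown IDs in lists are ignored with a warning.
    """

    # feature side
    min_mean_expr: float | None = None
    min_count: float | None = None
    min_samples: int = 1
    feature_keep_list: list[str] | None = None
    feature_drop_list: list[str] | None = None
    # sample side
    total_range: tuple[float, float] | None = None
    detected_range: tuple[float, float] | None = None
    dropout_max: float | None = None
    size_factor_range: tuple[float, float] | None = None
    sample_keep_list: list[str] | None = None
    sample_drop_list: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("total_range", "detected_range", "size_factor_range"):
            rng = getattr(self, name)
            if rng is not None:
                lo, hi = rng
                if lo > hi:
                    raise ValueError(f"{name} is not well ordered: {rng}")

    def to_params(self) -> dict:
        out: dict = {}
        for key, value in self.__dict__.items():
            if value is None:
                continue
            out[key] = list(value) if isinstance(value, tuple) else value
        return out

    @classmethod
    def from_params(cls, params: dict) -> "FilterCriteria":
        kwargs = dict(params)
        for name in ("total_range", "detected_range", "size_factor_range"):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)


def _known(ids: list[str] | None, universe: set[str], what: str) -> set[str]:
    if not ids:
        return set()
    unknown = [x for x in ids if x not in universe]
    if unknown:
        logger.warning("%d unknown %s ID(s) ignored (e.g. %r)", len(unknown), what, unknown[0])
    return {x for x in ids if x in universe}


def filter_features(
    matrix: ExpressionMatrix, criteria: FilterCriteria
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop features failing any active criterion; returns (survivors, removed).

    The keep list overrides expression criteria; the drop list always wins.
    The sample set is never touched.
    """
    counts = matrix.values.to_numpy()
    universe = set(matrix.feature_ids)
    keep_list = _known(criteria.feature_keep_list, universe, "feature")
    drop_list = _known(criteria.feature_drop_list, universe, "feature")

    passing = np.ones(matrix.n_features, dtype=bool)
    if criteria.min_mean_expr is not None:
        passing &= counts.mean(axis=1) >= criteria.min_mean_expr
    if criteria.min_count is not None:
        passing &= (counts >= criteria.min_count).sum(axis=1) >= criteria.min_samples
    kept = [
        f
        for f, ok in zip(matrix.feature_ids, passing)
        if (ok or f in keep_list) and f not in drop_list
    ]
    if not kept:
        raise ValueError("all features removed by the filter")
    removed = [f for f in matrix.feature_ids if f not in set(kept)]
    return matrix.subset(feature_ids=kept), removed


def filter_samples(
    matrix: ExpressionMatrix,
    criteria: FilterCriteria,
    qc: pd.DataFrame,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples outside any active QC range; feature set unchanged.

    ``qc`` must be the :func:`sample_qc_stats` table of this same matrix
    (with a ``size_factor`` column when a size-factor range is active).
    """
    if list(qc.index) != matrix.sample_ids:
        raise ValueError("QC table was not computed on this matrix")
    universe = set(matrix.sample_ids)
    keep_list = _known(criteria.sample_keep_list, universe, "sample")
    drop_list = _known(criteria.sample_drop_list, universe, "sample")

    passing = pd.Series(True, index=qc.index)
    if criteria.total_range is not None:
        lo, hi = criteria.total_range
        passing &= qc["total_counts"].between(lo, hi)
    if criteria.detected_range is not None:
        lo, hi = criteria.detected_range
        passing &= qc["detected_features"].between(lo, hi)
    if criteria.dropout_max is not None:
        passing &= qc["dropout_rate"] <= criteria.dropout_max
    if criteria.size_factor_range is not None:
        if "size_factor" not in qc.columns:
            raise ValueError("size-factor range given but QC table has no size_factor")
        lo, hi = criteria.size_factor_range
        passing &= qc["size_factor"].between(lo, hi)
    kept = [
        s
        for s in matrix.sample_ids
        if (passing[s] or s in keep_list) and s not in drop_list
    ]
    if not kept:
        raise ValueError("all samples removed by the filter")
    removed = [s for s in matrix.sample_ids if s not in set(kept)]
    return matrix.subset(sample_ids=kept), removed


def rank_frequency(matrix: ExpressionMatrix, sample_id: str) -> pd.DataFrame:
    """Rank-frequency table for one sample's positive counts.

    Counts are sorted descending (ties keep descending order with ranks
    assigned sequentially); frequency = count / total, so frequencies sum
    to 1.
    """
    if sample_id not in matrix.values.columns:
        raise KeyError(f"unknown sample ID {sample_id!r}")
    col = matrix.values[sample_id].to_numpy()
    total = col.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id!r} has no positive counts")
    positive = np.sort(col[col > 0])[::-1]
    return pd.DataFrame(
        {"rank": np.arange(1, positive.size + 1), "frequency": positive / total}
    )


def mean_variability(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature mean, sample SD (n-1 denominator) and CV of the values.

    CV is omitted (NaN) where the mean is zero.  Row order is preserved.
    """
    if matrix.n_samples < 2:
        raise ValueError("mean-variability needs at least 2 samples")
    vals = matrix.values.to_numpy()
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"feature_id": matrix.feature_ids, "mean": mean, "sd": sd, "cv": cv}
    )


def feature_query(
    matrix: ExpressionMatrix,
    target: str,
    method: Literal["pearson", "spearman"] = "pearson",
    top_n: int = 20,
) -> pd.DataFrame:
    """Features ranked by expression-profile correlation with a target feature.

    The target itself is excluded; constant features are skipped with a
    logged warning (their correlation is undefined).
    """
    if target not in matrix.values.index:
        raise KeyError(f"unknown feature ID {target!r}")
    tvec = matrix.values.loc[target].to_numpy()
    if np.ptp(tvec) == 0:
        raise ValueError(f"target feature {target!r} is constant")
    corr_fn = pearsonr if method == "pearson" else spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    rows = []
    n_constant = 0
    for fid in matrix.feature_ids:
        if fid == target:
            continue
        vec = matrix.values.loc[fid].to_numpy()
        if np.ptp(vec) == 0:
            n_constant += 1
            continue
        rows.append((fid, float(corr_fn(tvec, vec)[0])))
    if n_constant:
        logger.warning("%d constant feature(s) skipped in feature_query", n_constant)
    table = pd.DataFrame(rows, columns=["feature_id", "correlation"])
    table = table.sort_values(
        ["correlation", "feature_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return table.head(top_n)
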