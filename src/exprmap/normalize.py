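"""Size-factor and per-value normalization for count matrices.

Implements the classic between-sample scaling estimators used for RNA-seq —
median-of-ratios (with a configurable detection threshold so it stays
defined on sparse single-cell matrices), trimmed mean of M-values (TMM),
upper-quartile and spike-in-based factors — plus per-value CPM/RPKM/TPM and
quantile normalization.

Conventions
-----------
* All size factors are rescaled to geometric mean 1 so methods are directly
  comparable across samples; ``SizeFactors.raw`` keeps the pre-rescaling
  values (library-size-like quantities) for diagnostics.
* Normalized value = count / size factor; optionally ``log2(x + pseudocount)``.
* Percentiles use linear interpolation (type-7).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix, GeneLengths, SpikePartition, detect_spike_ins
from .records import OperationRecord

__all__ = [
    "SizeFactors",
    "NormalizationResult",
    "size_factors_median_ratio",
    "size_factors_tmm",
    "size_factors_upper_quartile",
    "size_factors_spike_in",
    "normalize_per_value",
    "quantile_normalize",
    "apply_size_factors",
    "normalize_matrix",
]


@dataclass
class SizeFactors:
    """Per-sample scaling factors with the method record that produced them.

    ``factors`` has geometric mean 1 (enforced); ``raw`` holds the
    pre-rescaling per-sample values, on which scaling equivariance holds
    exactly (multiplying a column by c multiplies its raw factor by c).
    """

    factors: pd.Series
    method: str
    params: dict
    raw: pd.Series | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(f)) or (f <= 0).any():
            raise ValueError("size factors must be positive and finite")
        gm = float(np.exp(np.mean(np.log(f))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"size factors must have geometric mean 1, got {gm}")

    def for_samples(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.factors.index]
        if missing:
            raise ValueError(f"no size factor for sample {missing[0]!r}")
        return self.factors.loc[sample_ids].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.factors.index, "size_factor": self.factors.to_numpy()})


@dataclass
class NormalizationResult:
    """Normalized matrix plus the size factors (when factor-based) and the
    replayable operation record."""

    matrix: ExpressionMatrix
    op: OperationRecord
    size_factors: SizeFactors | None = None


def _rescaled(raw: pd.Series, method: str, params: dict) -> SizeFactors:
    gm = np.exp(np.mean(np.log(raw.to_numpy())))
    return SizeFactors(raw / gm, method=method, params=params, raw=raw)


def size_factors_median_ratio(
    matrix: ExpressionMatrix, min_detect_frac: float = 1.0
) -> SizeFactors:
    """Median-of-ratios size factors with a tunable inclusion criterion.

    A feature enters the reference if it has positive counts in at least
    ``ceil(min_detect_frac * n_samples)`` samples.  Its reference value is
    the geometric mean of its *positive* counts, and each sample's raw
    factor is the median of that sample's positive count-to-reference
    ratios.  With ``min_detect_frac=1`` on a zero-free matrix this is
    exactly the classic median-of-ratios estimator.
    """
    if not (0 < min_detect_frac <= 1):
        raise ValueError("min_detect_frac must be in (0, 1]")
    if matrix.n_samples < 2:
        raise ValueError("median-of-ratios needs at least 2 samples")
    counts = matrix.values.to_numpy()
    m = matrix.n_samples
    pos = counts > 0
    need = math.ceil(min_detect_frac * m)
    include = pos.sum(axis=1) >= need
    if not include.any():
        raise ValueError(
            f"no feature has positive counts in >= {need} samples; "
            "lower min_detect_frac"
        )
    sub = counts[include]
    sub_pos = pos[include]
    with np.errstate(divide="ignore"):
        logs = np.where(sub_pos, np.log(np.where(sub_pos, sub, 1.0)), 0.0)
    ref = np.exp(logs.sum(axis=1) / sub_pos.sum(axis=1))  # geomean of positives
    raw = np.empty(m)
    for j, sample in enumerate(matrix.sample_ids):
        eligible = sub_pos[:, j]
        if not eligible.any():
            raise ValueError(f"sample {sample!r} has no eligible ratios")
        raw[j] = np.median(sub[eligible, j] / ref[eligible])
    series = pd.Series(raw, index=matrix.sample_ids)
    return _rescaled(series, "median_ratio", {"min_detect_frac": min_detect_frac})


def _upper_quartile_positive(col: np.ndarray) -> float:
    positive = col[col > 0]
    if positive.size == 0:
        return np.nan
    return float(np.percentile(positive, 75))  # linear (type-7)


def size_factors_tmm(
    matrix: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> SizeFactors:
    """Trimmed-mean-of-M-values size factors.

    The reference sample is the one whose upper quartile of positive counts
    is closest to the mean upper quartile.  For each sample, log ratios
    (M) and average log abundances (A) against the reference are computed
    over features positive in both samples, the top and bottom ``trim_m``
    fraction by M and ``trim_a`` fraction by A are dropped, and the TMM
    component is two to the precision-weighted mean of the surviving M
    values.  Raw factor = TMM component x library size; when fewer than 10
    features survive trimming a warning is issued and the untrimmed
    weighted mean is used.
    """
    if matrix.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = matrix.values.to_numpy()
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = matrix.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero total counts")
    uq = np.array([_upper_quartile_positive(counts[:, j]) for j in range(matrix.n_samples)])
    if np.isnan(uq).any():
        bad = matrix.sample_ids[int(np.where(np.isnan(uq))[0][0])]
        raise ValueError(f"sample {bad!r} has no positive counts")
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    kr, nr = counts[:, ref], lib[ref]

    tmm = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        if j == ref:
            tmm[j] = 1.0
            continue
        kg, ng = counts[:, j], lib[j]
        both = (kg > 0) & (kr > 0)
        pg, pr = kg[both] / ng, kr[both] / nr
        m_vals = np.log2(pg / pr)
        a_vals = 0.5 * np.log2(pg * pr)
        w = 1.0 / ((ng - kg[both]) / (ng * kg[both]) + (nr - kr[both]) / (nr * kr[both]))
        n = m_vals.size
        rank_m = rankdata(m_vals)  # average ranks, as in the usual convention
        rank_a = rankdata(a_vals)
        keep = (
            (rank_m >= n * trim_m + 1)
            & (rank_m <= n * (1 - trim_m))
            & (rank_a >= n * trim_a + 1)
            & (rank_a <= n * (1 - trim_a))
        )
        if keep.sum() < 10:
            warnings.warn(
                f"fewer than 10 features survive TMM trimming for sample "
                f"{matrix.sample_ids[j]!r}; using untrimmed weighted mean",
                stacklevel=2,
            )
            keep = np.ones(n, dtype=bool)
        tmm[j] = 2.0 ** (np.sum(w[keep] * m_vals[keep]) / np.sum(w[keep]))

    raw = pd.Series(tmm * lib, index=matrix.sample_ids)
    params = {
        "trim_m": trim_m,
        "trim_a": trim_a,
        "tmm_component": dict(zip(matrix.sample_ids, tmm.tolist())),
        "reference_sample": matrix.sample_ids[ref],
    }
    return _rescaled(raw, "tmm", params)


def size_factors_upper_quartile(matrix: ExpressionMatrix) -> SizeFactors:
    """Raw factor = 75th percentile of each sample's positive counts."""
    counts = matrix.values.to_numpy()
    raw = np.empty(matrix.n_samples)
    for j, sample in enumerate(matrix.sample_ids):
        q = _upper_quartile_positive(counts[:, j])
        if np.isnan(q):
            raise ValueError(f"sample {sample!r} has no positive counts")
        raw[j] = q
    return _rescaled(pd.Series(raw, index=matrix.sample_ids), "upper_quartile", {})


def size_factors_spike_in(
    matrix: ExpressionMatrix, partition: SpikePartition
) -> SizeFactors:
    """Median-of-ratios factors computed on the spike-in submatrix only.

    Spike-ins are present at identical nominal amounts in every sample, so
    their ratios isolate the technical depth component; the factors are then
    applied to the full matrix downstream.
    """
    if len(partition.spike_feature_ids) < 2:
        raise ValueError(
            f"need >= 2 spike-in features, got {len(partition.spike_feature_ids)}"
        )
    sub = matrix.subset(feature_ids=partition.spike_feature_ids)
    sf = size_factors_median_ratio(sub, min_detect_frac=1.0)
    params = {"n_spikes": len(partition.spike_feature_ids)}
    return SizeFactors(sf.factors, method="spike_in", params=params, raw=sf.raw)


def normalize_per_value(
    matrix: ExpressionMatrix,
    mode: Literal["cpm", "rpkm", "tpm"],
    lengths: GeneLengths | None = None,
) -> NormalizationResult:
    """Counts/reads/transcripts-per-million scaling.

    cpm = k * 1e6 / N_j;  rpkm = k * 1e9 / (N_j * L_i);
    tpm_i = 1e6 * (k_i/L_i) / sum_v (k_v/L_v).  CPM and TPM columns sum to
    1e6 by construction.
    """
    counts = matrix.values.to_numpy()
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = matrix.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero total counts")
    params: dict = {"method": mode}
    if mode == "cpm":
        out = counts * 1e6 / lib
    elif mode in ("rpkm", "tpm"):
        if lengths is None:
            raise ValueError(f"{mode} requires gene lengths")
        L = lengths.for_features(matrix.feature_ids)
        params["lengths"] = dict(zip(matrix.feature_ids, L.tolist()))
        if mode == "rpkm":
            out = counts * 1e9 / (lib * L[:, None])
        else:
            rate = counts / L[:, None]
            out = rate * 1e6 / rate.sum(axis=0)
    else:
        raise ValueError(f"unknown per-value mode {mode!r}")
    norm = ExpressionMatrix(
        pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.sample_ids),
        kind="normalized",
    )
    return NormalizationResult(norm, OperationRecord("normalize", params))


def quantile_normalize(matrix: ExpressionMatrix) -> NormalizationResult:
    """Classic rank-mean quantile normalization.

    Each column is sorted, values are averaged across columns at each rank,
    and the averages are mapped back through each column's original ranks;
    tied values within a column receive the mean of their rank-means.
    Afterwards all columns share the same sorted values (exactly so when
    the input is tie-free).
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = matrix.values.to_numpy()
    rank_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr, dtype=float)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        mapped = rank_means[rankdata(col, method="ordinal") - 1]
        out[:, j] = pd.Series(mapped).groupby(pd.Series(col), sort=False).transform("mean").to_numpy()
    norm = ExpressionMatrix(
        pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.sample_ids),
        kind="normalized",
    )
    return NormalizationResult(norm, OperationRecord("normalize", {"method": "quantile"}))


def apply_size_factors(
    matrix: ExpressionMatrix,
    sf: SizeFactors,
    log: bool = False,
    pseudocount: float = 1.0,
) -> NormalizationResult:
    """Divide each column by its size factor; optionally log2(x + pseudocount)."""
    factors = sf.for_samples(matrix.sample_ids)
    out = matrix.values.to_numpy() / factors
    kind = "normalized"
    if log:
        out = np.log2(out + pseudocount)
        kind = "log_normalized"
    norm = ExpressionMatrix(
        pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.sample_ids),
        kind=kind,
    )
    op = OperationRecord(
        "normalize",
        {"method": sf.method, "log": log, "pseudocount": pseudocount, **sf.params},
    )
    return NormalizationResult(norm, op, size_factors=sf)


def normalize_matrix(
    matrix: ExpressionMatrix,
    method: str,
    *,
    min_detect_frac: float = 1.0,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    spike_prefix: str = "ERCC-",
    lengths: GeneLengths | None = None,
    log: bool = False,
    pseudocount: float = 1.0,
) -> NormalizationResult:
    """Dispatch on the method name; the returned op record replays exactly.

    Factor-based methods (``median_ratio``, ``tmm``, ``upper_quartile``,
    ``spike_in``) estimate size factors and divide; ``cpm``/``rpkm``/``tpm``
    and ``quantile`` rewrite values directly.
    """
    if method == "median_ratio":
        sf = size_factors_median_ratio(matrix, min_detect_frac)
        sf = SizeFactors(sf.factors, sf.method, {"min_detect_frac": min_detect_frac}, sf.raw)
        return apply_size_factors(matrix, sf, log=log, pseudocount=pseudocount)
    if method == "tmm":
        sf = size_factors_tmm(matrix, trim_m=trim_m, trim_a=trim_a)
        slim = SizeFactors(sf.factors, sf.method, {"trim_m": trim_m, "trim_a": trim_a}, sf.raw)
        return apply_size_factors(matrix, slim, log=log, pseudocount=pseudocount)
    if method == "upper_quartile":
        sf = size_factors_upper_quartile(matrix)
        return apply_size_factors(matrix, sf, log=log, pseudocount=pseudocount)
    if method == "spike_in":
        partition = detect_spike_ins(matrix, prefix=spike_prefix)
        sf = size_factors_spike_in(matrix, partition)
        sf = SizeFactors(sf.factors, sf.method, {"spike_prefix": spike_prefix}, sf.raw)
        return apply_size_factors(matrix, sf, log=log, pseudocount=pseudocount)
    if method in ("cpm", "rpkm", "tpm"):
        result = normalize_per_value(matrix, method, lengths=lengths)  # type: ignore[arg-type]
        if log:
            logged = np.log2(result.matrix.values + pseudocount)
            result = NormalizationResult(
                ExpressionMatrix(logged, kind="log_normalized"),
                OperationRecord(
                    "normalize",
                    {**result.op.params, "log": True, "pseudocount": pseudocount},
                ),
            )
        return result
    if method == "quantile":
        return quantile_normalize(matrix)
    raise ValueError(f"unknown normalization method {method!r}")
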