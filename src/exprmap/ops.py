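"""Replay of recorded derivation operations.

Every data-map edge carries an :class:`~exprmap.records.OperationRecord`;
this module maps a record plus the parent matrices back onto the
deterministic transformation that produced the child, which makes full
lineage replay (root matrix → any node) possible and testable.
"""

from __future__ import annotations

from typing import Sequence

from .matrix import ExpressionMatrix, GeneLengths, merge_matrices
from .normalize import normalize_matrix, size_factors_median_ratio, size_factors_tmm, size_factors_upper_quartile
from .qc import FilterCriteria, filter_features, filter_samples, sample_qc_stats
from .records import OperationRecord

__all__ = ["apply_operation", "SIZE_FACTOR_METHODS"]

SIZE_FACTOR_METHODS = {
    "median_ratio": size_factors_median_ratio,
    "tmm": size_factors_tmm,
    "upper_quartile": size_factors_upper_quartile,
}


def _replay_normalize(op: OperationRecord, matrix: ExpressionMatrix) -> ExpressionMatrix:
    params = dict(op.params)
    method = params.pop("method")
    lengths = params.pop("lengths", None)
    kwargs = {
        k: params[k]
        for k in ("min_detect_frac", "trim_m", "trim_a", "spike_prefix", "log", "pseudocount")
        if k in params
    }
    if lengths is not None:
        import pandas as pd

        kwargs["lengths"] = GeneLengths(pd.Series(lengths))
    return normalize_matrix(matrix, method, **kwargs).matrix


def apply_operation(
    op: OperationRecord, parents: Sequence[ExpressionMatrix]
) -> ExpressionMatrix:
    """Re-apply a recorded operation to its parent matrices."""
    if op.op_name == "merge":
        if len(parents) < 2:
            raise ValueError("merge replay needs >= 2 parents")
        axis = op.params.get("axis", "samples")
        out = parents[0]
        for other in parents[1:]:
            out = merge_matrices(out, other, axis=axis)
        return out
    if len(parents) != 1:
        raise ValueError(f"operation {op.op_name!r} takes exactly one parent")
    matrix = parents[0]
    if op.op_name == "normalize":
        return _replay_normalize(op, matrix)
    if op.op_name == "filter_features":
        criteria = FilterCriteria.from_params(op.params.get("criteria", {}))
        return filter_features(matrix, criteria)[0]
    if op.op_name == "filter_samples":
        criteria = FilterCriteria.from_params(op.params.get("criteria", {}))
        sf_method = op.params.get("sf_method")
        sf = SIZE_FACTOR_METHODS[sf_method](matrix) if sf_method else None
        qc = sample_qc_stats(matrix, sf)
        return filter_samples(matrix, criteria, qc)[0]
    if op.op_name == "subset":
        return matrix.subset(
            feature_ids=op.params.get("feature_ids"),
            sample_ids=op.params.get("sample_ids"),
        )
    raise ValueError(f"cannot replay unknown operation {op.op_name!r}")
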