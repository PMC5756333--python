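"""Serializable records shared by the data map, session archive and analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd

__all__ = ["OperationRecord", "AnalysisRecipe", "Report"]

_SCALARS = (str, int, float, bool, type(None))


def _check_serializable(value: Any, where: str) -> None:
    if isinstance(value, _SCALARS):
        return
    if isinstance(value, (list, tuple)):
        for v in value:
            _check_serializable(v, where)
        return
    if isinstance(value, dict):
        for k, v in value.items():
            if not isinstance(k, str):
                raise ValueError(f"{where}: non-string key {k!r}")
            _check_serializable(v, where)
        return
    raise ValueError(f"{where}: value {value!r} is not JSON-serializable")


@dataclass
class OperationRecord:
    """One derivation step (normalize, filter, subset, merge) with its params.

    Records are replayable: :func:`exprmap.ops.apply_operation` maps an
    ``op_name`` plus ``params`` back onto a deterministic transformation, so
    every node matrix in a data map can be reproduced from the root.
    """

    op_name: str
    params: dict[str, Any] = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.op_name:
            raise ValueError("op_name must be non-empty")
        _check_serializable(self.params, f"operation {self.op_name!r} params")

    def to_dict(self) -> dict[str, Any]:
        return {"op_name": self.op_name, "params": self.params, "timestamp": self.timestamp}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "OperationRecord":
        return cls(op_name=d["op_name"], params=dict(d["params"]), timestamp=d.get("timestamp", ""))


@dataclass
class AnalysisRecipe:
    """A registered analysis to re-run whenever the active node changes."""

    recipe_id: str
    analysis_name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from . import analyses  # deferred: analyses imports qc/de/network

        if self.analysis_name not in analyses.REGISTRY:
            raise ValueError(
                f"unknown analysis {self.analysis_name!r}; registered: "
                f"{sorted(analyses.REGISTRY)}"
            )
        _check_serializable(self.params, f"recipe {self.recipe_id!r} params")

    def to_dict(self) -> dict[str, Any]:
        return {
            "recipe_id": self.recipe_id,
            "analysis_name": self.analysis_name,
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisRecipe":
        return cls(d["recipe_id"], d["analysis_name"], dict(d.get("params", {})))


@dataclass
class Report:
    """Markdown analysis report attached to a data-map node."""

    recipe_id: str
    produced_on: str
    body: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    ok: bool = True

    def summary(self) -> str:
        head = self.body.strip().splitlines()
        return head[0] if head else ""
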