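"""The data map: a provenance DAG of derived expression datasets.

Every dataset produced during an exploratory session — a normalization, a
feature or sample filter, a subset, a merge — becomes a node; edges carry
the :class:`~exprmap.records.OperationRecord` that derived the child from
its parent(s).  One node is *active*; registered analysis recipes are
re-run eagerly whenever the active node changes, and their reports are
attached to the node they were produced on.  Because operation records are
replayable (:mod:`exprmap.ops`), any node's matrix can be reproduced
exactly from the root, which is the backbone of session reproducibility.

The graph is a tree except at merge nodes, which have one parent per
merged dataset.  Deleting a node cascades to all its descendants (a child
is only defined relative to its parent data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Callable, Iterable, Sequence

import networkx as nx
import pandas as pd

from . import ops as _ops
from .analyses import run_recipe
from .matrix import ExpressionMatrix, merge_matrices
from .normalize import normalize_matrix
from .qc import FilterCriteria, filter_features, filter_samples, sample_qc_stats
from .records import AnalysisRecipe, OperationRecord, Report

__all__ = ["DataMapNode", "DataMap", "create_map"]


def _default_clock() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class DataMapNode:
    """One derived dataset: matrix reference, label, note, attached reports."""

    node_id: str
    label: str
    matrix: ExpressionMatrix
    note: str = ""
    reports: list[Report] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.matrix.n_features

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples


class DataMap:
    """Derivation DAG with an active node and re-runnable analysis recipes."""

    def __init__(
        self,
        root_matrix: ExpressionMatrix,
        label: str = "root",
        clock: Callable[[], str] | None = None,
    ) -> None:
        self.clock = clock or _default_clock
        self.nodes: dict[str, DataMapNode] = {}
        self.edges: list[tuple[str, str, OperationRecord]] = []
        self.recipes: list[AnalysisRecipe] = []
        self._counter = 0
        self._timestamps: dict[str, str] = {}
        root_id = self._new_id()
        self.nodes[root_id] = DataMapNode(root_id, label, root_matrix)
        self._timestamps[root_id] = self.clock()
        self.root_id = root_id
        self.active_id = root_id

    # -- structure ---------------------------------------------------------

    def _new_id(self) -> str:
        nid = f"n{self._counter}"
        self._counter += 1
        return nid

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((p, c) for p, c, _ in self.edges)
        return g

    def _check_node(self, node_id: str) -> DataMapNode:
        if node_id not in self.nodes:
            raise KeyError(f"unknown node {node_id!r}")
        return self.nodes[node_id]

    def _check_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("data map would contain a cycle")

    @property
    def active_matrix(self) -> ExpressionMatrix:
        return self.nodes[self.active_id].matrix

    def parents(self, node_id: str) -> list[str]:
        return [p for p, c, _ in self.edges if c == node_id]

    def incoming_op(self, node_id: str) -> OperationRecord | None:
        for p, c, op in self.edges:
            if c == node_id:
                return op
        return None

    # -- derivation --------------------------------------------------------

    def derive(
        self,
        parent_id: str,
        op: OperationRecord,
        result: ExpressionMatrix,
        label: str = "",
    ) -> str:
        """Attach ``result`` as a new child of ``parent_id`` via ``op``."""
        self._check_node(parent_id)
        if not op.timestamp:
            op.timestamp = self.clock()
        child = self._new_id()
        self.nodes[child] = DataMapNode(child, label or op.op_name, result)
        self._timestamps[child] = op.timestamp
        self.edges.append((parent_id, child, op))
        self._check_acyclic()
        return child

    def derive_merge(
        self,
        parent_ids: Sequence[str],
        op: OperationRecord,
        result: ExpressionMatrix,
        label: str = "",
    ) -> str:
        """Attach a merge result with one edge per parent (same op record)."""
        if len(parent_ids) < 2:
            raise ValueError("merge derivation needs >= 2 parents")
        if len(set(parent_ids)) != len(parent_ids):
            raise ValueError("duplicate parent IDs in merge derivation")
        for pid in parent_ids:
            self._check_node(pid)
        if not op.timestamp:
            op.timestamp = self.clock()
        child = self._new_id()
        self.nodes[child] = DataMapNode(child, label or op.op_name, result)
        self._timestamps[child] = op.timestamp
        for pid in parent_ids:
            self.edges.append((pid, child, op))
        self._check_acyclic()
        return child

    # convenience derivations that compute the child and record a replayable op

    def normalize_node(self, parent_id: str, method: str, label: str = "", **kwargs: Any) -> str:
        result = normalize_matrix(self.nodes[parent_id].matrix, method, **kwargs)
        return self.derive(parent_id, result.op, result.matrix, label or f"normalize:{method}")

    def filter_features_node(
        self, parent_id: str, criteria: FilterCriteria, label: str = ""
    ) -> str:
        parent = self._check_node(parent_id)
        survivors, _removed = filter_features(parent.matrix, criteria)
        op = OperationRecord("filter_features", {"criteria": criteria.to_params()})
        return self.derive(parent_id, op, survivors, label or "filter_features")

    def filter_samples_node(
        self,
        parent_id: str,
        criteria: FilterCriteria,
        sf_method: str | None = None,
        label: str = "",
    ) -> str:
        parent = self._check_node(parent_id)
        sf = _ops.SIZE_FACTOR_METHODS[sf_method](parent.matrix) if sf_method else None
        qc = sample_qc_stats(parent.matrix, sf)
        survivors, _removed = filter_samples(parent.matrix, criteria, qc)
        op = OperationRecord(
            "filter_samples",
            {"criteria": criteria.to_params(), "sf_method": sf_method},
        )
        return self.derive(parent_id, op, survivors, label or "filter_samples")

    def subset_node(
        self,
        parent_id: str,
        feature_ids: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
        label: str = "",
    ) -> str:
        parent = self._check_node(parent_id)
        feature_ids = list(feature_ids) if feature_ids is not None else None
        sample_ids = list(sample_ids) if sample_ids is not None else None
        result = parent.matrix.subset(feature_ids=feature_ids, sample_ids=sample_ids)
        op = OperationRecord(
            "subset", {"feature_ids": feature_ids, "sample_ids": sample_ids}
        )
        return self.derive(parent_id, op, result, label or "subset")

    def merge_node(
        self, parent_ids: Sequence[str], axis: str = "samples", label: str = ""
    ) -> str:
        matrices = [self._check_node(p).matrix for p in parent_ids]
        out = matrices[0]
        for other in matrices[1:]:
            out = merge_matrices(out, other, axis=axis)
        op = OperationRecord("merge", {"axis": axis})
        return self.derive_merge(parent_ids, op, out, label or "merge")

    # -- recipes and the active node ---------------------------------------

    def add_recipe(
        self, analysis_name: str, params: dict[str, Any] | None = None, recipe_id: str = ""
    ) -> AnalysisRecipe:
        """Register an analysis; it runs now on the active node and again on
        every subsequent node switch."""
        recipe = AnalysisRecipe(
            recipe_id or f"r{len(self.recipes)}", analysis_name, dict(params or {})
        )
        self.recipes.append(recipe)
        self._attach(run_recipe(recipe, self.active_matrix, self.active_id))
        return recipe

    def _attach(self, report: Report) -> None:
        node = self.nodes[report.produced_on]
        node.reports = [r for r in node.reports if r.recipe_id != report.recipe_id]
        node.reports.append(report)

    def set_active(self, node_id: str) -> list[Report]:
        """Switch the active dataset and eagerly re-run every recipe on it.

        Returns the fresh reports in recipe order.  A recipe whose
        preconditions fail on the new node yields a failure report instead
        of raising.
        """
        self._check_node(node_id)
        self.active_id = node_id
        fresh = []
        for recipe in self.recipes:
            report = run_recipe(recipe, self.active_matrix, node_id)
            self._attach(report)
            fresh.append(report)
        return fresh

    # -- node editing ------------------------------------------------------

    def rename_node(self, node_id: str, label: str) -> None:
        if not label:
            raise ValueError("node label must be non-empty")
        self._check_node(node_id).label = label

    def annotate_node(self, node_id: str, note: str) -> None:
        self._check_node(node_id).note = note

    def delete_node(self, node_id: str) -> list[str]:
        """Remove a node and all its descendants; returns the removed IDs.

        The root cannot be deleted.  If the active node is removed, the
        root becomes active again.
        """
        self._check_node(node_id)
        if node_id == self.root_id:
            raise ValueError("cannot delete the root node")
        doomed = {node_id} | nx.descendants(self.graph(), node_id)
        removed = [n for n in self.nodes if n in doomed]  # insertion order
        for n in removed:
            del self.nodes[n]
            self._timestamps.pop(n, None)
        self.edges = [(p, c, op) for p, c, op in self.edges if p not in doomed and c not in doomed]
        if self.active_id in doomed:
            self.active_id = self.root_id
        return removed

    # -- lineage and replay ------------------------------------------------

    def lineage_table(self) -> pd.DataFrame:
        """One row per node in topological order: identity, parents, the
        deriving operation, dimensions and timestamp."""
        order = list(nx.topological_sort(self.graph()))
        rows = []
        for nid in order:
            node = self.nodes[nid]
            op = self.incoming_op(nid)
            rows.append(
                {
                    "node_id": nid,
                    "label": node.label,
                    "parent_ids": ";".join(self.parents(nid)),
                    "op_name": op.op_name if op else "root",
                    "params": json.dumps(op.params, sort_keys=True) if op else "{}",
                    "n_features": node.n_features,
                    "n_samples": node.n_samples,
                    "timestamp": self._timestamps.get(nid, ""),
                }
            )
        return pd.DataFrame(rows)

    def lineage_path(self, node_id: str) -> list[str]:
        """Node IDs from the root to ``node_id`` (first parent at merges)."""
        self._check_node(node_id)
        path = [node_id]
        while path[-1] != self.root_id:
            parents = self.parents(path[-1])
            if not parents:
                break
            path.append(parents[0])
        return list(reversed(path))

    def replay(self, node_id: str) -> ExpressionMatrix:
        """Recompute a node's matrix from the root by replaying ancestor ops."""
        self._check_node(node_id)
        cache: dict[str, ExpressionMatrix] = {}

        def rebuild(nid: str) -> ExpressionMatrix:
            if nid in cache:
                return cache[nid]
            if nid == self.root_id:
                cache[nid] = self.nodes[nid].matrix
                return cache[nid]
            op = self.incoming_op(nid)
            assert op is not None
            parents = [rebuild(p) for p in self.parents(nid)]
            cache[nid] = _ops.apply_operation(op, parents)
            return cache[nid]

        return rebuild(node_id)


def create_map(
    root_matrix: ExpressionMatrix,
    label: str = "root",
    clock: Callable[[], str] | None = None,
) -> DataMap:
    """Start a data map from an imported count matrix."""
    return DataMap(root_matrix, label=label, clock=clock)
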