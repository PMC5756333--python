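"""Registered analyses the data map re-runs when the active node changes.

Each runner takes the active node's matrix plus the recipe parameters and
returns a :class:`~exprmap.records.Report`.  Precondition failures (for
example the DE groups disappearing after a sample filter) produce a
*failure report* (``ok=False``) rather than an exception, so switching
nodes never aborts.
"""

from __future__ import annotations

from typing import Any, Callable

import networkx as nx

from . import qc as _qc
from .de import GroupAssignment, de_report, mwu_de
from .matrix import ExpressionMatrix
from .network import RegulatoryNetwork, gene_scores, influence_scores
from .records import AnalysisRecipe, Report

__all__ = ["REGISTRY", "run_recipe"]


def _effective_groups(matrix: ExpressionMatrix, groups: dict[str, str]) -> GroupAssignment:
    present = {s: g for s, g in groups.items() if s in matrix.values.columns}
    labels = set(present.values())
    counts = {g: sum(1 for v in present.values() if v == g) for g in labels}
    if len([g for g, n in counts.items() if n >= 2]) < 2 or len(labels) < 2:
        raise ValueError("fewer than two groups with >= 2 samples on this node")
    return GroupAssignment(present)


def _run_sample_qc_stats(matrix: ExpressionMatrix, params: dict[str, Any]) -> Report:
    from .ops import SIZE_FACTOR_METHODS

    sf_method = params.get("sf_method")
    sf = SIZE_FACTOR_METHODS[sf_method](matrix) if sf_method else None
    stats = _qc.sample_qc_stats(matrix, sf)
    body = (
        "## Sample QC statistics\n\n"
        f"- samples: {matrix.n_samples}, features: {matrix.n_features}\n"
        f"- size-factor method: {sf_method or 'none'}\n"
        f"- median dropout rate: {stats['dropout_rate'].median():.4f}\n"
    )
    return Report("", "", body, tables={"sample_qc": stats.reset_index()})


def _run_rank_frequency(matrix: ExpressionMatrix, params: dict[str, Any]) -> Report:
    sample_id = params["sample_id"]
    table = _qc.rank_frequency(matrix, sample_id)
    body = (
        "## Rank-frequency\n\n"
        f"- sample: {sample_id}\n- positive features: {len(table)}\n"
    )
    return Report("", "", body, tables={"rank_frequency": table})


def _run_mean_variability(matrix: ExpressionMatrix, params: dict[str, Any]) -> Report:
    table = _qc.mean_variability(matrix)
    body = f"## Mean-variability\n\n- features: {len(table)}\n"
    return Report("", "", body, tables={"mean_variability": table})


def _run_mwu_de(matrix: ExpressionMatrix, params: dict[str, Any]) -> Report:
    groups = _effective_groups(matrix, params["groups"])
    result = mwu_de(matrix, groups, pseudocount=params.get("pseudocount", 1.0))
    report = de_report(
        result, alpha=params.get("alpha", 0.05), top_n=params.get("top_n", 100)
    )
    return Report("", "", report.body, tables=report.tables)


def _network_from_params(params: dict[str, Any]) -> RegulatoryNetwork:
    directed = params.get("directed", True)
    graph: "nx.DiGraph | nx.Graph" = nx.DiGraph() if directed else nx.Graph()
    for edge in params["network_edges"]:
        if len(edge) >= 3:
            graph.add_edge(edge[0], edge[1], weight=edge[2])
        else:
            graph.add_edge(edge[0], edge[1])
    tf_set = set(params.get("tf_set") or [])
    if not tf_set:
        tf_set = (
            {n for n in graph.nodes if graph.out_degree(n) > 0}
            if directed
            else set(graph.nodes)
        )
    return RegulatoryNetwork(graph, tf_set & set(graph.nodes))


def _run_tf_influence(matrix: ExpressionMatrix, params: dict[str, Any]) -> Report:
    groups = _effective_groups(matrix, params["groups"])
    result = mwu_de(matrix, groups, pseudocount=params.get("pseudocount", 1.0))
    scores = gene_scores(
        result,
        option=params.get("score_option", "lfc_times_logp"),
        p_floor=params.get("p_floor", 1e-300),
    )
    net = _network_from_params(params)
    table = influence_scores(
        net,
        scores,
        option=params.get("influence_option", "degree_normalized"),
        tau=params.get("tau", 1.0),
    )
    body = (
        "## Transcription-factor network influence\n\n"
        f"- score option: {scores.score_option}\n"
        f"- influence option: {params.get('influence_option', 'degree_normalized')}\n"
        f"- tau: {params.get('tau', 1.0)}\n"
        f"- TFs ranked: {len(table)}\n"
    )
    if len(table):
        top = table.iloc[0]
        body += f"- top factor: {top.tf} (influence {top.influence_score:.4g})\n"
    return Report("", "", body, tables={"tf_influence": table})


def _run_feature_query(matrix: ExpressionMatrix, params: dict[str, Any]) -> Report:
    table = _qc.feature_query(
        matrix,
        params["target"],
        method=params.get("method", "pearson"),
        top_n=params.get("top_n", 20),
    )
    body = (
        "## Feature query\n\n"
        f"- target: {params['target']}\n- method: {params.get('method', 'pearson')}\n"
    )
    return Report("", "", body, tables={"feature_query": table})


REGISTRY: dict[str, Callable[[ExpressionMatrix, dict[str, Any]], Report]] = {
    "sample_qc_stats": _run_sample_qc_stats,
    "rank_frequency": _run_rank_frequency,
    "mean_variability": _run_mean_variability,
    "mwu_de": _run_mwu_de,
    "tf_influence": _run_tf_influence,
    "feature_query": _run_feature_query,
}


def run_recipe(recipe: AnalysisRecipe, matrix: ExpressionMatrix, node_id: str) -> Report:
    """Run one recipe against a node matrix; failures become failure reports."""
    runner = REGISTRY[recipe.analysis_name]
    try:
        report = runner(matrix, recipe.params)
    except (ValueError, KeyError) as exc:
        reason = str(exc).strip("'\"")
        body = (
            f"## {recipe.analysis_name}: failed\n\n"
            f"- reason: {reason}\n- params: {recipe.params}\n"
        )
        report = Report(recipe.recipe_id, node_id, body, ok=False)
    report.recipe_id = recipe.recipe_id
    report.produced_on = node_id
    return report
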