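"""Regulatory-network influence scoring for candidate trans-differentiation
factors.

Given a differential-expression result between a start and a target cell
state and a regulatory (directed) or protein-association (undirected)
network, each gene receives a score combining its fold change and adjusted
p-value, and each transcription factor is ranked by how much score its
direct neighborhood accumulates.  A TF whose targets are strongly and
significantly differentially expressed is a candidate driver of the
conversion.

Three influence options are provided:

``sum``
    S_t = G_t + sum of neighbor gene scores.
``degree_normalized``
    S_t = G_t + sum of G_j / d(j) over neighbors j, where d(j) is the
    in-degree (directed) or degree (undirected) of j — shared targets
    share credit between their regulators.
``activated_count``
    S_t = number of neighbors with gene score >= tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .de import DEResult

__all__ = [
    "RegulatoryNetwork",
    "GeneScoreTable",
    "read_network",
    "gene_scores",
    "top_subgraph",
    "influence_scores",
    "tf_neighborhood",
]

logger = logging.getLogger(__name__)

SCORE_OPTIONS = ("lfc_times_logp", "abs_lfc", "neglogp")
INFLUENCE_OPTIONS = ("sum", "degree_normalized", "activated_count")


@dataclass
class RegulatoryNetwork:
    """Gene network (directed regulatory or undirected protein-association)
    with a designated transcription-factor subset."""

    graph: "nx.DiGraph | nx.Graph"
    tf_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        loops = list(nx.nodes_with_selfloops(self.graph))
        if loops:
            logger.warning("dropping %d self-loop(s) (e.g. %r)", len(loops), loops[0])
            self.graph.remove_edges_from((u, u) for u in loops)
        unknown = self.tf_set - set(self.graph.nodes)
        if unknown:
            raise ValueError(f"TF {sorted(unknown)[0]!r} is not a network node")

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighborhood(self, gene: str) -> list[str]:
        """Direct neighborhood: out-neighbors if directed, all neighbors else."""
        if self.directed:
            return list(self.graph.successors(gene))
        return list(self.graph.neighbors(gene))

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v, data in self.graph.edges(data=True):
                w = data.get("weight")
                fh.write(f"{u}\t{v}\n" if w is None else f"{u}\t{v}\t{w}\n")


@dataclass
class GeneScoreTable:
    """gene → non-negative score; genes absent from the DE result score 0."""

    scores: dict[str, float]
    score_option: str
    p_floor: float

    def __post_init__(self) -> None:
        bad = [g for g, s in self.scores.items() if not np.isfinite(s) or s < 0]
        if bad:
            raise ValueError(f"non-finite or negative score for gene {bad[0]!r}")

    def __getitem__(self, gene: str) -> float:
        return self.scores.get(gene, 0.0)


def read_network(
    path: str | Path,
    directed: bool = True,
    tf_list: str | Path | None = None,
) -> RegulatoryNetwork:
    """Load a network from a TSV edge list (source, target[, weight]).

    Self-loops are dropped with a warning and duplicate edges collapse to
    one.  The TF set comes from ``tf_list`` (one gene per line) when given;
    otherwise all nodes with out-degree > 0 in a directed network, or all
    nodes when undirected.
    """
    graph: "nx.DiGraph | nx.Graph" = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed network line {lineno}: {line!r}")
            if len(parts) >= 3 and parts[2]:
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"malformed weight on line {lineno}: {line!r}") from exc
                graph.add_edge(parts[0], parts[1], weight=weight)
            else:
                graph.add_edge(parts[0], parts[1])
    if tf_list is not None:
        with open(tf_list) as fh:
            tfs = {ln.strip() for ln in fh if ln.strip()}
        tfs &= set(graph.nodes)  # silently scoped to the network
    elif directed:
        tfs = {n for n in graph.nodes if graph.out_degree(n) > 0}
    else:
        tfs = set(graph.nodes)
    net = RegulatoryNetwork(graph, tfs)
    net.tf_set &= set(net.graph.nodes)
    return net


def gene_scores(
    de: DEResult,
    option: str = "lfc_times_logp",
    p_floor: float = 1e-300,
) -> GeneScoreTable:
    """Per-gene scores from the DE table.

    ``lfc_times_logp``: |log2 FC| * (-log10 max(adj. p, p_floor));
    ``abs_lfc``: |log2 FC|;  ``neglogp``: -log10 max(adj. p, p_floor).
    """
    if option not in SCORE_OPTIONS:
        raise ValueError(f"unknown score option {option!r}; choose from {SCORE_OPTIONS}")
    lfc = de.table["log2_fc"].abs()
    neglogp = -np.log10(np.maximum(de.table["p_adjusted"].to_numpy(), p_floor))
    if option == "lfc_times_logp":
        scores = lfc.to_numpy() * neglogp
    elif option == "abs_lfc":
        scores = lfc.to_numpy()
    else:
        scores = neglogp
    return GeneScoreTable(
        dict(zip(de.table.index, scores.astype(float))), option, p_floor
    )


def top_subgraph(
    net: RegulatoryNetwork,
    de: DEResult,
    min_abs_lfc: float = 1.0,
    max_p: float = 0.05,
) -> RegulatoryNetwork:
    """Induced subgraph on top-ranked genes — the regulatory "hot spot".

    Keeps network genes with |log2 FC| >= ``min_abs_lfc`` and adjusted
    p <= ``max_p``; an empty result is returned (with a warning) rather
    than raised.
    """
    passing = de.table[
        (de.table["log2_fc"].abs() >= min_abs_lfc) & (de.table["p_adjusted"] <= max_p)
    ].index
    keep = [g for g in passing if g in net.graph]
    if not keep:
        logger.warning("no network gene passes the top-gene thresholds")
    sub = net.graph.subgraph(keep).copy()
    return RegulatoryNetwork(sub, net.tf_set & set(sub.nodes))


def influence_scores(
    net: RegulatoryNetwork,
    scores: GeneScoreTable,
    option: str = "degree_normalized",
    tau: float = 1.0,
) -> pd.DataFrame:
    """Rank transcription factors by direct-neighborhood influence.

    Columns: tf, center_score, neighborhood_size, activated_neighbors
    (neighbors with score >= tau, reported for every option),
    influence_score, rank.  Ranks are by descending influence with ties
    broken by center score (descending) then gene name.
    """
    if option not in INFLUENCE_OPTIONS:
        raise ValueError(
            f"unknown influence option {option!r}; choose from {INFLUENCE_OPTIONS}"
        )
    if not net.tf_set:
        raise ValueError("network has an empty TF set")
    degree = (
        dict(net.graph.in_degree()) if net.directed else dict(net.graph.degree())
    )
    rows = []
    for tf in sorted(net.tf_set):
        nbrs = net.neighborhood(tf)
        center = scores[tf]
        activated = sum(1 for j in nbrs if scores[j] >= tau)
        if option == "sum":
            s = center + sum(scores[j] for j in nbrs)
        elif option == "degree_normalized":
            s = center + sum(scores[j] / degree[j] for j in nbrs if degree[j] > 0)
        else:
            s = float(activated)
        rows.append((tf, center, len(nbrs), activated, s))
    table = pd.DataFrame(
        rows,
        columns=[
            "tf",
            "center_score",
            "neighborhood_size",
            "activated_neighbors",
            "influence_score",
        ],
    )
    table = table.sort_values(
        ["influence_score", "center_score", "tf"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def tf_neighborhood(
    net: RegulatoryNetwork, scores: GeneScoreTable, tf: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Local network centered on one TF, ready for export/plotting.

    Returns ``(edges, nodes)``: the edge list of the subgraph induced by
    the TF and its direct neighborhood, and a node table with each gene's
    score attached.
    """
    if tf not in net.tf_set:
        raise KeyError(f"unknown TF {tf!r}")
    members = [tf] + [n for n in net.neighborhood(tf) if n != tf]
    sub = net.graph.subgraph(members)
    edges = pd.DataFrame(
        [(u, v) for u, v in sub.edges()], columns=["source", "target"]
    )
    nodes = pd.DataFrame(
        {"gene": members, "score": [scores[g] for g in members]}
    )
    return edges, nodes
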