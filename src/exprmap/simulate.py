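"""Synthetic count matrices and regulatory networks with known truth.

The count generator emulates the structure the toolkit assumes in real
RNA-seq data: per-gene baseline means drawn log-normally (a long-tailed
expression distribution), per-sample size factors (sequencing depth),
negative-binomial counts (var = m + phi * m^2), an optional logistic
zero-inflation in log mean that mimics single-cell dropout, a two-condition
design with a planted fraction of differentially expressed genes, and
optional spike-in rows at fixed known concentrations that scale with depth
only.  All randomness flows through one seed, so a given spec is fully
deterministic.

The companion truth objects (true size factors, true DE genes and effects,
spike IDs, planted-network scores) are what parameter-recovery and
error-control tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import DesignTable, ExpressionMatrix
from .network import GeneScoreTable, RegulatoryNetwork

__all__ = [
    "SimulationSpec",
    "SimulationTruth",
    "simulate_counts",
    "simulate_network",
    "negative_binomial_draws",
]


@dataclass
class SimulationSpec:
    """Parameters of the count simulation.

    Defaults describe a modest single-cell-like experiment: 2000 genes by
    20 cells in two balanced conditions, log-normal baseline means (median
    ~7 counts), size-factor spread sigma_s = 0.5 on the log scale,
    NB dispersion phi = 0.3, 10% DE genes with log2 effects of mean
    magnitude 2, and logistic dropout with a = 1.5, b = 1.0.
    """

    n_features: int = 2000
    n_samples: int = 20
    n_conditions: int = 2
    mean_log_mu: float = 2.0  # log-scale location of baseline means
    mean_log_sigma: float = 1.5  # log-scale spread of baseline means
    sigma_s: float = 0.5  # log-normal sd of size factors
    phi: float = 0.3  # NB dispersion; 0 → Poisson
    de_frac: float = 0.1  # fraction of genes with a condition effect
    effect_mu: float = 2.0  # mean |log2 fold change| of DE genes
    effect_sigma: float = 0.5
    dropout: bool = True
    dropout_a: float = 1.5
    dropout_b: float = 1.0
    n_spikes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.de_frac <= 1):
            raise ValueError("de_frac must be in [0, 1]")
        for name in ("mean_log_sigma", "sigma_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.n_features < 1 or self.n_samples < 2:
            raise ValueError("need >= 1 feature and >= 2 samples")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated matrix."""

    size_factors: pd.Series  # geometric mean 1, indexed by sample
    de_genes: list[str]
    log2_effects: pd.Series  # signed, indexed by DE gene
    spike_ids: list[str]


def negative_binomial_draws(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    """NB draws with var = m + phi m^2, as a gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def simulate_counts(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, DesignTable, SimulationTruth]:
    """Draw one count matrix with design table and ground truth."""
    rng = np.random.default_rng(spec.seed)
    nf, ns = spec.n_features, spec.n_samples
    genes = [f"gene{i:05d}" for i in range(nf)]
    samples = [f"S{j:03d}" for j in range(ns)]
    cond_labels = [f"C{k}" for k in range(spec.n_conditions)]
    condition = [cond_labels[j * spec.n_conditions // ns] for j in range(ns)]
    cond_idx = np.array([cond_labels.index(c) for c in condition])

    mu = rng.lognormal(spec.mean_log_mu, spec.mean_log_sigma, size=nf)
    s = rng.lognormal(0.0, spec.sigma_s, size=ns)
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean 1, comparable to estimates

    n_de = int(round(spec.de_frac * nf))
    de_idx = rng.choice(nf, size=n_de, replace=False)
    beta = np.zeros(nf)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        beta[de_idx] = signs * rng.normal(spec.effect_mu, spec.effect_sigma, size=n_de)

    # condition 0 is baseline; the effect multiplies every non-zero condition
    effect = np.where(cond_idx[None, :] > 0, 2.0 ** beta[:, None], 1.0)
    m = s[None, :] * mu[:, None] * effect
    counts = negative_binomial_draws(rng, m, spec.phi).astype(float)
    if spec.dropout:
        p_drop = 1.0 / (1.0 + np.exp(-(spec.dropout_a - spec.dropout_b * np.log(m))))
        counts[rng.random(size=m.shape) < p_drop] = 0.0

    spike_ids: list[str] = []
    if spec.n_spikes:
        spike_ids = [f"ERCC-{i + 1:05d}" for i in range(spec.n_spikes)]
        conc = 2.0 ** np.linspace(3, 10, spec.n_spikes)  # known amounts, wide range
        spike_counts = rng.poisson(s[None, :] * conc[:, None]).astype(float)
        counts = np.vstack([counts, spike_counts])
        genes = genes + spike_ids

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), kind="counts"
    )
    design = DesignTable(
        pd.DataFrame({"condition": condition}, index=pd.Index(samples, name="sample"))
    )
    truth = SimulationTruth(
        size_factors=pd.Series(s, index=samples),
        de_genes=[genes[i] for i in sorted(de_idx)],
        log2_effects=pd.Series(beta[sorted(de_idx)], index=[genes[i] for i in sorted(de_idx)]),
        spike_ids=spike_ids,
    )
    return matrix, design, truth


def simulate_network(
    n_tf: int,
    n_targets: int,
    planted_tf: bool = False,
    seed: int = 0,
    out_degree: int = 5,
) -> tuple[RegulatoryNetwork, GeneScoreTable]:
    """Random directed TF→target network with a companion truth score table.

    Each TF regulates ``out_degree`` targets drawn at random.  With
    ``planted_tf`` the first TF's targets receive dominant scores (and the
    TF itself the highest center score), so it must rank first under every
    influence option — the recovery fixture for the scoring module.
    """
    if n_tf < 1 or n_targets < 0:
        raise ValueError("need n_tf >= 1 and n_targets >= 0")
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i + 1:03d}" for i in range(n_tf)]
    targets = [f"G{i + 1:05d}" for i in range(n_targets)]
    graph = nx.DiGraph()
    graph.add_nodes_from(tfs)
    graph.add_nodes_from(targets)
    k = min(out_degree, n_targets)
    for tf in tfs:
        if k:
            for t in rng.choice(n_targets, size=k, replace=False):
                graph.add_edge(tf, targets[t])

    scores = {t: float(rng.uniform(0.0, 0.5)) for t in targets}
    scores.update({tf: float(rng.uniform(0.0, 0.5)) for tf in tfs})
    if planted_tf and k:
        planted = tfs[0]
        scores[planted] = 5.0
        for t in graph.successors(planted):
            scores[t] = float(100.0 + rng.uniform(0.0, 10.0))
    truth = GeneScoreTable(scores, score_option="planted_truth", p_floor=1e-300)
    return RegulatoryNetwork(graph, set(tfs)), truth
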