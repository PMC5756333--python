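"""Two-group nonparametric differential expression.

Per-feature two-sided Mann-Whitney U tests on normalized values, with
Benjamini-Hochberg control of the false discovery rate and a
pseudocount-stabilized log2 fold change.  The U statistic is reported for
the first (reference) group; exact null p-values are used for small
tie-free groups, otherwise the normal approximation with tie and
continuity corrections.  Rank tests are invariant to monotone transforms,
so running on normalized rather than log-normalized values is cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .matrix import ExpressionMatrix
from .records import Report

__all__ = ["DEResult", "GroupAssignment", "mwu_de", "bh_adjust", "de_report"]

#: largest per-group size for which the exact null distribution is enumerated
EXACT_MAX_N = 8


@dataclass
class GroupAssignment:
    """sample_id → group label; exactly two labels, each with >= 2 samples."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        groups = sorted(set(self.labels.values()))
        if len(groups) != 2:
            raise ValueError(f"need exactly two groups, got {groups}")
        for g in groups:
            n = sum(1 for v in self.labels.values() if v == g)
            if n < 2:
                raise ValueError(f"group {g!r} has {n} sample(s); need >= 2")

    @property
    def group_names(self) -> tuple[str, str]:
        a, b = sorted(set(self.labels.values()))
        return a, b

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]


@dataclass
class DEResult:
    """Per-feature DE table plus the test's metadata.

    ``table`` columns: u_statistic, p_value, p_adjusted, log2_fc, mean_a,
    mean_b, exact (True where the exact null was enumerated); indexed by
    feature ID in input row order.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    pseudocount: float

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index(names="feature_id")
        return out


def bh_adjust(p_values: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j>=i} p_(j) * n / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(n)
    adj[order] = adj_sorted
    return adj


def mwu_de(
    matrix: ExpressionMatrix,
    groups: GroupAssignment | Mapping[str, str],
    pseudocount: float = 1.0,
) -> DEResult:
    """Per-feature two-sided Mann-Whitney U test between two sample groups.

    The exact null is enumerated when both groups have at most
    ``EXACT_MAX_N`` samples and the feature's values are tie-free;
    otherwise the normal approximation with tie correction and continuity
    correction is used.  Features identical across all samples get p = 1
    and U = n_a * n_b / 2.  ``log2_fc = log2((mean_a + c) / (mean_b + c))``
    with pseudocount c on the normalized group means.
    """
    if not isinstance(groups, GroupAssignment):
        groups = GroupAssignment(dict(groups))
    missing = [s for s in groups.labels if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"unknown sample {missing[0]!r} in group assignment")
    name_a, name_b = groups.group_names
    samples_a, samples_b = groups.samples(name_a), groups.samples(name_b)
    a = matrix.values[samples_a].to_numpy()
    b = matrix.values[samples_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]

    both = np.concatenate([a, b], axis=1)
    has_ties = np.array([len(np.unique(row)) < row.size for row in both])
    constant = np.ptp(both, axis=1) == 0
    small = max(n_a, n_b) <= EXACT_MAX_N
    exact_rows = small & ~has_ties & ~constant
    approx_rows = ~exact_rows & ~constant

    u = np.full(both.shape[0], n_a * n_b / 2.0)
    p = np.ones(both.shape[0])
    if exact_rows.any():
        res = mannwhitneyu(
            a[exact_rows], b[exact_rows], axis=1, method="exact", alternative="two-sided"
        )
        u[exact_rows] = res.statistic
        p[exact_rows] = res.pvalue
    if approx_rows.any():
        res = mannwhitneyu(
            a[approx_rows],
            b[approx_rows],
            axis=1,
            method="asymptotic",
            use_continuity=True,
            alternative="two-sided",
        )
        u[approx_rows] = res.statistic
        p[approx_rows] = np.minimum(res.pvalue, 1.0)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    table = pd.DataFrame(
        {
            "u_statistic": u,
            "p_value": p,
            "p_adjusted": bh_adjust(p),
            "log2_fc": lfc,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "exact": exact_rows,
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )
    return DEResult(table, name_a, name_b, n_a, n_b, pseudocount)


def de_report(result: DEResult, alpha: float = 0.05, top_n: int = 100) -> Report:
    """Markdown report of significant features (BH-adjusted p <= alpha).

    Rows are sorted by adjusted p, then by |log2 fold change| descending,
    then feature ID, and truncated to ``top_n``.
    """
    sig = result.table[result.table["p_adjusted"] <= alpha].copy()
    sig["abs_lfc"] = sig["log2_fc"].abs()
    sig = sig.sort_values(
        ["p_adjusted", "abs_lfc", "feature_id"],
        ascending=[True, False, True],
        kind="stable",
    ).drop(columns=["abs_lfc"])
    shown = sig.head(top_n)
    lines = [
        "## Differential expression (Mann-Whitney U)",
        "",
        f"- groups: {result.group_a} (n={result.n_a}) vs {result.group_b} (n={result.n_b})",
        f"- correction: Benjamini-Hochberg, alpha = {alpha}",
        f"- log2 fold-change pseudocount: {result.pseudocount}",
        f"- features tested: {len(result.table)}",
        f"- significant at adjusted p <= {alpha}: {len(sig)}",
        "",
    ]
    if len(sig) == 0:
        lines.append("No features pass the significance threshold (zero hits).")
    else:
        lines.append(f"Top {len(shown)} features:")
        lines.append("")
        lines.append("| feature | U | p | adj. p | log2 FC | mean A | mean B |")
        lines.append("|---|---|---|---|---|---|---|")
        for fid, row in shown.iterrows():
            lines.append(
                f"| {fid} | {row.u_statistic:g} | {row.p_value:.4g} | "
                f"{row.p_adjusted:.4g} | {row.log2_fc:.4f} | "
                f"{row.mean_a:.4g} | {row.mean_b:.4g} |"
            )
    body = "\n".join(lines) + "\n"
    return Report(
        recipe_id="",
        produced_on="",
        body=body,
        tables={"significant": shown.reset_index()},
    )
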