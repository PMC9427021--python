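"""Single-sample GSEA enrichment scores and between-group comparison.

The enrichment score of a gene set S in a sample is the sum over all ranked
positions of the difference between a weighted in-set ECDF and the uniform
out-of-set ECDF: genes are ranked by expression (descending), the top gene
receives rank n, and

    ES = sum_i [ P_in(i) - P_out(i) ],
    P_in(i)  = sum_{g in S, pos(g) <= i} rank(g)^alpha / sum_{g in S} rank(g)^alpha,
    P_out(i) = #{g not in S, pos(g) <= i} / (n - |S|).

Expression ties are broken deterministically by gene-id lexical order, so
identical expression vectors always produce identical scores. Because only
ranks enter, scores are invariant under any strictly increasing transform
of a sample's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, ranksum_p
from .core_io import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentProfile:
    """Sample-by-gene-set ssGSEA score matrix."""

    scores: pd.DataFrame  # samples x sets
    alpha: float
    normalized: bool

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.columns)


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentProfile:
    """ssGSEA enrichment score for every (sample, gene set) pair.

    Sets are filtered to the genes present in ``expr``; sets left empty are
    dropped with a warning. A set covering the whole gene universe is an
    error (the out-of-set ECDF would be undefined). With ``normalize`` the
    full score matrix is min-max scaled to [0, 1].
    """
    if alpha <= 0:
        raise ValidationError("alpha must be > 0")
    usable = sets.restrict_to(expr.gene_ids)
    if not usable.sets:
        raise ValidationError("no gene set overlaps the expression matrix")
    n = len(expr.gene_ids)
    for name, genes in usable:
        if len(genes) == n:
            raise ValidationError(f"gene set {name!r} covers every gene in the matrix")

    frame = expr.frame
    # deterministic ranking: descending expression, ties by gene id ascending
    gene_order_idx = np.argsort(frame.index.to_numpy(), kind="stable")
    out = pd.DataFrame(
        index=pd.Index(expr.sample_ids, name="sample_id"),
        columns=usable.names,
        dtype=float,
    )
    values = frame.to_numpy()
    gene_ids = frame.index.to_numpy()
    for j, sample in enumerate(expr.sample_ids):
        x = values[:, j]
        # sort lexically first, then stable-sort by -expression
        lex = gene_order_idx
        order = lex[np.argsort(-x[lex], kind="stable")]
        pos_of = {gene_ids[g]: p for p, g in enumerate(order)}  # 0-based position
        ranks = n - np.arange(n)  # rank at position p (0-based) is n - p
        for name, genes in usable:
            in_set = np.zeros(n, dtype=bool)
            for g in genes:
                in_set[pos_of[g]] = True
            w = np.where(in_set, ranks.astype(float) ** alpha, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_set) / (n - len(genes))
            out.at[sample, name] = float(np.sum(p_in - p_out))
    if normalize:
        lo, hi = out.to_numpy().min(), out.to_numpy().max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
        else:
            out = out * 0.0
    return EnrichmentProfile(scores=out, alpha=alpha, normalized=normalize)


def compare_groups(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Nonparametric per-variable comparison across sample groups.

    ``table`` is samples x variables (e.g. an enrichment profile's scores);
    ``labels`` assigns a group to every sample. Two groups: two-sided
    Wilcoxon rank-sum per variable. Three or more: Kruskal–Wallis omnibus
    plus all pairwise Wilcoxon tests. Benjamini–Hochberg q-values are
    reported per test family (across variables), and effect direction as
    differences of group medians.
    """
    labels = pd.Series(labels)
    labels.index = labels.index.astype(str)
    table = table.loc[[s for s in table.index if s in labels.index]]
    labels = labels.reindex(table.index)
    groups = sorted(labels.dropna().unique())
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValidationError(
            f"groups with fewer than 2 samples: {sizes[sizes < 2].index.tolist()}"
        )

    rows = []
    for var in table.columns:
        x = table[var]
        by_group = {g: x[labels == g].to_numpy() for g in groups}
        medians = {g: float(np.median(v)) for g, v in by_group.items()}
        if len(groups) == 2:
            a, b = groups
            p = ranksum_p(by_group[a], by_group[b])
            rows.append(
                {
                    "variable": var,
                    "comparison": f"{a}vs{b}",
                    "p_value": p,
                    "median_diff": medians[a] - medians[b],
                    "test": "wilcoxon",
                }
            )
        else:
            arrays = [by_group[g] for g in groups]
            if np.unique(np.concatenate(arrays)).size == 1:
                p_kw = 1.0  # all values identical: no evidence against the null
            else:
                p_kw = float(stats.kruskal(*arrays).pvalue)
            rows.append(
                {
                    "variable": var,
                    "comparison": "omnibus",
                    "p_value": p_kw,
                    "median_diff": max(medians.values()) - min(medians.values()),
                    "test": "kruskal",
                }
            )
            for i, a in enumerate(groups):
                for b in groups[i + 1:]:
                    rows.append(
                        {
                            "variable": var,
                            "comparison": f"{a}vs{b}",
                            "p_value": ranksum_p(by_group[a], by_group[b]),
                            "median_diff": medians[a] - medians[b],
                            "test": "wilcoxon",
                        }
                    )
    result = pd.DataFrame(rows)
    result["q_value"] = np.nan
    for comp, idx in result.groupby("comparison").groups.items():
        result.loc[idx, "q_value"] = bh_adjust(result.loc[idx, "p_value"].to_numpy())
    return result
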