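"""Moderated-t differential expression, DEG intersection, and ORA.

The moderated two-sample t follows the empirical-Bayes variance-shrinkage
scheme used throughout microarray analysis: gene-wise pooled variances s²
with d = n_a + n_b - 2 residual df are assumed to follow a scaled F
distribution around a prior (d0, s0²), the prior is estimated by matching
the first two moments of log s² (digamma/trigamma identities), and each
gene's variance is shrunk to the posterior

    s~² = (d0 s0² + d s²) / (d0 + d),

giving t_mod = (mean_a - mean_b) / (s~ sqrt(1/n_a + 1/n_b)) on d0 + d
degrees of freedom (normal limit when d0 is infinite).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

from ._stats import bh_adjust
from .core_io import ExpressionMatrix, GeneSetCollection, ValidationError

VAR_FLOOR = 1e-10  # keeps zero-variance genes finite; flagged in the output


@dataclass
class ModeratedTPrior:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s_sq: np.ndarray, d: int) -> ModeratedTPrior:
    """Method-of-moments fit of (d0, s0²) from gene-wise variances."""
    s_sq = np.maximum(np.asarray(s_sq, dtype=float), VAR_FLOOR)
    z = np.log(s_sq)
    e_adj = special.digamma(d / 2.0) - np.log(d / 2.0)
    # degenerate spread (or a single gene): infinite prior df. The prior
    # variance is then the geometric mean of the observed variances, so
    # shrinkage towards an identical target is an exact no-op.
    if z.size < 2:
        return ModeratedTPrior(d0=np.inf, s0_sq=float(np.exp(z.mean())))
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return ModeratedTPrior(d0=np.inf, s0_sq=float(np.exp(z.mean())))
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s0 = z.mean() - e_adj + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    return ModeratedTPrior(d0=float(d0), s0_sq=float(np.exp(log_s0)))


def moderated_ttest(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    comparison: str | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per gene.

    Returns a table with one row per gene: ``log_fc`` (difference of group
    means, log2 units, a minus b), ``t_mod``, ``p_value``, ``q_value``
    (BH, informational), a ``zero_variance`` flag, and the shared prior
    (``d0``, ``s0_sq``).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    A = expr.subset_samples(group_a).frame.to_numpy()
    B = expr.subset_samples(group_b).frame.to_numpy()
    n_a, n_b = A.shape[1], B.shape[1]
    d = n_a + n_b - 2

    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + ((B - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = ss / d
    zero_var = s_sq <= VAR_FLOOR
    s_sq = np.maximum(s_sq, VAR_FLOOR)

    prior = estimate_prior(s_sq, d)
    if np.isinf(prior.d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + d * s_sq) / (prior.d0 + d)
        df_total = prior.d0 + d

    log_fc = mean_a - mean_b
    t_mod = log_fc / np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.minimum(p, 1.0)

    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log_fc": log_fc,
            "t_mod": t_mod,
            "p_value": p,
            "q_value": bh_adjust(p),
            "zero_variance": zero_var,
            "comparison": comparison or "AvsB",
            "d0": prior.d0,
            "s0_sq": prior.s0_sq,
        }
    )


def cluster_degs(
    expr: ExpressionMatrix,
    cluster_labels: pd.Series,
    p_cut: float = 0.05,
    contrasts: str = "pairwise",
) -> tuple[dict[str, set[str]], set[str], dict[str, pd.DataFrame]]:
    """DEG sets between three clusters and their three-way intersection.

    With ``contrasts="pairwise"`` (default, matching a three-circle Venn)
    the three comparisons are AvsB, AvsC, BvsC; ``"one_vs_rest"`` compares
    each cluster against the pooled remainder. A gene enters a comparison's
    DEG set iff its moderated-t p-value is below ``p_cut``; no fold-change
    threshold and no multiplicity adjustment are applied to the selection.
    """
    labels = pd.Series(cluster_labels)
    labels.index = labels.index.astype(str)
    clusters = sorted(labels.unique())
    if len(clusters) != 3:
        raise ValidationError(f"expected exactly 3 clusters, found {len(clusters)}")
    members = {c: labels.index[labels == c].tolist() for c in clusters}
    for c, m in members.items():
        if len(m) < 2:
            raise ValidationError(f"cluster {c!r} has fewer than 2 samples")

    tables: dict[str, pd.DataFrame] = {}
    deg_sets: dict[str, set[str]] = {}
    if contrasts == "pairwise":
        pairs = list(combinations(clusters, 2))
        for a, b in pairs:
            name = f"{a}vs{b}"
            tab = moderated_ttest(expr, members[a], members[b], comparison=name)
            tables[name] = tab
            deg_sets[name] = set(tab.loc[tab["p_value"] < p_cut, "gene_id"])
    elif contrasts == "one_vs_rest":
        for c in clusters:
            rest = [s for s in labels.index if labels[s] != c]
            name = f"{c}vsRest"
            tab = moderated_ttest(expr, members[c], rest, comparison=name)
            tables[name] = tab
            deg_sets[name] = set(tab.loc[tab["p_value"] < p_cut, "gene_id"])
    else:
        raise ValidationError(f"unknown contrasts mode {contrasts!r}")

    shared = set.intersection(*deg_sets.values())
    return deg_sets, shared, tables


def ora_hypergeometric(
    selected: list[str],
    universe: list[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    p = P(X >= k) where X counts how many of the n selected genes fall in
    a set of size K drawn from a universe of size N; q-values are BH
    across sets.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    offenders = [g for g in selected if g not in uni_set]
    if offenders:
        raise ValidationError(f"selected genes outside the universe: {offenders}")
    sel = set(selected)
    usable = sets.restrict_to(uni)
    N, n = len(uni_set), len(sel)
    rows = []
    for name, genes in usable:
        K = len(genes)
        k = len(sel & set(genes))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set_name": name, "overlap": k, "set_size": K,
             "selected_size": n, "universe_size": N, "p_value": min(p, 1.0)}
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].to_numpy())
    return result
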