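"""Synthetic RA/HC cohorts with planted m6A-pattern structure.

The generator emulates, on a log2 expression scale, every statistical
structure the downstream stages assume:

* a case–control contrast: five designated regulators (FMR1, HNRNPC,
  LRPPRC, WTAP, YTHDF3) are mean-shifted in RA versus healthy controls;
* three latent RA subgroups ("A", "B", "C"), each shifting a disjoint
  subset of the 20-gene regulator panel (6 writers-heavy / 7
  eraser-reader / 7 mixed genes);
* immune signature gene blocks whose per-sample activity differs by
  subgroup, realised through a single rank-1 latent factor with block
  loadings +1/-1 and subgroup-dependent latent means (subgroup C highest,
  the adaptive-like phenotype);
* a treated subcohort in which responders carry a systematically lower
  latent signature score.

Noise is Gaussian on the log2 scale: all downstream statistics are rank-
or moment-based and the real inputs are normalised array / log-FPKM
values, so count-level noise models would add nothing the pipeline can
see. Identical (config, seed) reproduces the matrix bit for bit;
different seeds redraw the noise but leave every planted mean unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
    default_regulator_panel,
    validate_metadata,
)

#: regulators consistently differentially expressed between RA and HC
DE_REGULATORS = ("FMR1", "HNRNPC", "LRPPRC", "WTAP", "YTHDF3")

#: disjoint regulator subsets shifted by each planted subgroup (6/7/7)
CLUSTER_REGULATOR_SUBSETS = {
    "A": ("METTL3", "METTL14", "RBM15", "RBM15B", "WTAP", "KIAA1429"),
    "B": ("ALKBH5", "FTO", "YTHDC1", "YTHDC2", "YTHDF1", "YTHDF2", "YTHDF3"),
    "C": ("CBLL1", "ZC3H13", "HNRNPA2B1", "HNRNPC", "FMR1", "LRPPRC", "ELAVL1"),
}

#: per-cluster mean patterns for signature blocks, in units of
#: immune_effect / 2. Positively loaded blocks cycle through these
#: (A, B, C) level triples; every triple has three distinct levels, so
#: each signature gene separates every pair of subgroups, and the block
#: means rise A < B < C (the adaptive-like subgroup C scores highest).
POSITIVE_SET_PATTERNS = ((0.0, 1.0, 2.0), (0.0, 2.0, 1.0), (1.0, 0.0, 2.0))
#: the negatively loaded block falls A > B > C
NEGATIVE_SET_PATTERN = (2.0, 1.0, 0.0)

BASELINE_MEAN = 6.0  # log2 units
LATENT_SD = 0.5  # sample-to-sample spread of the response latent factor


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    n_ra: int = 300
    n_hc: int = 100
    cluster_proportions: tuple[float, float, float] = (0.234, 0.488, 0.278)
    regulator_effect: float = 1.5
    cluster_effect: float = 2.0
    n_background_genes: int = 500
    n_immune_sets: int = 4
    n_signature_genes_per_set: int = 25
    immune_effect: float = 2.0
    noise_sd: float = 1.0
    n_treated: int = 154
    response_score_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ra, self.n_hc, self.n_background_genes,
               self.n_immune_sets, self.n_signature_genes_per_set) < 1:
            raise ValidationError("all synthetic counts must be >= 1")
        props = np.asarray(self.cluster_proportions, dtype=float)
        if props.shape != (3,) or (props < 0).any():
            raise ValidationError("cluster_proportions must be 3 nonnegative reals")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError("cluster_proportions must sum to 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.n_treated < 2 or self.n_treated % 2:
            raise ValidationError("n_treated must be a positive even integer")
        if self.n_treated > self.n_ra:
            raise ValidationError("n_treated cannot exceed n_ra")
        if self.n_immune_sets < 2:
            raise ValidationError("need >= 2 immune sets (one carries loading -1)")


@dataclass
class TruthLabels:
    """Planted assignments recorded alongside a generated cohort."""

    cluster: pd.Series  # RA sample -> {"A","B","C"}
    responder: pd.Series  # treated sample -> bool
    latent_factor: pd.Series  # per sample: the planted signature activity
    # (positive-block minus negative-block mean shift) the m6Ascore recovers
    de_regulators: tuple[str, ...]
    cluster_regulator_subsets: dict[str, tuple[str, ...]]
    signature_sets: dict[str, list[str]]
    set_loadings: dict[str, float]
    planted_means: pd.DataFrame = field(repr=False)  # genes x samples

    def to_frame(self) -> pd.DataFrame:
        """Per-sample truth table (cluster, responder, latent factor)."""
        idx = self.latent_factor.index
        return pd.DataFrame(
            {
                "sample_id": idx,
                "cluster": self.cluster.reindex(idx),
                "responder": self.responder.reindex(idx),
                "latent_factor": self.latent_factor,
            }
        ).reset_index(drop=True)


def _cluster_counts(n_ra: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of RA samples over the 3 subgroups."""
    quotas = np.asarray(proportions, dtype=float) * n_ra
    counts = np.floor(quotas).astype(int)
    remainder = n_ra - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    if (counts == 0).any():
        raise ValidationError(
            f"cluster_proportions {tuple(proportions)} leave an empty cluster at n_ra={n_ra}"
        )
    return counts.tolist()


def _signature_layout(
    config: SyntheticConfig,
) -> tuple[dict[str, list[str]], dict[str, float], dict[str, tuple[float, float, float]]]:
    """Gene sets, their response-factor loadings, and per-cluster levels.

    The last block anti-correlates with the response latent factor so the
    signature has genuine positive and negative sign groups; keeping the
    positive side larger makes score orientation unambiguous.
    """
    sets: dict[str, list[str]] = {}
    loadings: dict[str, float] = {}
    patterns: dict[str, tuple[float, float, float]] = {}
    for s in range(1, config.n_immune_sets + 1):
        name = f"IMM{s}"
        sets[name] = [
            f"IMM{s}_{g:03d}" for g in range(1, config.n_signature_genes_per_set + 1)
        ]
        if s == config.n_immune_sets:
            loadings[name] = -1.0
            patterns[name] = NEGATIVE_SET_PATTERN
        else:
            loadings[name] = 1.0
            patterns[name] = POSITIVE_SET_PATTERNS[(s - 1) % len(POSITIVE_SET_PATTERNS)]
    return sets, loadings, patterns


def generate_gene_sets(config: SyntheticConfig) -> GeneSetCollection:
    """The immune/signature gene sets planted by :func:`generate_cohort`."""
    sets, loadings, _ = _signature_layout(config)
    descriptions = {name: f"synthetic immune block, loading {loadings[name]:+.0f}" for name in sets}
    return GeneSetCollection(sets, descriptions)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, TruthLabels]:
    """Generate one cohort: expression matrix, metadata table, truth labels.

    Returns genes = 20 regulators + background + signature genes, samples =
    RA then HC. The treated subcohort is taken round-robin across the three
    subgroups (so treatment is not confounded with subgroup) and split
    alternately into responders and non-responders.
    """
    rng = np.random.default_rng(config.seed)
    panel = default_regulator_panel()
    regulators = panel["gene_id"].tolist()
    background = [f"BG{g:04d}" for g in range(1, config.n_background_genes + 1)]
    signature_sets, set_loadings, set_patterns = _signature_layout(config)
    signature_genes = [g for genes in signature_sets.values() for g in genes]
    genes = regulators + background + signature_genes

    n_ra, n_hc = config.n_ra, config.n_hc
    ra_samples = [f"RA_{i:04d}" for i in range(1, n_ra + 1)]
    hc_samples = [f"HC_{i:04d}" for i in range(1, n_hc + 1)]
    samples = ra_samples + hc_samples

    counts = _cluster_counts(n_ra, config.cluster_proportions)
    cluster = pd.Series(
        np.repeat(list("ABC"), counts), index=ra_samples, name="cluster"
    )

    # treated subcohort: round-robin over subgroups, then alternate response
    by_rank: list[str] = []
    rank = 0
    members = {c: [s for s in ra_samples if cluster[s] == c] for c in "ABC"}
    while len(by_rank) < n_ra:
        for c in "ABC":
            if rank < len(members[c]):
                by_rank.append(members[c][rank])
        rank += 1
    treated = by_rank[: config.n_treated]
    responder = pd.Series(
        [i % 2 == 0 for i in range(len(treated))], index=treated, name="responder"
    )

    # response latent factor: deterministic responder offset + wobble
    latent_mean = pd.Series(0.0, index=samples)
    latent_mean[responder.index[responder]] -= config.response_score_shift

    # planted mean matrix (seed-independent)
    cluster_idx = {"A": 0, "B": 1, "C": 2}
    scale = config.immune_effect / 2.0
    means = pd.DataFrame(BASELINE_MEAN, index=genes, columns=samples, dtype=float)
    means.loc[list(DE_REGULATORS), ra_samples] += config.regulator_effect
    for c, subset in CLUSTER_REGULATOR_SUBSETS.items():
        means.loc[list(subset), members[c]] += config.cluster_effect
    for name, block in signature_sets.items():
        # per-cluster block level + responder offset through the loading
        for c, rows in members.items():
            means.loc[block, rows] += scale * set_patterns[name][cluster_idx[c]]
        means.loc[block] += set_loadings[name] * latent_mean.to_numpy()

    # noise: per-sample latent wobble on signature blocks + iid gene noise
    latent_eps = rng.normal(0.0, LATENT_SD, size=len(samples))
    values = means.to_numpy().copy()
    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    gene_index = pd.Index(genes)
    for name, block in signature_sets.items():
        rows = gene_index.get_indexer(block)
        values[rows] += set_loadings[name] * latent_eps

    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    # the planted signature activity the fitted score should recover:
    # mean positive-block level minus mean negative-block level, plus the
    # response factor through both block signs
    pos_sets = [n for n, w in set_loadings.items() if w > 0]
    neg_sets = [n for n, w in set_loadings.items() if w < 0]
    activity = pd.Series(0.0, index=samples)
    for c, rows in members.items():
        pos_level = np.mean([set_patterns[n][cluster_idx[c]] for n in pos_sets])
        neg_level = np.mean([set_patterns[n][cluster_idx[c]] for n in neg_sets])
        activity[rows] = scale * (pos_level - neg_level)
    activity += 2.0 * (latent_mean + latent_eps)

    das28_esr = np.clip(rng.normal(4.5, 1.2, size=n_ra), 0.1, 10.0)
    das28_crp = np.clip(rng.normal(4.0, 1.1, size=n_ra), 0.1, 10.0)
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "disease_status": ["RA"] * n_ra + ["HC"] * n_hc,
            "cohort_id": "synth1",
            "das28_esr": list(das28_esr) + [np.nan] * n_hc,
            "das28_crp": list(das28_crp) + [np.nan] * n_hc,
            "treatment": [
                "infliximab" if s in responder.index else "none" for s in samples
            ],
            "response": [
                ("responder" if responder[s] else "non_responder")
                if s in responder.index
                else np.nan
                for s in samples
            ],
        }
    )
    meta = validate_metadata(meta)

    truth = TruthLabels(
        cluster=cluster,
        responder=responder,
        latent_factor=activity.rename("latent_factor"),
        de_regulators=DE_REGULATORS,
        cluster_regulator_subsets=dict(CLUSTER_REGULATOR_SUBSETS),
        signature_sets=signature_sets,
        set_loadings=set_loadings,
        planted_means=means,
    )
    return expr, meta, truth
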