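"""Config-driven orchestration of the full synthetic experiment.

Stage order mirrors the analysis: simulate -> merge -> diagnose ->
cluster -> ssgsea/compare -> deg/ora -> score -> respond (-> panel when
panel genes are present). One master seed deterministically spawns a
per-stage seed (stage-name hashing), so any stage can be rerun in
isolation and a rerun with identical config reproduces every numeric
output.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus, deg, diagnostics, score, ssgsea
from .core_io import (
    AnalysisConfig,
    ExpressionMatrix,
    ValidationError,
    default_checkpoint_panel,
    default_hla_panel,
    default_regulator_panel,
    merge_cohorts,
)
from .synthetic import SyntheticConfig, TruthLabels, generate_cohort, generate_gene_sets

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunReport:
    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    diagnosis_auc: float | None = None
    train_size: int | None = None
    test_size: int | None = None
    chosen_k: int | None = None
    cluster_sizes: dict[str, int] = field(default_factory=dict)
    deg_counts: dict[str, int] = field(default_factory=dict)
    n_shared_degs: int | None = None
    signature_block_sizes: dict[str, int] = field(default_factory=dict)
    response: dict = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


@dataclass
class PipelineOutputs:
    """In-memory results of a full pipeline run."""

    report: RunReport
    expr: ExpressionMatrix
    metadata: pd.DataFrame
    truth: TruthLabels | None
    cluster_labels: pd.Series
    consensus: consensus.ConsensusResult
    enrichment: ssgsea.EnrichmentProfile
    enrichment_stats: pd.DataFrame
    shared_degs: list[str]
    signature_model: score.SignatureModel
    scores: pd.DataFrame
    response: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    synth: SyntheticConfig,
    config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
    run_boruta: bool = True,
) -> PipelineOutputs:
    """Run every stage on one synthetic cohort and return all results.

    When ``outdir`` is given the stage artifacts (matrix, metadata,
    labels, statistics, scores, report) are written beneath it and listed
    in the report manifest.
    """
    config = config or AnalysisConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={"analysis": asdict(config), "synthetic": asdict(synth)})
    master = config.random_seed

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # annotate with the failing stage
            raise StageError(name, exc) from exc
        report.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        return result

    def emit(name: str, writer) -> None:
        if out is None:
            return
        path = out / name
        writer(path)
        report.manifest[name] = str(path)

    # --- simulate -----------------------------------------------------
    report.seeds["simulate"] = synth.seed
    expr, meta, truth = run_stage("simulate", lambda: generate_cohort(synth))
    gene_sets = generate_gene_sets(synth)
    emit("expression.tsv", expr.to_tsv)
    emit("metadata.csv", lambda p: meta.to_csv(p, index=False))
    emit("truth.csv", lambda p: truth.to_frame().to_csv(p, index=False))
    emit("gene_sets.gmt", gene_sets.to_gmt)

    # --- merge (single synthetic cohort: identity with validation) ----
    expr = run_stage("merge", lambda: merge_cohorts([expr], meta, scale_within_cohort=False))

    panel = default_regulator_panel()
    regulators = panel["gene_id"].tolist()
    ra_samples = meta.loc[meta["disease_status"] == "RA", "sample_id"].tolist()

    # --- diagnose ------------------------------------------------------
    seed = stage_seed(master, "diagnose")
    report.seeds["diagnose"] = seed

    def diagnose():
        labels = pd.Series(
            meta["disease_status"].to_numpy(), index=meta["sample_id"].to_numpy()
        )
        split = diagnostics.stratified_split(labels, config.split_fraction, seed)
        feats = expr.subset_genes(regulators).frame
        X_train = feats[split.train_sample_ids].to_numpy().T
        y_train = labels[split.train_sample_ids].to_numpy()
        X_bal, y_bal = diagnostics.smote_oversample(
            X_train, y_train, k=config.smote_k, seed=seed
        )
        model = diagnostics.train_classifier(X_bal, y_bal, config.n_trees, seed)
        X_test = feats[split.test_sample_ids].to_numpy().T
        y_test = labels[split.test_sample_ids].to_numpy()
        proba = model.predict_proba(X_test)[:, list(model.classes_).index("RA")]
        curve = diagnostics.roc_auc(proba, y_test == "RA", positive=True)
        return split, curve

    split, curve = run_stage("diagnose", diagnose)
    report.diagnosis_auc = curve.auc
    report.train_size = len(split.train_sample_ids)
    report.test_size = len(split.test_sample_ids)
    emit(
        "roc_points.csv",
        lambda p: pd.DataFrame(
            {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
        ).to_csv(p, index=False),
    )

    # --- cluster (RA samples over the regulator panel) -----------------
    seed = stage_seed(master, "cluster")
    report.seeds["cluster"] = seed

    def cluster():
        X = expr.subset_genes(regulators).frame[ra_samples].to_numpy().T
        return consensus.run_consensus(
            X,
            k_min=config.k_min,
            k_max=config.k_max,
            H=config.consensus_h,
            p_item=config.consensus_p_item,
            base_method=config.base_method,
            delta_threshold=config.delta_threshold,
            seed=seed,
        )

    cons = run_stage("cluster", cluster)
    cluster_labels = pd.Series(
        [f"C{c}" for c in cons.labels], index=ra_samples, name="m6a_cluster"
    )
    report.chosen_k = cons.chosen_k
    report.cluster_sizes = cluster_labels.value_counts().to_dict()
    emit(
        "cluster_labels.csv",
        lambda p: cluster_labels.rename_axis("sample_id").to_csv(p),
    )
    emit(
        "cluster_diagnostics.csv",
        lambda p: pd.DataFrame(
            {
                "k": cons.k_range,
                "cdf_area": [cons.cdf_area[k] for k in cons.k_range],
                "delta_area": [cons.delta_area[k] for k in cons.k_range],
                "silhouette": [cons.silhouette[k] for k in cons.k_range],
            }
        ).to_csv(p, index=False),
    )

    # --- ssgsea + group comparison -------------------------------------
    def immune():
        profile = ssgsea.ssgsea_score(
            expr.subset_samples(ra_samples), gene_sets,
            alpha=config.ssgsea_alpha, normalize=True,
        )
        stats_tab = ssgsea.compare_groups(profile.scores, cluster_labels)
        return profile, stats_tab

    profile, enrich_stats = run_stage("ssgsea", immune)
    emit("ssgsea_scores.tsv", lambda p: profile.scores.to_csv(p, sep="\t"))
    emit("ssgsea_comparison.csv", lambda p: enrich_stats.to_csv(p, index=False))

    # --- DEGs + ORA -----------------------------------------------------
    def degs():
        if cons.chosen_k != 3:
            raise ValidationError(
                f"DEG intersection is defined over 3 clusters; consensus chose k={cons.chosen_k}"
            )
        ra_expr = expr.subset_samples(ra_samples)
        deg_sets, shared, tables = deg.cluster_degs(
            ra_expr, cluster_labels, p_cut=config.deg_p_cut
        )
        ora = deg.ora_hypergeometric(sorted(shared), ra_expr.gene_ids, gene_sets)
        return deg_sets, sorted(shared), tables, ora

    deg_sets, shared, deg_tables, ora_tab = run_stage("deg", degs)
    report.deg_counts = {name: len(s) for name, s in deg_sets.items()}
    report.n_shared_degs = len(shared)
    emit("shared_degs.txt", lambda p: Path(p).write_text("\n".join(shared) + "\n"))
    emit(
        "deg_tables.csv",
        lambda p: pd.concat(deg_tables.values(), ignore_index=True).to_csv(p, index=False),
    )
    emit("ora.csv", lambda p: ora_tab.to_csv(p, index=False))

    # --- m6Ascore -------------------------------------------------------
    seed = stage_seed(master, "score")
    report.seeds["score"] = seed

    def build_score():
        ra_expr = expr.subset_samples(ra_samples)
        pos, neg = score.assign_sign_groups(ra_expr.subset_genes(shared), r_min=config.r_min)
        if run_boruta:
            pos, neg = _prune_blocks(ra_expr, pos, neg, cluster_labels, config, seed)
        model = score.fit_signature(ra_expr, pos, neg)
        scored = score.score_samples(model, ra_expr)
        return model, scored

    model, scored = run_stage("score", build_score)
    report.signature_block_sizes = {
        "positive": len(model.positive_genes),
        "negative": len(model.negative_genes),
    }
    emit("scores.csv", lambda p: scored.to_csv(p, index=False, float_format="%.10g"))
    emit(
        "signature_model.json",
        lambda p: Path(p).write_text(
            json.dumps(
                {
                    side: {
                        "genes": blk.genes,
                        "means": blk.means.tolist(),
                        "loadings": blk.loadings.tolist(),
                        "sign": blk.sign,
                    }
                    for side, blk in (
                        ("positive", model.positive),
                        ("negative", model.negative),
                    )
                    if blk is not None
                },
                indent=2,
            )
        ),
    )

    # --- response -------------------------------------------------------
    def respond():
        resp = pd.Series(
            meta["response"].to_numpy(), index=meta["sample_id"].to_numpy()
        ).dropna()
        return score.response_analysis(scored, resp)

    response = run_stage("respond", respond)
    report.response = response
    emit("response.json", lambda p: Path(p).write_text(json.dumps(response, indent=2)))

    # --- panel comparisons (only when panel genes exist in the matrix) --
    groups = pd.Series(scored["group"].to_numpy(), index=scored["sample_id"].to_numpy())
    for panel_name, genes in (
        ("hla", default_hla_panel()),
        ("checkpoint", default_checkpoint_panel()),
    ):
        if not any(g in expr.frame.index for g in genes):
            logger.info("panel %r has no gene in the matrix; stage skipped", panel_name)
            continue
        tab, skipped = run_stage(
            f"panel_{panel_name}",
            lambda genes=genes: score.panel_comparison(
                expr.subset_samples(ra_samples), groups, genes
            ),
        )
        emit(f"panel_{panel_name}.csv", lambda p, tab=tab: tab.to_csv(p, index=False))

    if out is not None:
        report.to_json(out / "run_report.json")
        report.manifest["run_report.json"] = str(out / "run_report.json")
        missing = [p for p in report.manifest.values() if not Path(p).exists()]
        assert not missing, f"manifest entries missing on disk: {missing}"

    return PipelineOutputs(
        report=report,
        expr=expr,
        metadata=meta,
        truth=truth,
        cluster_labels=cluster_labels,
        consensus=cons,
        enrichment=profile,
        enrichment_stats=enrich_stats,
        shared_degs=shared,
        signature_model=model,
        scores=scored,
        response=response,
    )


def _prune_blocks(
    ra_expr: ExpressionMatrix,
    pos: list[str],
    neg: list[str],
    cluster_labels: pd.Series,
    config: AnalysisConfig,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Boruta-prune each sign group against the m6A cluster label.

    A block where nothing is selected keeps all its genes (logged), so an
    overly strict run cannot empty the signature.
    """
    target = cluster_labels.loc[ra_expr.sample_ids]
    pruned = []
    for block in (pos, neg):
        if not block:
            pruned.append(block)
            continue
        feats = ra_expr.subset_genes(block).frame.T  # samples x genes
        result = score.boruta_select(
            feats,
            target.to_numpy(),
            max_iter=config.boruta_max_iter,
            alpha=config.boruta_alpha,
            seed=seed,
        )
        kept = sorted(result.selected)
        if not kept:
            logger.info("Boruta selected nothing in a block of %d genes; keeping all", len(block))
            kept = block
        pruned.append(kept)
    return pruned[0], pruned[1]
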