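"""The m6Ascore: sign-grouped signature genes, Boruta selection, and the
PCA-subtraction score used to stratify samples and drug response.

Shared DEGs are split into a positively and a negatively correlated sign
group (sign of each gene's Pearson correlation with the first principal
axis of the z-scored DEG submatrix); each group is optionally pruned by
Boruta; a first principal component is fitted per group; and the score is

    score_s = PC1_pos(s) - PC1_neg(s),

with each PC1 oriented to correlate positively with its block's mean
expression (the eigenvector sign is otherwise arbitrary). Samples are
split into high/low groups at the median score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ._stats import bh_adjust, ranksum_p
from .core_io import ExpressionMatrix, ValidationError
from .diagnostics import roc_auc


@dataclass
class SignatureBlock:
    genes: list[str]
    means: np.ndarray  # per-gene centering vector
    loadings: np.ndarray  # unit-norm PC1 loadings
    sign: float  # orientation, +1 or -1

    def scores(self, expr: ExpressionMatrix) -> np.ndarray:
        missing = [g for g in self.genes if g not in expr.frame.index]
        if missing:
            raise ValidationError(f"model genes missing from matrix: {missing}")
        X = expr.frame.loc[self.genes].to_numpy().T  # samples x genes
        return self.sign * ((X - self.means) @ self.loadings)


@dataclass
class SignatureModel:
    positive: SignatureBlock | None
    negative: SignatureBlock | None

    @property
    def positive_genes(self) -> list[str]:
        return list(self.positive.genes) if self.positive else []

    @property
    def negative_genes(self) -> list[str]:
        return list(self.negative.genes) if self.negative else []


def assign_sign_groups(
    expr: ExpressionMatrix,
    r_min: float = 0.3,
) -> tuple[list[str], list[str]]:
    """Split genes into positively / negatively correlated signature groups.

    The reference vector is the first principal axis of the z-scored
    gene-by-sample submatrix (label-free and self-consistent); each gene's
    group is the sign of its Pearson correlation with that axis, genes with
    |r| < r_min are dropped, and the orientation is fixed so the positive
    group is the larger one (tie: the group holding the lexically smallest
    gene).
    """
    if len(expr.gene_ids) < 2:
        raise ValidationError("need at least 2 genes to assign sign groups")
    if len(expr.sample_ids) < 3:
        raise ValidationError("need at least 3 samples to assign sign groups")
    X = expr.frame.to_numpy()  # genes x samples
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Z = (X - mu) / np.where(sd == 0, 1.0, sd)
    # first principal axis over samples
    _, _, vt = np.linalg.svd(Z - Z.mean(axis=1, keepdims=True), full_matrices=False)
    axis = vt[0]  # per-sample scores of PC1

    r = np.zeros(len(expr.gene_ids))
    axis_sd = axis.std(ddof=0)
    for i in range(len(r)):
        gsd = Z[i].std(ddof=0)
        if gsd == 0 or axis_sd == 0:
            r[i] = 0.0
        else:
            r[i] = float(np.corrcoef(Z[i], axis)[0, 1])
    genes = np.asarray(expr.gene_ids)
    keep = np.abs(r) >= r_min
    if not keep.any():
        raise ValidationError(
            f"every gene fell below |r| >= {r_min}; lower r_min to retain signature genes"
        )
    pos = sorted(genes[keep & (r > 0)].tolist())
    neg = sorted(genes[keep & (r < 0)].tolist())
    swap = len(neg) > len(pos) or (
        len(neg) == len(pos) and neg and pos and min(neg) < min(pos)
    )
    if swap:
        pos, neg = neg, pos
    return pos, neg


@dataclass
class BorutaResult:
    """Feature statuses after the shadow-feature importance test."""

    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    tentative_resolved: list[str]  # tentatives whose median importance beats
    # the median of the per-iteration shadow maxima
    hits: dict[str, int] = field(default_factory=dict)
    n_iter: int = 0

    @property
    def selected(self) -> list[str]:
        """Confirmed features plus upward-resolved tentatives."""
        return self.confirmed + self.tentative_resolved


def boruta_select(
    features: pd.DataFrame,
    target: pd.Series | np.ndarray,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    n_trees: int = 100,
) -> BorutaResult:
    """All-relevant feature selection against shuffled shadow features.

    Each iteration appends a permuted copy of every feature, fits a random
    forest, and scores a feature a "hit" when its impurity importance
    exceeds the maximum shadow importance. After ``max_iter`` iterations a
    two-sided binomial test of the hit count against Binomial(iters, 0.5)
    confirms (significantly more hits) or rejects (significantly fewer)
    each feature; the remaining tentative features are additionally
    resolved by comparing their median importance to the median of the
    per-iteration shadow maxima (reported separately from confirmation).
    """
    X = pd.DataFrame(features)
    y = np.asarray(target)
    if X.shape[0] < 5:
        raise ValidationError("Boruta needs at least 5 samples")
    if X.shape[1] < 1:
        raise ValidationError("Boruta needs at least 1 feature")
    if len(np.unique(y)) < 2:
        raise ValidationError("target is constant; nothing to select for")

    classification = not np.issubdtype(y.dtype, np.number) or len(np.unique(y)) <= 8
    rng = np.random.default_rng(seed)
    n, p = X.shape
    hits = np.zeros(p, dtype=int)
    imp_history = np.zeros((max_iter, p))
    shadow_max_history = np.zeros(max_iter)
    Xv = X.to_numpy(dtype=float)
    for it in range(max_iter):
        shadow = Xv[rng.permuted(np.tile(np.arange(n), (p, 1)).T, axis=0),
                    np.arange(p)]
        full = np.hstack([Xv, shadow])
        forest_cls = RandomForestClassifier if classification else RandomForestRegressor
        forest = forest_cls(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31)),
        )
        forest.fit(full, y)
        imp = forest.feature_importances_
        real, sh = imp[:p], imp[p:]
        shadow_max = sh.max()
        hits += real > shadow_max
        imp_history[it] = real
        shadow_max_history[it] = shadow_max

    confirmed: list[str] = []
    rejected: list[str] = []
    tentative: list[str] = []
    resolved: list[str] = []
    median_shadow_max = np.median(shadow_max_history)
    for j, name in enumerate(X.columns):
        res = stats.binomtest(int(hits[j]), max_iter, 0.5, alternative="two-sided")
        if res.pvalue < alpha and hits[j] > max_iter / 2:
            confirmed.append(str(name))
        elif res.pvalue < alpha:
            rejected.append(str(name))
        else:
            tentative.append(str(name))
            if np.median(imp_history[:, j]) > median_shadow_max:
                resolved.append(str(name))
    return BorutaResult(
        confirmed=confirmed,
        rejected=rejected,
        tentative=tentative,
        tentative_resolved=resolved,
        hits={str(c): int(h) for c, h in zip(X.columns, hits)},
        n_iter=max_iter,
    )


def fit_signature(
    expr: ExpressionMatrix,
    positive_genes: list[str],
    negative_genes: list[str],
) -> SignatureModel:
    """Fit per-block centering and PC1 loadings for the subtraction score."""
    if len(expr.sample_ids) < 3:
        raise ValidationError("need at least 3 samples to fit the signature")
    overlap = set(positive_genes) & set(negative_genes)
    if overlap:
        raise ValidationError(f"sign groups overlap: {sorted(overlap)}")
    if not positive_genes and not negative_genes:
        raise ValidationError("both sign groups are empty")

    def fit_block(genes: list[str]) -> SignatureBlock | None:
        if not genes:
            return None
        X = expr.subset_genes(genes).frame.to_numpy().T  # samples x genes
        means = X.mean(axis=0)
        Xc = X - means
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = vt[0]
        scores = Xc @ loadings
        block_mean = X.mean(axis=1)
        if scores.std(ddof=0) == 0 or block_mean.std(ddof=0) == 0:
            sign = 1.0
        else:
            sign = 1.0 if np.corrcoef(scores, block_mean)[0, 1] >= 0 else -1.0
        return SignatureBlock(list(genes), means, loadings, sign)

    return SignatureModel(positive=fit_block(positive_genes),
                          negative=fit_block(negative_genes))


def score_samples(model: SignatureModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample m6Ascore and median-split high/low group (ties -> low)."""
    n = len(expr.sample_ids)
    pos = model.positive.scores(expr) if model.positive else np.zeros(n)
    neg = model.negative.scores(expr) if model.negative else np.zeros(n)
    score = pos - neg
    median = float(np.median(score))
    group = np.where(score > median, "high", "low")
    return pd.DataFrame(
        {"sample_id": expr.sample_ids, "score": score, "group": group}
    )


def response_analysis(scores: pd.DataFrame, response: pd.Series) -> dict:
    """Wilcoxon test and ROC of the score against treatment response.

    Lower scores are expected in responders, so the ROC ranks -score as
    the predictor of response (AUC > 0.5 means low score predicts
    response).
    """
    response = pd.Series(response)
    response.index = response.index.astype(str)
    tab = scores.set_index("sample_id")["score"]
    common = [s for s in tab.index if s in response.index and pd.notna(response[s])]
    tab = tab[common]
    resp = response[common]
    classes = set(resp.unique())
    if classes != {"responder", "non_responder"}:
        raise ValidationError(
            f"need both responder and non_responder present, found {sorted(classes)}"
        )
    r_scores = tab[resp == "responder"].to_numpy()
    nr_scores = tab[resp == "non_responder"].to_numpy()
    if len(r_scores) < 2 or len(nr_scores) < 2:
        raise ValidationError("each response class needs at least 2 samples")
    p = ranksum_p(r_scores, nr_scores)
    curve = roc_auc(-tab.to_numpy(), (resp == "responder").to_numpy(), positive=True)
    return {
        "wilcoxon_p": p,
        "roc_auc": curve.auc,
        "median_responder": float(np.median(r_scores)),
        "median_non_responder": float(np.median(nr_scores)),
        "n_responder": int(len(r_scores)),
        "n_non_responder": int(len(nr_scores)),
    }


def panel_comparison(
    expr: ExpressionMatrix,
    score_groups: pd.Series,
    panel: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene high-vs-low comparison over a gene panel (e.g. HLA genes).

    Returns the statistics table (Wilcoxon p, BH q, signed median
    difference high - low) and the list of panel genes absent from the
    matrix (skipped).
    """
    groups = pd.Series(score_groups)
    groups.index = groups.index.astype(str)
    present = [g for g in panel if g in expr.frame.index]
    skipped = [g for g in panel if g not in expr.frame.index]
    if not present:
        raise ValidationError("no panel gene is present in the expression matrix")
    high = groups.index[groups == "high"].tolist()
    low = groups.index[groups == "low"].tolist()
    if len(high) < 2 or len(low) < 2:
        raise ValidationError("both score groups need at least 2 samples")
    rows = []
    for g in present:
        x = expr.frame.loc[g]
        hi, lo = x[high].to_numpy(), x[low].to_numpy()
        rows.append(
            {
                "gene_id": g,
                "p_value": ranksum_p(hi, lo),
                "median_diff_high_minus_low": float(np.median(hi) - np.median(lo)),
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table, skipped
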