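"""RA-vs-HC diagnosis model: stratified split, SMOTE, random forest, ROC.

The classifier itself is an ordinary random forest (delegated to
scikit-learn); the operations around it — the per-class largest-remainder
split arithmetic, the SMOTE interpolation contract and the tie-corrected
Mann–Whitney AUC — are implemented here so their behaviour is fully
specified and testable. SMOTE is applied to the training set only, after
splitting; oversampling before the split would leak synthetic copies of
test-set neighbours into training, so that ordering is not offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .core_io import ValidationError


@dataclass
class SplitResult:
    train_sample_ids: list[str]
    test_sample_ids: list[str]
    seed: int


@dataclass
class ROCCurve:
    """ROC curve from a descending threshold sweep plus its AUC.

    ``auc`` is the tie-corrected Mann–Whitney concordance
    (P[score_pos > score_neg] + 0.5 P[tie]); the trapezoidal integral of
    the (fpr, tpr) polyline equals it to numerical precision because tied
    scores collapse into a single diagonal segment.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


_FP_EPS = 1e-9  # guards half-up rounding against binary-float droop (0.7*1335)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5 + _FP_EPS))


def stratified_split(labels: pd.Series, fraction: float, seed: int) -> SplitResult:
    """Stratified train/test split with largest-remainder reconciliation.

    The total training count is round(fraction * n) (half up); per-class
    counts start at floor(fraction * n_class) and the remaining slots go to
    the classes with the largest fractional remainders, so per-class counts
    equal round(fraction * n_class) whenever that is consistent with the
    total. A 70/30 split of 1,335 samples therefore yields 935 train / 400
    test.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    labels = pd.Series(labels)
    labels.index = labels.index.astype(str)
    class_counts = labels.value_counts()
    if (class_counts < 2).any():
        small = class_counts[class_counts < 2].index.tolist()
        raise ValidationError(f"classes with fewer than 2 samples: {small}")
    n_total = len(labels)
    total_train = _round_half_up(fraction * n_total)

    classes = list(class_counts.index)
    quotas = {c: fraction * class_counts[c] for c in classes}
    take = {c: math.floor(quotas[c] + _FP_EPS) for c in classes}
    leftover = total_train - sum(take.values())
    by_remainder = sorted(classes, key=lambda c: (-(quotas[c] - take[c]), str(c)))
    for c in by_remainder[:leftover]:
        take[c] += 1

    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for c in classes:
        members = np.asarray(labels.index[labels == c])
        perm = rng.permutation(len(members))
        train.extend(members[perm[: take[c]]])
        test.extend(members[perm[take[c]:]])
    return SplitResult(sorted(train), sorted(test), seed)


def smote_oversample(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary problem by SMOTE interpolation of the minority class.

    Each synthetic point is x + u (x' - x) with u ~ Uniform(0, 1), x a
    minority sample and x' one of its k nearest minority neighbours
    (Euclidean; k is capped at minority size - 1). Original rows are
    preserved unchanged and come first in the output.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and labels disagree in length")
    values, counts = np.unique(y, return_counts=True)
    if len(values) != 2:
        raise ValidationError("SMOTE expects exactly two classes")
    minority = values[np.argmin(counts)]
    majority_n = counts.max()
    minority_idx = np.flatnonzero(y == minority)
    n_min = len(minority_idx)
    if n_min < 2:
        raise ValidationError("minority class must have >= 2 samples to interpolate")
    n_new = int(majority_n - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    if k < 1:
        raise ValidationError("k must be >= 1")
    k_eff = min(k, n_min - 1)

    Xmin = X[minority_idx]
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    neighbours = nn.kneighbors(Xmin, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.random(n_new)
    x = Xmin[base]
    x_prime = Xmin[neighbours[base, pick]]
    synthetic = x + u[:, None] * (x_prime - x)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the random-forest diagnosis model (sqrt(p) features per split)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("need at least two classes to train a classifier")
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains non-finite values")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed
    )
    model.fit(X, y)
    return model


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive=1) -> ROCCurve:
    """ROC curve and tie-corrected Mann–Whitney AUC for binary labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute a ROC curve")

    ranks = stats.rankdata(s)  # midranks
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc))
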