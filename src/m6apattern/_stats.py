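"""Small shared statistical helpers (rank tests, BH adjustment)."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value with midrank tie handling.

    Exact enumeration when there are no ties; otherwise the normal
    approximation with tie-corrected variance and no continuity correction
    (so identical distributions with shared values give p = 1 exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
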