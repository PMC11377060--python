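"""Statistical helpers used on model outputs.

Thin, guarded wrappers around the rank and variance tests applied throughout
the analyses (Kruskal-Wallis, Wilcoxon signed-rank, Bartlett, Student's t)
plus a Pearson correlation that reports undefined values as NaN instead of
silently returning zero for constant vectors.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps


def safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.max() == x.min() or y.max() == y.min():
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc * xc).sum())
    ny = np.sqrt((yc * yc).sum())
    return float((xc * yc).sum() / (nx * ny))


def pairwise_pearson(rows: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise Pearson r of the rows of a matrix."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(rows)
    bad = rows.max(axis=1) == rows.min(axis=1)
    c[bad, :] = np.nan
    c[:, bad] = np.nan
    return c[iu]


def kruskal_test(*samples: Sequence[float]) -> Tuple[float, float]:
    """Kruskal-Wallis H and p; identical all-equal input yields p = 1."""
    try:
        h, p = sps.kruskal(*samples)
    except ValueError:  # all values identical
        return 0.0, 1.0
    if np.isnan(h):  # fully tied data
        return 0.0, 1.0
    return float(h), float(p)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]
                         ) -> Tuple[float, float]:
    """Paired Wilcoxon signed-rank test; all-zero differences yield p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    stat, p = sps.wilcoxon(x, y)
    return float(stat), float(p)


def bartlett_test(*samples: Sequence[float]) -> Tuple[float, float]:
    stat, p = sps.bartlett(*samples)
    return float(stat), float(p)


def student_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Student's t test (equal variances, as classically printed)."""
    stat, p = sps.ttest_ind(x, y)
    return float(stat), float(p)
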