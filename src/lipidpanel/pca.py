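"""PCA-based group-separation analysis.

A sweep over data transforms (none/log/sqrt/reciprocal) and centering
(on/off) scores the first two principal components of each setting by how
well they segregate a binary contrast (dementia vs rest): Mann-Whitney
rank-sum p-value, AUC-ROC, and area under the precision-recall curve.
Per-feature squared correlations with a component provide the importance
measure consumed by the feature-selection stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

__all__ = [
    "PcaSweepResult",
    "pca",
    "separation_quality",
    "pca_sweep",
    "feature_pc_r2",
]

_TRANSFORMS = {
    "none": lambda x: x,
    "log": np.log,
    "sqrt": np.sqrt,
    "reciprocal": lambda x: 1.0 / x,
}


@dataclass
class PcaSweepResult:
    table: pd.DataFrame  # one row per (transform, centering, component)
    best_setting: tuple[str, bool]  # (transform, centered)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def pca(matrix, center: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components via singular-value decomposition.

    With ``center=False`` the SVD is taken of the raw matrix, so the first
    component tracks the overall magnitude axis and "variance explained"
    is the fraction of total (uncentered) sum of squares. Sign convention:
    the largest-magnitude loading of each component is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if center:
        X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("matrix has rank 0")
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    var = s**2 / np.sum(s**2)
    return scores, Vt.T, var


def separation_quality(component_scores, binary_labels) -> tuple[float, float, float]:
    """Score how well a component separates two groups.

    Returns (Mann-Whitney two-sided p, AUC-ROC, AUPR). The AUC is computed
    from the rank statistic and oriented so that AUC >= 0.5; the AUPR
    integrates the precision-recall curve with the minority class as the
    positive class, on identically oriented scores.
    """
    scores = np.asarray(component_scores, dtype=float)
    y = np.asarray(binary_labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be nonempty")
    u = stats.mannwhitneyu(scores[y], scores[~y], alternative="two-sided")
    auc = u.statistic / (n1 * n0)
    oriented = scores if auc >= 0.5 else -scores
    auc = max(auc, 1.0 - auc)
    positive = y if n1 <= n0 else ~y
    if n1 > n0:
        oriented = -oriented
    aupr = average_precision_score(positive, oriented)
    return float(u.pvalue), float(auc), float(aupr)


def pca_sweep(matrix, binary_labels, n_components: int = 2) -> PcaSweepResult:
    """Evaluate transform x centering settings by PC-wise group separation.

    Each valid setting is scored on its first ``n_components`` components;
    settings whose transform is undefined for the data range are skipped
    with a warning. The best setting maximizes AUC, with the p-value as
    tiebreaker.
    """
    X = np.asarray(matrix, dtype=float)
    rows = []
    for tname, func in _TRANSFORMS.items():
        if tname != "none" and np.any(X <= 0):
            warnings.warn(f"transform {tname!r} invalid for non-positive data; skipped")
            continue
        T = func(X)
        for center in (False, True):
            scores, _, var = pca(T, center=center)
            for comp in range(min(n_components, scores.shape[1])):
                p, auc, aupr = separation_quality(scores[:, comp], binary_labels)
                rows.append(
                    {
                        "transform": tname,
                        "centered": center,
                        "component": comp + 1,
                        "p": p,
                        "auc_roc": auc,
                        "aupr": aupr,
                        "variance_explained": float(var[comp]),
                    }
                )
    if not rows:
        raise ValueError("no valid transform settings for this data")
    table = pd.DataFrame(rows)
    best = table.sort_values(["auc_roc", "p"], ascending=[False, True]).iloc[0]
    return PcaSweepResult(table, (str(best["transform"]), bool(best["centered"])))


def feature_pc_r2(matrix, component_scores) -> np.ndarray:
    """Squared Pearson correlation of each feature with the component scores."""
    X = np.asarray(matrix, dtype=float)
    s = np.asarray(component_scores, dtype=float)
    s_centered = s - s.mean()
    denom_s = np.sqrt(np.sum(s_centered**2))
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        x = X[:, j] - X[:, j].mean()
        denom_x = np.sqrt(np.sum(x**2))
        if denom_x == 0 or denom_s == 0:
            warnings.warn(f"constant column {j}; r^2 set to 0")
            out[j] = 0.0
        else:
            out[j] = (np.dot(x, s_centered) / (denom_x * denom_s)) ** 2
    return out
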