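"""Ward clustering, progeny-based cluster-number selection, and
cluster-vs-diagnosis association testing.

The progeny stability score follows the progeny-clustering idea: synthetic
cluster members ("progenies") are built by resampling each feature
independently within a cluster, the progenies are re-clustered, and a
cluster number is stable when progenies of common origin stay together
while progenies of different origin separate.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

__all__ = [
    "StabilityProfile",
    "AssociationResult",
    "ward_cluster",
    "progeny_stability",
    "choose_k",
    "silhouette_coefficient",
    "association_test",
]


@dataclass
class StabilityProfile:
    k_range: list[int]
    score: dict[int, float]
    score_sd: dict[int, float]
    gap: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    criterion: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=float)


@dataclass
class AssociationResult:
    contingency: pd.DataFrame
    chi2: float
    df: int
    p: float
    residuals: pd.DataFrame
    flagged_cells: list[tuple[str, str, float]]

    def to_json(self, path) -> None:
        doc = {
            "contingency": self.contingency.to_dict(),
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "residuals": self.residuals.to_dict(),
            "flagged_cells": self.flagged_cells,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=float)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 by decreasing size (ties: first occurrence)."""
    uniq, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == u) for u in uniq])
    order = np.lexsort((first, -counts))
    mapping = {uniq[o]: i for i, o in enumerate(order)}
    return np.array([mapping[l] for l in labels])


def ward_cluster(matrix, k: int) -> np.ndarray:
    """Agglomerative Ward clustering (Euclidean) into k groups.

    Labels are 0-based and deterministic: clusters are numbered by
    decreasing size.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    Z = linkage(X, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    return _relabel_by_size(raw)


def _progeny_counts(X, labels, k, n_progenies, rng) -> np.ndarray:
    """One progeny round: resample progenies per cluster, re-cluster, and
    count co-clustered pairs among same-origin and different-origin pairs.

    Returns [same_co, same_total, diff_co, diff_total].
    """
    clusters = np.unique(labels)
    progenies = []
    origin = []
    for c in clusters:
        members = X[labels == c]
        if members.shape[0] == 1:
            warnings.warn("singleton cluster during progeny draw; resampling with replacement")
        cols = [
            members[rng.integers(0, members.shape[0], size=n_progenies), j]
            for j in range(members.shape[1])
        ]
        progenies.append(np.column_stack(cols))
        origin += [c] * n_progenies
    P = np.vstack(progenies)
    origin = np.asarray(origin)
    new = ward_cluster(P, k) if P.shape[0] > k else np.zeros(len(P), dtype=int)
    same_origin = origin[:, None] == origin[None, :]
    co = new[:, None] == new[None, :]
    iu = np.triu_indices(len(origin), k=1)
    same = same_origin[iu]
    co_u = co[iu]
    return np.array(
        [co_u[same].sum(), same.sum(), co_u[~same].sum(), (~same).sum()],
        dtype=float,
    )


def _score_from_counts(counts: np.ndarray) -> float:
    """Smoothed same-origin / different-origin co-clustering rate ratio."""
    same_rate = (counts[0] + 0.5) / (counts[1] + 1.0)
    diff_rate = (counts[2] + 0.5) / (counts[3] + 1.0)
    return float(same_rate / diff_rate)


def progeny_stability(
    matrix,
    k_range=range(2, 6),
    n_progenies: int = 10,
    n_datasets: int = 10,
    n_iterations: int = 100,
    repeats: int = 10,
    seed: int = 0,
) -> StabilityProfile:
    """Progeny-clustering stability profile over candidate cluster numbers.

    For each k the full data is Ward-clustered once; each iteration draws
    ``n_progenies`` synthetic members per cluster by within-cluster
    feature-wise resampling with replacement, re-clusters the progenies,
    and accumulates pairwise co-membership. Per repeat, the
    ``n_iterations`` rounds are grouped into ``n_datasets`` batches: each
    batch pools its co-membership counts into one same-origin vs
    different-origin rate ratio (lightly smoothed so a perfectly separated
    batch stays finite), and the batch scores are averaged. The
    ``repeats`` repeat-level scores give mean and standard deviation.
    """
    X = np.asarray(matrix, dtype=float)
    k_range = list(k_range)
    rng = np.random.default_rng(seed)
    score: dict[int, float] = {}
    score_sd: dict[int, float] = {}
    batch = max(1, n_iterations // max(1, n_datasets))
    for k in k_range:
        labels = ward_cluster(X, k)
        rep_scores = []
        for _ in range(repeats):
            batch_scores = []
            done = 0
            while done < n_iterations:
                m = min(batch, n_iterations - done)
                counts = sum(
                    _progeny_counts(X, labels, k, n_progenies, rng) for _ in range(m)
                )
                batch_scores.append(_score_from_counts(counts))
                done += m
            rep_scores.append(float(np.mean(batch_scores)))
        score[k] = float(np.mean(rep_scores))
        score_sd[k] = float(np.std(rep_scores, ddof=1)) if repeats > 1 else 0.0
    profile = StabilityProfile(k_range=k_range, score=score, score_sd=score_sd)
    choose_k(profile)
    return profile


def choose_k(profile: StabilityProfile) -> int:
    """Select the cluster number by the greatest-score and greatest-gap criteria.

    Greatest score: k with the maximal mean stability score. Greatest gap:
    interior k maximizing ``2*s(k) - s(k-1) - s(k+1)`` (at the range edges
    the single neighbour difference is used). When the criteria agree the
    common k is returned; otherwise the greatest-gap k wins, with a
    warning. Ties resolve to the smaller k.
    """
    ks = profile.k_range
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate cluster numbers")
    s = profile.score
    best_score_k = min(ks, key=lambda k: (-s[k], k))
    gap: dict[int, float] = {}
    for i, k in enumerate(ks):
        if 0 < i < len(ks) - 1:
            gap[k] = 2 * s[k] - s[ks[i - 1]] - s[ks[i + 1]]
        elif i == 0:
            gap[k] = s[k] - s[ks[1]]
        else:
            gap[k] = s[k] - s[ks[-2]]
    profile.gap = gap
    best_gap_k = min(ks, key=lambda k: (-gap[k], k))
    if best_score_k == best_gap_k:
        profile.chosen_k, profile.criterion = best_score_k, "both"
    else:
        warnings.warn(
            f"greatest-score (k={best_score_k}) and greatest-gap (k={best_gap_k}) "
            "criteria disagree; using greatest gap"
        )
        profile.chosen_k, profile.criterion = best_gap_k, "greatest_gap"
    return profile.chosen_k


def silhouette_coefficient(matrix, labels) -> float:
    """Mean silhouette width (Euclidean); singleton clusters score 0."""
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if np.all(counts == 1):
        return 0.0
    return float(silhouette_score(X, labels, metric="euclidean"))


def association_test(labels, diagnoses, flag_threshold: float = 2.0) -> AssociationResult:
    """Pearson chi-squared test of independence between cluster membership
    and diagnosis, with per-cell Pearson residuals.

    Cells with ``|residual| > flag_threshold`` are flagged as over- or
    under-represented. Empty rows/columns are dropped with a warning.
    """
    labels = pd.Series(labels, name="cluster").astype(str)
    diagnoses = pd.Series(list(diagnoses), name="diagnosis").astype(str)
    if len(labels) != len(diagnoses):
        raise ValueError("labels and diagnoses must have equal length")
    table = pd.crosstab(labels, diagnoses)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        warnings.warn("empty categories dropped from contingency table")
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    residuals = (table - expected) / np.sqrt(expected)
    flagged = [
        (str(r), str(c), float(residuals.loc[r, c]))
        for r in residuals.index
        for c in residuals.columns
        if abs(residuals.loc[r, c]) > flag_threshold
    ]
    return AssociationResult(table, float(chi2), int(df), float(p), residuals, flagged)
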