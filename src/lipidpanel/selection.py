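"""Consensus feature selection by Monte-Carlo resampling and computed ABC
analysis.

Two independent importance routes are run on each of many random
training subsets: (i) mean decrease in out-of-bag accuracy of a bagged
decision-tree ensemble when a feature is permuted, and (ii) the squared
correlation of each feature with the first principal component. Each
importance vector is categorized by computed ABC analysis; the consensus
panel per route has the modal set-"A" size and the most frequent set-"A"
members; the final marker panel is the intersection of the two consensus
panels.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .pca import feature_pc_r2, pca

__all__ = [
    "AbcResult",
    "ResamplingPlan",
    "PanelSelection",
    "monte_carlo_split",
    "rf_importance",
    "abc_analysis",
    "consensus_panel",
    "intersect_panels",
    "run_selection",
]


@dataclass
class AbcResult:
    """Computed ABC partition of a non-negative value distribution.

    ``effort``/``yield_`` trace the cumulative curve in the unit square
    for the values sorted in descending order; ``ab_index``/``bc_index``
    are 1-based positions of the last item of set A and set B.
    """

    order: list[int]
    effort: np.ndarray
    yield_: np.ndarray
    ab_index: int
    bc_index: int
    set_a: list[int]
    set_b: list[int]
    set_c: list[int]
    degenerate: bool = False


@dataclass
class ResamplingPlan:
    n_runs: int = 1000
    train_fraction: float = 2.0 / 3.0
    balanced: bool = False
    seed: int = 0


@dataclass
class PanelSelection:
    runs: list[dict] = field(default_factory=list)
    consensus_size: dict[str, int] = field(default_factory=dict)
    consensus_members: dict[str, list[str]] = field(default_factory=dict)
    final_panel: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    def runs_to_csv(self, path) -> None:
        rows = [
            {"run": r["run"], "source": src, "set_a_size": len(r[src]),
             "set_a_members": ";".join(r[src])}
            for r in self.runs
            for src in ("rf", "pca")
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def monte_carlo_split(
    labels, plan: ResamplingPlan, run_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified (or class-balanced) random train/test partition.

    Stratified mode keeps each class's proportion in the 2/3 training
    part. Balanced mode takes equal per-class counts governed by the
    smallest class, so training and test sets both have 50% prevalence;
    leftover majority-class subjects are left out of that run.
    Reproducible per (plan.seed, run_index).
    """
    y = np.asarray(labels)
    rng = np.random.default_rng([int(plan.seed) % (2**31), int(run_index)])
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValueError("each class needs at least 3 members")
    train, test = [], []
    if plan.balanced:
        n_min = counts.min()
        n_train = int(round(plan.train_fraction * n_min))
        for c in classes:
            idx = rng.permutation(np.flatnonzero(y == c))[:n_min]
            train.append(idx[:n_train])
            test.append(idx[n_train:])
    else:
        for c in classes:
            idx = rng.permutation(np.flatnonzero(y == c))
            n_train = int(round(plan.train_fraction * idx.size))
            train.append(idx[:n_train])
            test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def rf_importance(
    X,
    y,
    n_trees: int = 1500,
    mtry: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Permutation importance: mean decrease in out-of-bag accuracy.

    A bagged ensemble of CART trees (bootstrap per tree, ``mtry`` features
    tried per split, default sqrt(d)) is grown; for every tree, each
    feature of the tree's out-of-bag samples is permuted in turn and the
    drop in out-of-bag accuracy, averaged over trees, is the feature's
    importance. Can be negative for irrelevant features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set has a single class")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    n, d = X.shape
    mtry = mtry if mtry is not None else max(1, int(np.sqrt(d)))
    rng = np.random.default_rng(seed)
    drops = np.zeros(d)
    used = np.zeros(d)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=mtry, random_state=int(rng.integers(0, 2**31))
        )
        tree.fit(X[boot], y[boot])
        X_oob, y_oob = X[oob], y[oob]
        m = oob.size
        # one batched predict: block 0 = intact, block j+1 = feature j permuted
        stacked = np.tile(X_oob, (d + 1, 1))
        for j in range(d):
            perm = rng.permutation(m)
            stacked[(j + 1) * m : (j + 2) * m, j] = X_oob[perm, j]
        pred = tree.predict(stacked)
        acc = (pred[:m] == y_oob).mean()
        for j in range(d):
            acc_perm = (pred[(j + 1) * m : (j + 2) * m] == y_oob).mean()
            drops[j] += acc - acc_perm
            used[j] += 1
    if not used.any():
        raise ValueError("no tree produced out-of-bag samples")
    return drops / np.maximum(used, 1)


def abc_analysis(values) -> AbcResult:
    """Computed ABC analysis of a non-negative importance vector.

    Items are sorted by descending value; the cumulative effort/yield
    curve is traced in the unit square. The A/B boundary is the curve
    point closest (Euclidean) to the ideal point (0, 1); the B/C boundary
    is the break-even position where the curve's slope first falls to 1
    (item value drops to the mean), constrained to lie at or after the
    A/B boundary. Negative inputs are clipped to 0 with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 items")
    if np.any(v < 0):
        warnings.warn("negative importance values clipped to 0")
        v = np.clip(v, 0.0, None)
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero input")
    n = v.size
    order = np.argsort(-v, kind="stable")
    sv = v[order]
    effort = np.arange(1, n + 1) / n
    yld = np.cumsum(sv) / total

    dist2 = effort**2 + (1.0 - yld) ** 2
    ab = int(np.argmin(dist2)) + 1  # 1-based position of last A item

    mean = total / n
    submean = np.flatnonzero(sv <= mean)
    be = int(submean[0]) + 1 if submean.size else n + 1
    # C starts at the break-even item; B spans between the boundaries.
    bc = max(be - 1, ab)
    bc = min(bc, n)

    return AbcResult(
        order=[int(i) for i in order],
        effort=effort,
        yield_=yld,
        ab_index=ab,
        bc_index=bc,
        set_a=[int(i) for i in order[:ab]],
        set_b=[int(i) for i in order[ab:bc]],
        set_c=[int(i) for i in order[bc:]],
        degenerate=bool(np.all(sv == sv[0])),
    )


def consensus_panel(
    run_sets: list[list[str]],
    importances: dict[str, float] | None = None,
) -> tuple[int, list[str]]:
    """Consensus over per-run ABC set-"A" records.

    The panel size is the modal set-A size across runs (ties resolve to
    the smaller size); the members are the ``size`` features appearing
    most frequently in set A (ties: higher mean importance, then name).
    """
    if not run_sets:
        raise ValueError("no run records")
    sizes = Counter(len(s) for s in run_sets)
    top = max(sizes.values())
    size = min(k for k, c in sizes.items() if c == top)
    freq = Counter()
    for s in run_sets:
        freq.update(s)
    importances = importances or {}
    ranked = sorted(
        freq, key=lambda f: (-freq[f], -importances.get(f, 0.0), f)
    )
    return size, ranked[:size]


def intersect_panels(panel_rf: list[str], panel_pca: list[str]) -> list[str]:
    """Order-stable intersection of the two consensus panels (rf order)."""
    if not panel_rf or not panel_pca:
        raise ValueError("both panels must be nonempty")
    other = set(panel_pca)
    final = [f for f in panel_rf if f in other]
    if not final:
        warnings.warn("panel intersection is empty")
    return final


def run_selection(
    matrix: pd.DataFrame,
    labels,
    plan: ResamplingPlan | None = None,
    n_trees: int = 1500,
    pca_center: bool = False,
    pca_component: int = 0,
) -> PanelSelection:
    """Full Monte-Carlo consensus selection on a preprocessed matrix.

    Per run: split, compute both importance vectors on the training part
    only, apply ABC analysis to each, and record the set-"A" members.
    The PCA route uses the sweep-selected centering (non-centered by
    default, matching a strong magnitude axis) fixed across runs.
    """
    plan = plan or ResamplingPlan()
    y = np.asarray(labels).astype(bool)
    features = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    sel = PanelSelection()
    mean_imp = {"rf": Counter(), "pca": Counter()}
    for run in range(plan.n_runs):
        train, _ = monte_carlo_split(y, plan, run)
        run_seed = (plan.seed * 100003 + run) % (2**31)
        rec = {"run": run}
        imp_rf = rf_importance(X[train], y[train], n_trees=n_trees, seed=run_seed)
        abc_rf = abc_analysis(np.clip(imp_rf, 0.0, None))
        rec["rf"] = [features[i] for i in abc_rf.set_a]
        scores, _, _ = pca(X[train], center=pca_center)
        r2 = feature_pc_r2(X[train], scores[:, pca_component])
        abc_pca = abc_analysis(r2)
        rec["pca"] = [features[i] for i in abc_pca.set_a]
        for src, imp in (("rf", imp_rf), ("pca", r2)):
            for f, v in zip(features, imp):
                mean_imp[src][f] += float(v) / plan.n_runs
        sel.runs.append(rec)
    for src in ("rf", "pca"):
        size, members = consensus_panel(
            [r[src] for r in sel.runs], dict(mean_imp[src])
        )
        sel.consensus_size[src] = size
        sel.consensus_members[src] = members
    sel.final_panel = intersect_panels(
        sel.consensus_members["rf"], sel.consensus_members["pca"]
    )
    return sel
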