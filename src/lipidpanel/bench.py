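"""Multi-classifier validation bench with permutation negative controls.

Five classifier families (random forest, k-nearest neighbours, RBF
support vector machine, multilayer perceptron, Gaussian naive Bayes) are
evaluated over Monte-Carlo class-balanced train/test splits, for three
feature sets (the selected marker panel, equally sized random panels
drawn from the non-selected features, and all features), each trained on
original data and on a negative control in which the feature pattern is
decoupled from the labels by permuting training rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import ResamplingPlan, monte_carlo_split

__all__ = [
    "CLASSIFIERS",
    "Scenario",
    "permute_training",
    "train_predict",
    "performance_metrics",
    "run_benchmark",
]

CLASSIFIERS = ("rf", "knn", "svm", "mlp", "nbayes")
FEATURE_SETS = ("selected", "random_nonselected", "all")
TRAININGS = ("original", "permuted")

METRIC_NAMES = (
    "sensitivity", "specificity", "ppv", "npv", "precision", "recall",
    "f1", "prevalence", "detection_rate", "detection_prevalence",
    "balanced_accuracy",
)


@dataclass
class Scenario:
    feature_set: str  # selected | random_nonselected | all
    training: str  # original | permuted
    classifier: str  # rf | knn | svm | mlp | nbayes
    n_trees: int = 1500
    knn_k: int = 3
    seed: int = 0


def _make_classifier(scenario: Scenario):
    """Build one scenario's classifier.

    Scale-sensitive families (kNN, SVM, MLP) get a feature standardizer
    fitted on the training part of the fold, inside the pipeline, so no
    test information leaks into the scaling.
    """
    name = scenario.classifier
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=scenario.n_trees,
            max_features="sqrt",
            random_state=scenario.seed,
        )
    if name == "knn":
        return make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=scenario.knn_k)
        )
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf"))
    if name == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(35, 35, 35),
                solver="sgd",
                learning_rate_init=0.1,
                max_iter=200,
                n_iter_no_change=10,
                tol=1e-4,
                random_state=scenario.seed,
            ),
        )
    if name == "nbayes":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}")


def permute_training(X_train, y_train, seed: int = 0):
    """Decouple features from labels by permuting training rows.

    The whole concentration pattern (row vector) of each training subject
    is reassigned to a random subject, so every feature's marginal
    distribution is preserved exactly while the feature-label linkage is
    destroyed. The labels (and any test data) are untouched.
    """
    X = np.asarray(X_train, dtype=float)
    rng = np.random.default_rng(seed)
    return X[rng.permutation(X.shape[0])], np.asarray(y_train)


def train_predict(
    scenario: Scenario, X_train, y_train, X_test
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one scenario's classifier on the training part and score the test.

    Returns hard class predictions and probability-like scores for the
    positive class. SVM scores are decision-function values passed through
    a logistic link.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate training set: single class")
    clf = _make_classifier(scenario)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_train, y_train)
        pred = clf.predict(X_test)
        if scenario.classifier == "svm":
            score = 1.0 / (1.0 + np.exp(-clf.decision_function(X_test)))
        else:
            proba = clf.predict_proba(X_test)
            pos_col = int(np.flatnonzero(clf.classes_ == True)[0]) if True in clf.classes_ else 1
            score = proba[:, pos_col]
    return pred, score


def performance_metrics(predictions, truth, scores=None) -> dict[str, float]:
    """Confusion-matrix test-performance panel (positive class = dementia).

    All rate metrics are percentages; ratios with a zero denominator are
    reported as NaN (missing), never as zero. AUC-ROC comes from the rank
    statistic, AUPRC from precision-recall integration, when scores are
    supplied.
    """
    pred = np.asarray(predictions).astype(bool)
    y = np.asarray(truth).astype(bool)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth differ in length")
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    n = len(y)

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "precision": ppv,
        "recall": sens,
        "f1": f1,
        "prevalence": ratio(tp + fn, n),
        "detection_rate": ratio(tp, n),
        "detection_prevalence": ratio(tp + fp, n),
        "balanced_accuracy": (sens + spec) / 2.0
        if not (np.isnan(sens) or np.isnan(spec))
        else float("nan"),
    }
    if scores is not None and 0 < y.sum() < n:
        s = np.asarray(scores, dtype=float)
        out["auc_roc"] = float(roc_auc_score(y, s))
        out["auprc"] = float(average_precision_score(y, s))
    return out


def _draw_random_panel(rng, features, selected):
    pool = [f for f in features if f not in set(selected)]
    if len(pool) < len(selected):
        raise ValueError("non-selected feature pool smaller than the panel")
    return list(rng.choice(pool, size=len(selected), replace=False))


def run_benchmark(
    matrix: pd.DataFrame,
    labels,
    panel: list[str],
    plan: ResamplingPlan | None = None,
    classifiers=CLASSIFIERS,
    feature_sets=FEATURE_SETS,
    trainings=TRAININGS,
    n_trees: int = 1500,
) -> pd.DataFrame:
    """Run the full scenario grid and average metrics over the runs.

    Every run uses one class-balanced Monte-Carlo split shared by all
    scenario cells, and a fresh random non-selected panel. Failed runs
    (degenerate folds) are excluded from the averages with a warning.
    Returns a table with one row per (feature_set, training, classifier).
    """
    plan = plan or ResamplingPlan(balanced=True)
    if not plan.balanced:
        warnings.warn("benchmark is designed for class-balanced splits")
    y = np.asarray(labels).astype(bool)
    features = list(matrix.columns)
    records: dict[tuple, list[dict]] = {
        (fs, tr, clf): [] for fs in feature_sets for tr in trainings for clf in classifiers
    }
    failures = 0
    for run in range(plan.n_runs):
        train, test = monte_carlo_split(y, plan, run)
        rng = np.random.default_rng([(plan.seed + 77) % (2**31), run])
        panels = {
            "selected": list(panel),
            "random_nonselected": _draw_random_panel(rng, features, panel),
            "all": features,
        }
        for fs in feature_sets:
            sub = matrix[panels[fs]].to_numpy(dtype=float)
            X_tr, X_te = sub[train], sub[test]
            y_tr, y_te = y[train], y[test]
            for tr_mode in trainings:
                if tr_mode == "permuted":
                    X_fit, y_fit = permute_training(
                        X_tr, y_tr, seed=int(rng.integers(0, 2**31))
                    )
                else:
                    X_fit, y_fit = X_tr, y_tr
                for clf in classifiers:
                    scenario = Scenario(
                        fs, tr_mode, clf, n_trees=n_trees,
                        seed=int((plan.seed * 1009 + run) % (2**31)),
                    )
                    try:
                        pred, score = train_predict(scenario, X_fit, y_fit, X_te)
                    except ValueError:
                        failures += 1
                        continue
                    records[(fs, tr_mode, clf)].append(
                        performance_metrics(pred, y_te, score)
                    )
    if failures:
        warnings.warn(f"{failures} degenerate runs excluded from averages")
    rows = []
    for (fs, tr_mode, clf), recs in records.items():
        if not recs:
            continue
        df = pd.DataFrame(recs)
        row = {"feature_set": fs, "training": tr_mode, "classifier": clf,
               "n_runs": len(recs)}
        for m in list(METRIC_NAMES) + ["auc_roc", "auprc"]:
            if m in df:
                row[m] = float(df[m].mean(skipna=True))
        rows.append(row)
    return pd.DataFrame(rows)
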