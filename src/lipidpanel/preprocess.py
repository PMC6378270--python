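"""Preprocessing of targeted lipidomics concentration tables.

Fixed stage order: analyte exclusion by LLOQ censoring, distribution-guided
per-analyte transformation, iterative two-sided Grubbs outlier elimination,
k-nearest-neighbour imputation, and age correction against the control
group. A :class:`PreprocessReport` records every decision so the curation
is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.impute import KNNImputer

from .synthetic import CohortTable

__all__ = [
    "TransformSpec",
    "PreprocessReport",
    "exclude_low_quantified",
    "select_transform",
    "grubbs_iterative",
    "impute_knn",
    "age_correct",
    "rescale_0_100",
    "preprocess_cohort",
]

TRANSFORMS = ("identity", "log", "sqrt", "reciprocal")

_TRANSFORM_FUNCS = {
    "identity": lambda x: x,
    "log": np.log,
    "sqrt": np.sqrt,
    "reciprocal": lambda x: 1.0 / x,
}


@dataclass
class TransformSpec:
    """Chosen transform per analyte with the KS p-values that justified it."""

    transform: dict[str, str] = field(default_factory=dict)
    ks_pvalues: dict[str, dict[str, float]] = field(default_factory=dict)

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        out = matrix.copy()
        for col in matrix.columns:
            out[col] = _TRANSFORM_FUNCS[self.transform[col]](matrix[col].to_numpy())
        return out

    def invert(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Back-transform to the natural concentration scale (antilog,
        square, or reciprocal per analyte)."""
        inv = {
            "identity": lambda x: x,
            "log": np.exp,
            "sqrt": np.square,
            "reciprocal": lambda x: 1.0 / x,
        }
        out = matrix.copy()
        for col in matrix.columns:
            out[col] = inv[self.transform[col]](matrix[col].to_numpy())
        return out


@dataclass
class PreprocessReport:
    excluded_analytes: dict[str, str] = field(default_factory=dict)
    transform: TransformSpec = field(default_factory=TransformSpec)
    outliers: list[tuple[str, str, float]] = field(default_factory=list)
    imputed_cells: list[tuple[str, str, float]] = field(default_factory=list)
    age_correction: dict[str, dict[str, float]] = field(default_factory=dict)
    reference_age: float = float("nan")

    def to_json(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["transform"] = {
            "transform": self.transform.transform,
            "ks_pvalues": self.transform.ks_pvalues,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=float)


def exclude_low_quantified(
    cohort: CohortTable, threshold: float = 0.2
) -> tuple[CohortTable, PreprocessReport]:
    """Drop analytes censored beyond ``threshold`` in every diagnosis group.

    An analyte is considered insufficiently quantified when the fraction of
    its measurements below the LLOQ exceeds ``threshold`` within each
    diagnosis group separately ("across all diagnoses"). Retained analytes
    keep their verified sub-LLOQ numeric values; unquantifiable cells stay
    missing.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    report = PreprocessReport()
    mask = cohort.below_lloq | cohort.concentrations.isna()
    keep = []
    for col in cohort.concentrations.columns:
        frac = mask[col].groupby(cohort.diagnosis, observed=True).mean()
        if (frac > threshold).all():
            report.excluded_analytes[col] = (
                f"below LLOQ in >{threshold:.0%} of measurements in every group"
            )
        else:
            keep.append(col)
    return cohort.select_analytes(keep), report


def select_transform(values: np.ndarray, alpha: float = 0.05, name: str = "") -> tuple[str, dict]:
    """Pick a normalizing transform for one analyte.

    All four candidates (identity, log, sqrt, reciprocal) are tested for
    normality with a Kolmogorov-Smirnov test against a normal with the
    sample mean and standard deviation. Policy: log is preferred for
    blood-concentration data and is chosen unless the KS test rejects
    normality of the log-transformed values at ``alpha``, in which case the
    reciprocal transform is used.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError(f"analyte {name!r}: need at least 3 values")
    pvals = {}
    for tname, func in _TRANSFORM_FUNCS.items():
        if tname in ("log", "sqrt", "reciprocal") and np.any(x <= 0):
            raise ValueError(f"analyte {name!r}: non-positive values under {tname}")
        t = func(x)
        mu, sd = t.mean(), t.std(ddof=1)
        if sd == 0:
            pvals[tname] = 0.0
            continue
        pvals[tname] = float(stats.kstest(t, "norm", args=(mu, sd)).pvalue)
    chosen = "log" if pvals["log"] >= alpha else "reciprocal"
    return chosen, pvals


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha)."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_iterative(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iterative two-sided Grubbs outlier elimination.

    The most extreme point is set to NaN while the Grubbs test is
    significant at ``alpha``; the procedure repeats on the curated vector.
    Returns the curated vector and the indices removed, in removal order.
    Stops (with a warning) when fewer than 3 values remain.
    """
    x = np.asarray(values, dtype=float).copy()
    removed: list[int] = []
    while True:
        idx = np.flatnonzero(~np.isnan(x))
        n = idx.size
        if n < 3:
            if removed:
                warnings.warn("fewer than 3 values remain; Grubbs iteration stopped")
            break
        sub = x[idx]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        g = dev.max() / sd
        if g <= _grubbs_critical(n, alpha):
            break
        worst = idx[int(np.argmax(dev))]
        removed.append(int(worst))
        x[worst] = np.nan
    return x, removed


def impute_knn(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing cells by distance-weighted k-nearest-neighbour imputation.

    Distances between subjects are Euclidean over mutually observed,
    standardized analytes; imputed values are distance-weighted means of
    the k nearest subjects, de-standardized back to the analyte's scale.
    Observed cells are left untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    empty = matrix.columns[matrix.isna().all(axis=0)]
    if len(empty):
        raise ValueError(f"columns entirely missing: {list(empty)}")
    if (matrix.notna().sum(axis=1) == 0).any():
        raise ValueError("some subjects have no observed values")
    if not matrix.isna().any().any():
        return matrix.copy()
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1).replace(0.0, 1.0)
    z = (matrix - mu) / sd
    imputer = KNNImputer(n_neighbors=k, weights="distance")
    filled = imputer.fit_transform(z.to_numpy())
    out = pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)
    return out * sd + mu


def age_correct(
    matrix: pd.DataFrame,
    age: pd.Series,
    control_mask: pd.Series,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Remove age trends identified in the control group.

    For every analyte whose Pearson correlation with age is significant in
    controls (p < ``alpha``), a robust linear regression (Huber
    M-estimator) of concentration on age is fitted in the controls only,
    and ``slope * (age - median age of all subjects)`` is subtracted from
    every subject's value, i.e. the analyte is normalized to the cohort's
    median age.
    """
    ctrl = np.asarray(control_mask, dtype=bool)
    if ctrl.sum() < 10:
        raise ValueError("need at least 10 controls for age correction")
    age_arr = np.asarray(age, dtype=float)
    if np.std(age_arr[ctrl]) == 0:
        raise ValueError("degenerate age variance in controls")
    ref_age = float(np.median(age_arr))
    out = matrix.copy()
    report: dict[str, dict[str, float]] = {"__reference_age__": {"median_age": ref_age}}
    for col in matrix.columns:
        y_ctrl = matrix[col].to_numpy()[ctrl]
        r_pre, p_pre = stats.pearsonr(age_arr[ctrl], y_ctrl)
        if p_pre >= alpha:
            continue
        X = sm.add_constant(age_arr[ctrl])
        fit = sm.RLM(y_ctrl, X, M=sm.robust.norms.HuberT()).fit()
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        out[col] = matrix[col] - slope * (age_arr - ref_age)
        r_post, p_post = stats.pearsonr(age_arr[ctrl], out[col].to_numpy()[ctrl])
        report[col] = {
            "slope": slope,
            "intercept": intercept,
            "p_pre": float(p_pre),
            "p_post": float(p_post),
            "r_pre": float(r_pre),
            "r_post": float(r_post),
        }
    return out, report


def rescale_0_100(matrix: pd.DataFrame) -> pd.DataFrame:
    """Affinely map every analyte onto [0, 100] (min -> 0, max -> 100)."""
    out = matrix.copy().astype(float)
    for col in matrix.columns:
        lo, hi = matrix[col].min(), matrix[col].max()
        if hi == lo:
            warnings.warn(f"analyte {col!r} is constant; rescaled to all zeros")
            out[col] = 0.0
        else:
            out[col] = (matrix[col] - lo) / (hi - lo) * 100.0
    return out


def preprocess_cohort(
    cohort: CohortTable,
    lloq_threshold: float = 0.2,
    alpha: float = 0.05,
    knn_k: int = 10,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the full curation pipeline on a cohort.

    Stage order: LLOQ-based analyte exclusion, transform selection,
    iterative Grubbs outlier removal (on transformed values), kNN
    imputation, age correction. Returns the complete transformed and
    age-corrected subjects x analytes matrix plus the report.
    """
    cohort, report = exclude_low_quantified(cohort, lloq_threshold)
    matrix = cohort.concentrations.copy()

    spec = TransformSpec()
    for col in matrix.columns:
        chosen, pvals = select_transform(matrix[col].to_numpy(), alpha, name=col)
        spec.transform[col] = chosen
        spec.ks_pvalues[col] = pvals
    report.transform = spec
    matrix = spec.apply(matrix)

    for col in matrix.columns:
        curated, removed = grubbs_iterative(matrix[col].to_numpy(), alpha)
        for i in removed:
            report.outliers.append((str(matrix.index[i]), col, float(matrix[col].iloc[i])))
        matrix[col] = curated

    missing_before = matrix.isna()
    matrix = impute_knn(matrix, k=knn_k)
    for subj, col in zip(*np.nonzero(missing_before.to_numpy())):
        report.imputed_cells.append(
            (str(matrix.index[subj]), str(matrix.columns[col]), float(matrix.iloc[subj, col]))
        )

    control_mask = cohort.diagnosis == "control"
    matrix, age_report = age_correct(matrix, cohort.age, control_mask, alpha)
    report.reference_age = age_report.pop("__reference_age__")["median_age"]
    report.age_correction = age_report
    return matrix, report
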