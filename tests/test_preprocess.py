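"""Preprocessing contracts: LLOQ exclusion, transform policy, Grubbs
curation, kNN imputation, age correction, rescaling."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lipidpanel as lp
from lipidpanel.preprocess import _grubbs_critical
from lipidpanel.synthetic import CohortTable


def _toy_cohort(conc, mask, groups):
    index = pd.Index([f"S{i}" for i in range(len(groups))], name="subject_id")
    cols = pd.Index([f"A{j}" for j in range(conc.shape[1])], name="analyte")
    meta = pd.DataFrame(
        {"diagnosis": groups, "age": 40.0, "sex": "f", "bmi": 24.0}, index=index
    )
    return CohortTable(
        pd.DataFrame(conc, index=index, columns=cols),
        pd.DataFrame(mask, index=index, columns=cols),
        meta,
        pd.Series("other", index=cols),
    )


class TestExcludeLowQuantified:
    def test_all_false_mask_keeps_everything(self):
        conc = np.ones((6, 3))
        cohort = _toy_cohort(conc, np.zeros_like(conc, bool), ["a"] * 3 + ["b"] * 3)
        kept, report = lp.exclude_low_quantified(cohort, 0.2)
        assert kept.n_analytes == 3 and not report.excluded_analytes

    def test_group_wise_rule(self):
        """30% censoring in all groups excludes; in one group only retains."""
        conc = np.ones((20, 2))
        mask = np.zeros_like(conc, bool)
        groups = ["a"] * 10 + ["b"] * 10
        mask[:3, 0] = mask[10:13, 0] = True  # analyte 0: 30% in both groups
        mask[:3, 1] = True  # analyte 1: 30% in group a only
        cohort = _toy_cohort(conc, mask, groups)
        kept, report = lp.exclude_low_quantified(cohort, 0.2)
        assert list(kept.concentrations.columns) == ["A1"]
        assert "A0" in report.excluded_analytes

    def test_default_cohort_retains_35_of_41(self, default_cohort):
        kept, report = lp.exclude_low_quantified(default_cohort, 0.2)
        assert default_cohort.n_analytes == 41
        assert kept.n_analytes == 35
        assert len(report.excluded_analytes) == 6

    def test_threshold_validated(self, default_cohort):
        with pytest.raises(ValueError):
            lp.exclude_low_quantified(default_cohort, 1.5)


class TestSelectTransform:
    def test_lognormal_sample_gets_log(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(2.0, 0.5, size=94))
        chosen, pvals = lp.select_transform(x)
        assert chosen == "log"
        assert set(pvals) == {"identity", "log", "sqrt", "reciprocal"}
        assert pvals["log"] >= 0.05

    def test_log_preferred_even_if_identity_also_passes(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100.0, 1.0, size=94)  # tight positive normal: all pass
        chosen, pvals = lp.select_transform(x)
        assert chosen == "log" and pvals["identity"] >= 0.05

    def test_reciprocal_fallback_when_log_rejected(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(0.0, 1.0, size=200) ** 3)  # log is cubic-normal
        chosen, pvals = lp.select_transform(x)
        assert pvals["log"] < 0.05 and chosen == "reciprocal"

    def test_nonpositive_rejected_with_analyte_name(self):
        with pytest.raises(ValueError, match="myanalyte"):
            lp.select_transform(np.array([1.0, -2.0, 3.0, 4.0]), name="myanalyte")


class TestGrubbs:
    def test_zero_variance_untouched(self):
        curated, removed = lp.grubbs_iterative(np.array([5.0] * 5))
        assert removed == [] and not np.isnan(curated).any()

    def test_single_outlier_removed_with_closed_form_critical_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        curated, removed = lp.grubbs_iterative(x, alpha=0.05)
        assert removed == [4]
        # independent closed-form oracle for the first iteration
        n = 5
        g = np.abs(x - x.mean()).max() / x.std(ddof=1)
        t2 = stats.t.ppf(1 - 0.05 / (2 * n), n - 2) ** 2
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
        assert abs(_grubbs_critical(n, 0.05) - g_crit) < 1e-9
        assert g > g_crit

    def test_gaussian_null_type_one_error_controlled(self):
        """Average removals on null data stay below alpha*n (3 SE slack)."""
        rng = np.random.default_rng(3)
        alpha, n = 0.05, 50
        removals = [
            len(lp.grubbs_iterative(rng.normal(size=n), alpha)[1]) for _ in range(200)
        ]
        mean, se = np.mean(removals), np.std(removals, ddof=1) / np.sqrt(200)
        assert mean <= alpha * n + 3 * se

    def test_stops_below_three_values(self):
        x = np.array([1.0, 2.0, np.nan, np.nan, np.nan])
        curated, removed = lp.grubbs_iterative(x)
        assert removed == []


class TestImputeKnn:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        pd.testing.assert_frame_equal(lp.impute_knn(df, k=2), df)

    def test_toy_matrix_matches_hand_enumeration(self):
        """5x3 matrix, one missing cell, k=2: distance-weighted mean of the
        two nearest rows, recomputed by brute force."""
        X = np.array(
            [
                [1.0, 2.0, 3.0],
                [1.1, 2.1, np.nan],
                [1.2, 1.9, 3.2],
                [5.0, 6.0, 9.0],
                [5.1, 6.2, 9.3],
            ]
        )
        df = pd.DataFrame(X)
        out = lp.impute_knn(df, k=2)
        # brute force on the same standardized scale the imputer uses
        mu, sd = df.mean(), df.std(ddof=1)
        z = ((df - mu) / sd).to_numpy()
        dists = []
        for i in [0, 2, 3, 4]:
            obs = [0, 1]  # columns observed in both rows
            d = np.sqrt(np.mean((z[1, obs] - z[i, obs]) ** 2) * z.shape[1])
            dists.append((d, z[i, 2]))
        dists.sort()
        (d1, v1), (d2, v2) = dists[:2]
        z_hat = (v1 / d1 + v2 / d2) / (1 / d1 + 1 / d2)
        expected = z_hat * sd[2] + mu[2]
        assert abs(out.iloc[1, 2] - expected) < 1e-8
        # observed cells untouched
        assert np.allclose(out.to_numpy()[~np.isnan(X)], X[~np.isnan(X)])

    def test_beats_column_mean_on_masked_cells(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(60, 1)) @ rng.normal(size=(1, 8)) + rng.normal(
            scale=0.3, size=(60, 8)
        )
        df = pd.DataFrame(base)
        holes = df.copy()
        cells = [(rng.integers(0, 60), rng.integers(0, 8)) for _ in range(30)]
        for r, c in cells:
            holes.iat[r, c] = np.nan
        knn = lp.impute_knn(holes, k=5)
        colmean = holes.fillna(holes.mean())
        err_knn = np.sqrt(np.mean([(knn.iat[r, c] - df.iat[r, c]) ** 2 for r, c in cells]))
        err_mean = np.sqrt(np.mean([(colmean.iat[r, c] - df.iat[r, c]) ** 2 for r, c in cells]))
        assert err_knn < err_mean

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="b"):
            lp.impute_knn(df)


class TestAgeCorrect:
    def test_uncorrelated_analyte_unchanged(self):
        rng = np.random.default_rng(6)
        n = 60
        age = pd.Series(rng.uniform(20, 70, n))
        df = pd.DataFrame({"flat": rng.normal(size=n)})
        ctrl = pd.Series([True] * n)
        out, report = lp.age_correct(df, age, ctrl)
        pd.testing.assert_frame_equal(out, df)
        assert set(report) == {"__reference_age__"}

    def test_planted_slope_removed(self):
        rng = np.random.default_rng(7)
        n = 1000
        age = pd.Series(rng.uniform(20, 70, n))
        b = 0.05
        df = pd.DataFrame({"x": 3.0 + b * age + rng.normal(scale=0.3, size=n)})
        ctrl = pd.Series([True] * n)
        out, report = lp.age_correct(df, age, ctrl)
        r_post = stats.pearsonr(age, out["x"]).statistic
        assert abs(report["x"]["slope"] - b) < 0.01
        assert abs(r_post) < 0.05

    def test_degenerate_control_ages_rejected(self):
        df = pd.DataFrame({"x": np.arange(12.0)})
        with pytest.raises(ValueError):
            lp.age_correct(df, pd.Series([50.0] * 12), pd.Series([True] * 12))


class TestRescale:
    def test_affine_map(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert list(lp.rescale_0_100(df)["a"]) == [0.0, 50.0, 100.0]

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(20, 4)))
        once = lp.rescale_0_100(df)
        twice = lp.rescale_0_100(once)
        pd.testing.assert_frame_equal(once, twice)
        assert np.allclose(once.min(), 0) and np.allclose(once.max(), 100)

    def test_constant_column_warns_to_zero(self):
        df = pd.DataFrame({"c": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning):
            out = lp.rescale_0_100(df)
        assert (out["c"] == 0).all()


class TestPipeline:
    def test_full_pipeline_yields_complete_35_column_matrix(self, preprocessed):
        matrix, report = preprocessed
        assert matrix.shape == (94, 35)
        assert not matrix.isna().any().any()
        assert len(report.excluded_analytes) == 6
        # every removed outlier later appears among imputed cells
        outlier_cells = {(s, a) for s, a, _ in report.outliers}
        imputed_cells = {(s, a) for s, a, _ in report.imputed_cells}
        assert outlier_cells <= imputed_cells

    def test_age_corrected_analytes_lose_control_correlation(self, preprocessed):
        _, report = preprocessed
        assert report.age_correction  # some analytes were corrected
        for col, rec in report.age_correction.items():
            assert rec["p_pre"] < 0.05
            assert rec["p_post"] >= 0.05, col

    def test_report_serializes(self, preprocessed, tmp_path):
        _, report = preprocessed
        report.to_json(tmp_path / "rep.json")
        assert (tmp_path / "rep.json").stat().st_size > 0
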