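"""Monte-Carlo splits, bagged-tree permutation importance, computed ABC
analysis, and consensus panel construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lipidpanel as lp
from lipidpanel.selection import ResamplingPlan


def abc_brute_force(values):
    """Independent exhaustive-search oracle for the ABC boundaries.

    Scans every candidate A/B boundary position for the minimal distance
    to (0,1), and every candidate break-even position for the first
    at-or-below-average item.
    """
    v = np.clip(np.asarray(values, dtype=float), 0, None)
    n = len(v)
    sv = np.sort(v)[::-1]
    total = sv.sum()
    best_i, best_d = None, np.inf
    for i in range(1, n + 1):
        d = np.hypot(i / n, 1.0 - sv[:i].sum() / total)
        if d < best_d - 1e-15:
            best_d, best_i = d, i
    be = next((i for i in range(1, n + 1) if sv[i - 1] <= total / n), n + 1)
    bc = min(max(be - 1, best_i), n)
    return best_i, bc


class TestMonteCarloSplit:
    def test_two_thirds_arithmetic_on_94_subjects(self, dementia_labels):
        plan = ResamplingPlan(seed=0)
        train, test = lp.monte_carlo_split(dementia_labels, plan, 0)
        assert 62 <= len(train) <= 63
        assert 31 <= len(test) <= 32
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 94

    def test_same_seed_and_run_reproduce_split(self, dementia_labels):
        plan = ResamplingPlan(seed=5)
        a = lp.monte_carlo_split(dementia_labels, plan, 3)
        b = lp.monte_carlo_split(dementia_labels, plan, 3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = lp.monte_carlo_split(dementia_labels, plan, 4)
        assert not np.array_equal(a[0], c[0])

    def test_each_subject_tested_about_a_third_of_runs(self, dementia_labels):
        plan = ResamplingPlan(seed=1)
        counts = np.zeros(94)
        n_runs = 1000
        for run in range(n_runs):
            _, test = lp.monte_carlo_split(dementia_labels, plan, run)
            counts[test] += 1
        freq = counts / n_runs
        # each class's exact test fraction (5/16 and 26/78) is ~1/3;
        # individual subjects are binomial, so allow the extreme-value tail
        y = dementia_labels
        expected = np.where(y, 5 / 16, 26 / 78)
        dev = np.abs(freq - expected)
        assert np.mean(dev < 0.05) >= 0.9
        assert np.all(dev < 0.07)
        assert abs(freq.mean() - 1 / 3) < 0.02

    def test_balanced_mode_equalizes_prevalence(self, dementia_labels):
        plan = ResamplingPlan(balanced=True, seed=2)
        train, test = lp.monte_carlo_split(dementia_labels, plan, 0)
        y = dementia_labels
        assert y[train].sum() == (~y[train]).sum()
        assert y[test].sum() == (~y[test]).sum()

    def test_tiny_class_rejected(self):
        y = np.array([True, True, False, False, False])
        with pytest.raises(ValueError):
            lp.monte_carlo_split(y, ResamplingPlan(), 0)


class TestRfImportance:
    def test_planted_separator_ranks_first(self):
        """A perfectly separating feature tops the importance ranking in
        >= 95% of seeds."""
        hits, seeds = 0, 20
        for seed in range(seeds):
            rng = np.random.default_rng(seed)
            n, d = 200, 8
            y = rng.random(n) < 0.5
            X = rng.normal(size=(n, d))
            X[:, 3] = y * 2.0 + rng.normal(scale=0.1, size=n)
            imp = lp.rf_importance(X, y, n_trees=30, seed=seed)
            hits += np.argmax(imp) == 3
        assert hits >= 0.95 * seeds

    def test_label_permuted_importances_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 8))
        y = rng.permutation(100) < 50
        imp = lp.rf_importance(X, y, n_trees=100, seed=0)
        assert np.all(np.abs(imp) < 0.1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lp.rf_importance(np.ones((10, 3)), np.ones(10, bool), n_trees=5)


class TestAbcAnalysis:
    def test_single_dominant_item(self):
        values = np.array([100.0] + [1.0] * 9)
        res = lp.abc_analysis(values)
        assert res.set_a == [0]
        assert set(res.set_a + res.set_b + res.set_c) == set(range(10))

    def test_uniform_values_boundary_at_half_and_degenerate(self):
        res = lp.abc_analysis(np.ones(10))
        assert res.degenerate
        assert res.ab_index == 5  # minimize sqrt(t^2 + (1-t)^2) on the diagonal
        assert abs(res.effort[res.ab_index - 1] - 0.5) < 1e-12

    def test_negative_values_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            res = lp.abc_analysis(np.array([5.0, -1.0, 2.0, 0.5]))
        assert 1 not in res.set_a

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lp.abc_analysis(np.zeros(5))

    def test_boundaries_match_exhaustive_search(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = rng.integers(3, 51)
            v = rng.gamma(1.0, 1.0, size=n)
            res = lp.abc_analysis(v)
            ab, bc = abc_brute_force(v)
            assert res.ab_index == ab and res.bc_index == bc

    @settings(max_examples=300, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=3, max_size=50)
    )
    def test_partition_property(self, values):
        v = np.asarray(values)
        if v.sum() == 0:
            return
        res = lp.abc_analysis(v)
        parts = [res.set_a, res.set_b, res.set_c]
        union = [i for p in parts for i in p]
        assert sorted(union) == list(range(len(v)))
        assert len(union) == len(set(union))
        assert res.set_a  # nonempty for non-constant positive input
        assert np.all(np.diff(res.yield_) >= -1e-12)
        # yield of sorted input is concave
        assert np.all(np.diff(np.diff(res.yield_)) <= 1e-9)


class TestConsensusPanel:
    def test_identical_sets_returned_exactly(self):
        runs = [["a", "b", "c"]] * 10
        size, members = lp.consensus_panel(runs)
        assert size == 3 and sorted(members) == ["a", "b", "c"]

    def test_modal_size_and_frequency_ranking(self):
        """600 runs of size 8 and 400 of size 9 with known frequencies."""
        feats = [f"f{i:02d}" for i in range(15)]
        runs = [feats[:8]] * 600 + [feats[1:10]] * 400
        size, members = lp.consensus_panel(runs)
        assert size == 8
        # f1..f7 appear 1000x, f0 600x, f8/f9 400x -> top 8 = f1..f7 + f0
        assert set(members) == set(feats[:8])

    def test_size_tie_resolves_smaller(self):
        runs = [["a", "b"]] * 5 + [["a", "b", "c"]] * 5
        size, _ = lp.consensus_panel(runs)
        assert size == 2

    def test_frequency_tie_broken_by_importance(self):
        runs = [["a", "b"], ["a", "c"]]
        _, members = lp.consensus_panel(runs, {"b": 0.1, "c": 0.9})
        assert members == ["a", "c"]


class TestIntersectPanels:
    def test_identical_panels(self):
        assert lp.intersect_panels(["x", "y"], ["y", "x"]) == ["x", "y"]

    def test_disjoint_panels_warn_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            assert lp.intersect_panels(["a"], ["b"]) == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lp.intersect_panels([], ["a"])


class TestRunSelection:
    def test_small_run_produces_consistent_records(self, preprocessed, dementia_labels):
        matrix, _ = preprocessed
        plan = ResamplingPlan(n_runs=8, seed=4)
        sel = lp.run_selection(matrix, dementia_labels, plan, n_trees=40)
        assert len(sel.runs) == 8
        for src in ("rf", "pca"):
            sizes = [len(r[src]) for r in sel.runs]
            assert sel.consensus_size[src] == max(set(sizes), key=lambda s: (sizes.count(s), -s))
            assert len(sel.consensus_members[src]) == sel.consensus_size[src]
        assert len(sel.final_panel) <= min(sel.consensus_size.values())
        # order-stable: final panel follows the rf consensus order
        rf_order = {f: i for i, f in enumerate(sel.consensus_members["rf"])}
        assert sel.final_panel == sorted(sel.final_panel, key=rf_order.get)
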