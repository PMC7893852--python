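"""CHAID: merging, Bonferroni, complexity selection, validity metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frailscan.chaid import (
    ChaidParams,
    bootstrap_select,
    clopper_pearson,
    cross_validate,
    fit_chaid,
    stirling2,
    tree_to_expression,
    validity_metrics,
    _chi2_groups,
    _merge_categories,
)


def _partitions(items):
    """All set partitions of a list (brute force, for the Stirling oracle)."""
    if not items:
        yield []
        return
    head, *rest = items
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


class TestStirling:
    def test_against_partition_enumeration(self):
        for c in range(1, 7):
            parts = list(_partitions(list(range(c))))
            for r in range(1, c + 1):
                brute = sum(1 for p in parts if len(p) == r)
                assert stirling2(c, r) == brute

    def test_edge_cases(self):
        assert stirling2(0, 0) == 1
        assert stirling2(5, 0) == 0
        assert stirling2(3, 4) == 0


class TestFitChaid:
    def test_constant_outcome_gives_root_only_tree(self):
        X = pd.DataFrame({"a": ["0", "1"] * 10})
        tree = fit_chaid(X, np.zeros(20, dtype=bool), ChaidParams(min_node_size=1))
        assert tree.root.is_leaf
        assert tree.depth() == 0

    def test_perfect_binary_feature_splits_with_chi2_20(self):
        """20 rows, feature ⇔ label: 2×2 all-diagonal table has χ² = n = 20."""
        X = pd.DataFrame({"a": ["1"] * 10 + ["0"] * 10})
        y = np.array([True] * 10 + [False] * 10)
        tree = fit_chaid(X, y, ChaidParams(min_node_size=1, max_depth=2))
        assert tree.root.feature == "a"
        assert tree.root.chi2 == pytest.approx(20.0)
        assert (tree.predict(X) == y).all()

    def test_continuous_feature_rejected(self):
        X = pd.DataFrame({"a": [0.1, 0.7, 0.3, 0.9]})
        with pytest.raises(TypeError, match="continuous"):
            fit_chaid(X, np.array([0, 1, 0, 1], dtype=bool))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            fit_chaid(pd.DataFrame({"a": ["x"]}), np.array([True]))

    def test_prediction_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.integers(0, 2, 300).astype(str),
                          "b": rng.integers(0, 3, 300).astype(str)})
        y = (X["a"] == "1").to_numpy() & (rng.random(300) < 0.9)
        perm = rng.permutation(300)
        t1 = fit_chaid(X, y)
        t2 = fit_chaid(X.iloc[perm].reset_index(drop=True), y[perm])
        probe = X.drop_duplicates().reset_index(drop=True)
        assert (t1.predict(probe) == t2.predict(probe)).all()

    def test_duplicating_rows_preserves_predictions(self):
        """χ² scales with n but fixed-alpha decisions keep the same tree shape
        on exact duplication of a clearly-separable set."""
        X = pd.DataFrame({"a": ["1"] * 20 + ["0"] * 20})
        y = np.array([True] * 18 + [False] * 2 + [False] * 20)
        t1 = fit_chaid(X, y, ChaidParams(min_node_size=1))
        t2 = fit_chaid(pd.concat([X, X], ignore_index=True),
                       np.concatenate([y, y]), ChaidParams(min_node_size=1))
        probe = pd.DataFrame({"a": ["0", "1"]})
        assert (t1.predict(probe) == t2.predict(probe)).all()
        assert t2.root.chi2 == pytest.approx(2 * t1.root.chi2)


class TestMergeStep:
    def _oracle_merge(self, counts, alpha):
        """Greedy reference implementation re-deriving the merge sequence."""
        groups = [(c,) for c in sorted(counts, key=str)]
        tallies = {g: np.array(counts[g[0]], dtype=float) for g in groups}
        while len(groups) > 2:
            pairs = list(itertools.combinations(groups, 2))
            ps = [_chi2_groups(np.vstack([tallies[a], tallies[b]]))[1]
                  for a, b in pairs]
            best = int(np.argmax(ps))
            if ps[best] < alpha:
                break
            a, b = pairs[best]
            merged = tuple(sorted(a + b, key=str))
            tallies[merged] = tallies.pop(a) + tallies.pop(b)
            groups = sorted([g for g in groups if g not in (a, b)] + [merged],
                            key=str)
        return sorted(groups)

    def test_small_instance_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n_cat = rng.integers(2, 5)
            counts = {str(c): (int(rng.integers(1, 40)), int(rng.integers(1, 40)))
                      for c in range(n_cat)}
            got = sorted(_merge_categories(counts, 0.05))
            assert got == self._oracle_merge(counts, 0.05)

    def test_identical_categories_merge(self):
        counts = {"a": (30, 10), "b": (30, 10), "c": (5, 35)}
        groups = _merge_categories(counts, 0.05)
        assert ("a", "b") in groups and ("c",) in groups


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(5)
    n = 4000
    a = rng.random(n) < 0.5
    b = rng.random(n) < 0.5
    noise = rng.random(n)
    y = (a & b & (noise < 0.95)) | (~(a & b) & (noise > 0.98))
    X = pd.DataFrame({"a": a.astype(int).astype(str),
                      "b": b.astype(int).astype(str),
                      "c": rng.integers(0, 2, n).astype(str)})
    return X, y


class TestPlantedRecovery:
    def test_depth2_conjunction_recovered(self, planted):
        X, y = planted
        tree = fit_chaid(X, y, ChaidParams(max_depth=2))
        holdout = X.iloc[3000:].reset_index(drop=True)
        acc = np.mean(tree.predict(holdout) == y[3000:])
        assert acc > 0.95
        assert {tree.root.feature} <= {"a", "b"}

    def test_bootstrap_prefers_planted_depth(self, planted):
        X, y = planted
        grid = [ChaidParams(max_depth=1), ChaidParams(max_depth=2),
                ChaidParams(max_depth=3)]
        chosen = bootstrap_select(X.iloc[:1200], y[:1200], grid, n_boot=8, seed=1)
        assert chosen.max_depth == 2

    def test_tree_to_expression_is_conjunction(self, planted):
        X, y = planted
        tree = fit_chaid(X.astype(int), y, ChaidParams(max_depth=2))
        expr = tree_to_expression(tree)
        # the positive leaf requires both planted features
        assert expr[0] == "and" or isinstance(expr, list)

    def test_grid_of_one_returns_it(self, planted):
        X, y = planted
        only = ChaidParams(max_depth=1)
        assert bootstrap_select(X.iloc[:200], y[:200], [only], n_boot=3,
                                seed=0) is only

    def test_pure_noise_selects_simplest(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"a": rng.integers(0, 2, 400).astype(str),
                          "b": rng.integers(0, 2, 400).astype(str)})
        y = rng.random(400) < 0.3
        grid = [ChaidParams(max_depth=2, min_node_size=10),
                ChaidParams(max_depth=1, min_node_size=10),
                ChaidParams(max_depth=1, min_node_size=50)]
        chosen = bootstrap_select(X, y, grid, n_boot=10, seed=4)
        # on noise every tree degenerates to the majority vote: scores tie and
        # the tie rule picks the shallowest tree with the largest node size
        assert chosen.max_depth == 1 and chosen.min_node_size == 50


class TestCrossValidate:
    def test_perfectly_separable(self):
        X = pd.DataFrame({"a": ["1"] * 50 + ["0"] * 50})
        y = np.array([True] * 50 + [False] * 50)
        rep = cross_validate(X, y, ChaidParams(min_node_size=1), k=10, seed=0)
        assert rep.sensitivity.point == 1.0
        assert rep.specificity.point == 1.0

    def test_always_negative_classifier(self):
        """Uninformative features: trees predict the majority (not frail)."""
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": ["0"] * 200})
        y = rng.random(200) < 0.25
        with pytest.warns(UserWarning, match="PPV"):
            rep = cross_validate(X, y, ChaidParams(), k=10, seed=1)
        assert rep.sensitivity.point == 0.0
        prevalence = y.mean()
        assert rep.npv.point == pytest.approx(1 - prevalence, abs=1e-12)

    def test_leave_one_out_matches_direct_computation(self):
        X = pd.DataFrame({"a": ["1", "1", "0", "0", "1", "0"]})
        y = np.array([True, True, False, False, True, False])
        n = len(y)
        rep = cross_validate(X, y, ChaidParams(min_node_size=1), k=n, seed=3)
        # direct LOO with the same folds
        from frailscan.chaid import _stratified_folds
        folds = _stratified_folds(y, n, 3)
        preds = np.empty(n, dtype=bool)
        for f in range(n):
            test = folds == f
            tree = fit_chaid(X[~test].reset_index(drop=True), y[~test],
                             ChaidParams(min_node_size=1))
            preds[test] = tree.predict(X[test].reset_index(drop=True))
        assert rep.tp == int(np.sum(preds & y))
        assert rep.tn == int(np.sum(~preds & ~y))

    def test_k_below_2_rejected(self):
        with pytest.raises(ValueError, match="k"):
            cross_validate(pd.DataFrame({"a": ["0", "1"]}),
                           np.array([True, False]), k=1)


class TestValidityMetrics:
    def test_reference_set_confusion_matrix(self):
        """(42, 43, 682, 108): 150 frail of 875 → sens .280, spec .941, npv .863."""
        rep = validity_metrics(tp=42, fp=43, tn=682, fn=108)
        assert rep.sensitivity.point == pytest.approx(0.280, abs=5e-4)
        assert rep.specificity.point == pytest.approx(0.941, abs=5e-4)
        assert rep.npv.point == pytest.approx(0.863, abs=5e-4)
        assert rep.ppv.point == pytest.approx(42 / 85)

    def test_exact_ci_matches_beta_quantile_oracle(self):
        rep = validity_metrics(tp=42, fp=43, tn=682, fn=108)
        x, n = 42, 150
        lo = stats.beta.ppf(0.025, x, n - x + 1)
        hi = stats.beta.ppf(0.975, x + 1, n - x)
        assert rep.sensitivity.ci_low == pytest.approx(lo)
        assert rep.sensitivity.ci_high == pytest.approx(hi)

    def test_perfect_matrix(self):
        rep = validity_metrics(10, 0, 10, 0)
        for m in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert m.point == 1.0
            assert 0.0 <= m.ci_low <= 1.0 and m.ci_high == 1.0

    def test_cis_contain_point_estimate(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 60, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            rep = validity_metrics(int(tp), int(fp), int(tn), int(fn))
            for m in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
                if m is not None:
                    assert m.ci_low <= m.point <= m.ci_high

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (10, 100, 1000):
            lo, hi = clopper_pearson(int(0.3 * n), n)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_no_positive_predictions_warns(self):
        with pytest.warns(UserWarning, match="PPV"):
            rep = validity_metrics(0, 0, 50, 10)
        assert rep.ppv is None

    def test_empty_truth_classes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            validity_metrics(0, 5, 5, 0)
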