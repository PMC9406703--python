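"""Random Forest mechanics against brute-force CART, the planted rule, and
an established library cross-check."""

import numpy as np
import pytest

import jawcyst as jc
from jawcyst.errors import DegenerateInputError, FitError, ShapeError
from jawcyst.forest import _macro_f1

from conftest import rule_classifier

O, N = jc.ODONTOGENIC, jc.NON_ODONTOGENIC


class TestGini:
    def test_pure_node(self):
        assert jc.gini((5, 0)) == 0.0

    def test_maximal_two_class_impurity(self):
        assert jc.gini((4, 4)) == 0.5

    def test_three_one_split(self):
        assert jc.gini((3, 1)) == pytest.approx(1 - (0.75 ** 2 + 0.25 ** 2))

    def test_empty_node_rejected(self):
        with pytest.raises(DegenerateInputError):
            jc.gini((0, 0))


def brute_force_best_split(X, y, features):
    """Independent exhaustive search: every feature, every midpoint, gini
    recomputed by direct counting."""
    def g(labels):
        n = len(labels)
        if n == 0:
            return 0.0
        p1 = sum(labels) / n
        return 1 - p1 ** 2 - (1 - p1) ** 2

    n = len(y)
    parent = g(y)
    best = None
    for f in sorted(features):
        vals = sorted(set(X[:, f]))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left = [y[i] for i in range(n) if X[i, f] <= thr]
            right = [y[i] for i in range(n) if X[i, f] > thr]
            gain = parent - (len(left) * g(left) + len(right) * g(right)) / n
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (f, thr, gain)
    return best


class TestBestSplit:
    def test_worked_example_pure_children(self):
        X = np.array([[0.0], [0.0], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        f, thr, gain = jc.best_split(X, y, [0])
        assert (f, thr) == (0, pytest.approx(0.45))
        assert gain == pytest.approx(0.5)

    def test_constant_features_give_none(self):
        X = np.ones((6, 3))
        y = np.array([0, 1, 0, 1, 0, 1])
        assert jc.best_split(X, y, [0, 1, 2]) is None

    def test_pure_labels_give_none(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        assert jc.best_split(X, np.zeros(4, dtype=int), [0, 1]) is None

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            X = rng.random((12, 4)).round(1)
            y = rng.integers(0, 2, 12)
            ours = jc.best_split(X, y, range(4))
            oracle = brute_force_best_split(X, y, range(4))
            if oracle is None:
                assert ours is None
            else:
                assert ours[0] == oracle[0]
                assert ours[1] == pytest.approx(oracle[1])
                assert ours[2] == pytest.approx(oracle[2])


def brute_force_cart(X, y, min_samples_split=2):
    """Exhaustive greedy CART built independently of the package's grower."""
    def build(idx):
        labels = [y[i] for i in idx]
        if len(idx) < min_samples_split or len(set(labels)) == 1:
            return ("leaf", labels)
        split = brute_force_best_split(X[idx], np.array(labels), range(X.shape[1]))
        if split is None:
            return ("leaf", labels)
        f, thr, _ = split
        left = [i for i in idx if X[i, f] <= thr]
        right = [i for i in idx if X[i, f] > thr]
        return ("node", f, thr, build(left), build(right))

    return build(list(range(len(y))))


def cart_predict(tree, x):
    while tree[0] == "node":
        _, f, thr, left, right = tree
        tree = left if x[f] <= thr else right
    labels = tree[1]
    return int(sum(labels) > len(labels) - sum(labels))


class TestFitForest:
    def test_single_tree_equals_brute_force_cart(self):
        rng = np.random.default_rng(9)
        X = rng.random((20, 3)).round(1)
        y_int = rng.integers(0, 2, 20)
        y = np.array([jc.CLASS_ORDER[i] for i in y_int], dtype=object)
        model = jc.fit_forest(X, y, jc.ForestParams(n_trees=1, m_try=3), seed=0,
                              bootstrap=False)
        oracle = brute_force_cart(X, y_int)
        grid = rng.random((200, 3))
        pred, _ = jc.predict(model, grid)
        pred_int = np.array([jc.CLASS_ORDER.index(p) for p in pred])
        oracle_pred = np.array([cart_predict(oracle, x) for x in grid])
        assert np.array_equal(pred_int, oracle_pred)

    def test_planted_rule_training_accuracy(self, planted_dataset):
        X, y = planted_dataset
        model = jc.fit_forest(X, y, jc.ForestParams(n_trees=200), seed=1)
        pred, frac = jc.predict(model, X)
        assert (pred == y).mean() == 1.0
        assert ((frac >= 0) & (frac <= 1)).all()

    def test_determinism_same_seed(self, planted_dataset):
        X, y = planted_dataset
        a = jc.fit_forest(X[:80], y[:80], jc.ForestParams(n_trees=25), seed=3)
        b = jc.fit_forest(X[:80], y[:80], jc.ForestParams(n_trees=25), seed=3)
        pa, fa = jc.predict(a, X)
        pb, fb = jc.predict(b, X)
        assert np.array_equal(pa, pb)
        assert np.array_equal(fa, fb)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 37))
        with pytest.raises(FitError):
            jc.fit_forest(X, [O] * 10, jc.ForestParams(n_trees=2), seed=0)

    def test_wrong_dimensionality_rejected(self, planted_dataset):
        X, y = planted_dataset
        model = jc.fit_forest(X, y, jc.ForestParams(n_trees=5), seed=0)
        with pytest.raises(ShapeError):
            jc.predict(model, X[:, :10])


class TestPredictVoting:
    def test_tie_vote_goes_to_odontogenic(self):
        # two stumps voting 1-1 on any input
        t1 = jc.TreeNode(counts=(5, 0))  # odontogenic leaf
        t2 = jc.TreeNode(counts=(0, 5))  # non-odontogenic leaf
        model = jc.ForestModel([t1, t2], jc.ForestParams(n_trees=2, m_try=1), 0, 37)
        labels, frac = jc.predict(model, np.zeros((3, 37)))
        assert (labels == O).all()
        assert np.allclose(frac, 0.5)

    def test_unanimous_forest(self):
        model = jc.ForestModel([jc.TreeNode(counts=(5, 0))] * 3,
                               jc.ForestParams(n_trees=3, m_try=1), 0, 37)
        labels, frac = jc.predict(model, np.zeros((2, 37)))
        assert (labels == O).all() and np.allclose(frac, 1.0)

    def test_matches_rule_classifier_on_held_out(self, planted_dataset):
        X, y = planted_dataset
        tr, te = jc.split_80_20(y, seed=5)
        model = jc.fit_forest(X[tr], y[tr], jc.ForestParams(n_trees=300), seed=5)
        pred, _ = jc.predict(model, X[te])
        oracle = rule_classifier(X[te])
        assert (pred == oracle).mean() >= 0.98

    def test_matches_sklearn_forest_on_planted_rule(self, planted_dataset):
        """Independent route: an established Random Forest trained on the same
        features reaches the same (perfect) held-out behaviour."""
        from sklearn.ensemble import RandomForestClassifier

        X, y = planted_dataset
        tr, te = jc.split_80_20(y, seed=2)
        ours = jc.fit_forest(X[tr], y[tr], jc.ForestParams(n_trees=200), seed=2)
        ref = RandomForestClassifier(n_estimators=200, criterion="gini",
                                     max_features="sqrt", random_state=2)
        ref.fit(X[tr], y[tr].astype(str))
        ours_pred, _ = jc.predict(ours, X[te])
        ref_pred = ref.predict(X[te]).astype(object)
        assert (ours_pred == ref_pred).mean() >= 0.98


class TestImportanceDirection:
    def test_tooth_block_matters_sinus_does_not(self, planted_dataset):
        """Destroying the tooth-overlap information (dentition + 32 teeth)
        degrades held-out accuracy; destroying the sinus feature does not."""
        X, y = planted_dataset
        tr, te = jc.split_80_20(y, seed=7)
        model = jc.fit_forest(X[tr], y[tr], jc.ForestParams(n_trees=300), seed=7)
        rng = np.random.default_rng(7)

        def permuted_accuracy(cols):
            Xp = X[te].copy()
            for c in cols:
                Xp[:, c] = Xp[rng.permutation(len(te)), c]
            pred, _ = jc.predict(model, Xp)
            return (pred == y[te]).mean()

        base_pred, _ = jc.predict(model, X[te])
        base = (base_pred == y[te]).mean()
        dent = jc.FEATURE_NAMES.index("dentition")
        tooth_block = [dent] + list(range(len(jc.REGION_KEYS), 37))
        sinus = [jc.FEATURE_NAMES.index("maxillary_sinus")]
        assert permuted_accuracy(tooth_block) < base
        assert permuted_accuracy(sinus) >= base - 0.02


class TestSplit8020:
    def test_stratified_arithmetic(self):
        y = np.array([O] * 60 + [N] * 40, dtype=object)
        tr, te = jc.split_80_20(y, seed=0)
        assert len(tr) == 80 and len(te) == 20
        assert (y[tr] == O).sum() == 48 and (y[tr] == N).sum() == 32
        assert (y[te] == O).sum() == 12 and (y[te] == N).sum() == 8

    def test_disjoint_and_exhaustive(self):
        y = np.array([O, N] * 13, dtype=object)
        tr, te = jc.split_80_20(y, seed=4)
        assert set(tr) | set(te) == set(range(26))
        assert set(tr) & set(te) == set()

    def test_same_seed_same_split(self):
        y = np.array([O] * 30 + [N] * 20, dtype=object)
        assert np.array_equal(jc.split_80_20(y, 9)[0], jc.split_80_20(y, 9)[0])

    def test_rare_class_falls_back_unstratified(self):
        y = np.array([O] * 9 + [N], dtype=object)
        with pytest.warns(UserWarning, match="unstratified"):
            tr, te = jc.split_80_20(y, seed=0)
        assert len(tr) == 8 and len(te) == 2


class TestGridSearch:
    def test_single_cell_returned(self, planted_dataset):
        X, y = planted_dataset
        cell = jc.ForestParams(n_trees=10, m_try=3)
        best, table = jc.grid_search(X[:60], y[:60], [cell], k=3, seed=0)
        assert best == cell and len(table) == 1

    def test_prefers_strictly_better_cell(self, planted_dataset):
        """A forest restricted to depth 1 with 1 tree cannot represent the
        planted rule as well as an unrestricted one."""
        X, y = planted_dataset
        weak = jc.ForestParams(n_trees=1, m_try=1, max_depth=1)
        strong = jc.ForestParams(n_trees=100, m_try=6)
        best, table = jc.grid_search(X[:100], y[:100], [weak, strong], k=3, seed=1)
        assert best == strong
        assert table[1]["macro_f1"] > table[0]["macro_f1"]

    def test_deterministic_score_table(self, planted_dataset):
        X, y = planted_dataset
        grid = [jc.ForestParams(n_trees=10, m_try=3), jc.ForestParams(n_trees=10, m_try=6)]
        _, t1 = jc.grid_search(X[:60], y[:60], grid, k=3, seed=2)
        _, t2 = jc.grid_search(X[:60], y[:60], grid, k=3, seed=2)
        assert [c["macro_f1"] for c in t1] == [c["macro_f1"] for c in t2]


def test_macro_f1_agrees_with_per_class_reports():
    rng = np.random.default_rng(0)
    y = np.array([O if v else N for v in rng.integers(0, 2, 60)], dtype=object)
    p = np.array([O if v else N for v in rng.integers(0, 2, 60)], dtype=object)
    rep = jc.two_class_report(y, p, jc.CLASS_ORDER)
    expected = np.mean([rep[O].f1, rep[N].f1])
    assert _macro_f1(y, p) == pytest.approx(expected)


def test_save_load_round_trip(planted_dataset, tmp_path):
    X, y = planted_dataset
    model = jc.fit_forest(X[:80], y[:80], jc.ForestParams(n_trees=20), seed=6)
    path = tmp_path / "model.json"
    jc.save_forest(model, path)
    loaded = jc.load_forest(path)
    p1, f1 = jc.predict(model, X)
    p2, f2 = jc.predict(loaded, X)
    assert np.array_equal(p1, p2) and np.array_equal(f1, f2)
    assert loaded.params == model.params
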