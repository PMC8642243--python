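import numpy as np
import pytest

from cytoref import (
    Bound,
    GatingScheme,
    TreeLeaf,
    TreeSplit,
    balanced_subsample,
    evaluate_expert_scheme,
    evaluate_gate,
    fit_hypergate,
    fit_tree,
    otsu_threshold,
    split_by_cd34,
)
from cytoref.gating import hyperrectangle_mask


def route_oracle(scheme, x, names):
    """Event-by-event python routing through a tree."""
    out = []
    for row in x:
        node = scheme.tree
        while isinstance(node, TreeSplit):
            v = row[names.index(node.marker)]
            node = node.left if v <= node.threshold else node.right
        out.append(node.label)
    return np.array(out)


class TestEvaluateGate:
    def test_purity_recall_example(self):
        # gate captures 8 targets + 2 non-targets; 8 targets exist in total
        x = np.concatenate([np.full(8, 5.0), np.full(2, 5.0), np.full(10, 0.0)])[:, None]
        truth = np.array([True] * 8 + [False] * 12)
        scheme = GatingScheme(kind="hyperrectangle",
                              bounds=[Bound("m0", "min", 1.0)], target_population="t")
        m = evaluate_gate(scheme, x, truth, marker_names=["m0"])
        assert (m.tp, m.fp, m.fn) == (8, 2, 0)
        assert m.purity == pytest.approx(0.8)
        assert m.recall == 1.0

    def test_empty_gate_flagged(self):
        x = np.zeros((5, 1))
        scheme = GatingScheme(kind="hyperrectangle",
                              bounds=[Bound("m0", "min", 1.0)], target_population="t")
        with pytest.warns(UserWarning, match="empty gate"):
            m = evaluate_gate(scheme, x, np.array([True, True, False, False, False]),
                              marker_names=["m0"])
        assert m.empty_gate and m.purity == 0.0 and m.recall == 0.0

    def test_bookkeeping_identities(self, rng):
        """TP+FP = gate size and TP+FN = target size for random schemes."""
        for _ in range(10):
            x = rng.normal(size=(100, 4))
            truth = rng.random(100) < 0.3
            bounds = [Bound(f"m{j}", "min", float(rng.normal()))
                      for j in rng.choice(4, size=2, replace=False)]
            scheme = GatingScheme(kind="hyperrectangle", bounds=bounds,
                                  target_population="t")
            names = [f"m{j}" for j in range(4)]
            m = evaluate_gate(scheme, x, truth, marker_names=names)
            gate = hyperrectangle_mask(bounds, x, marker_names=names)
            assert m.tp + m.fp == gate.sum()
            assert m.tp + m.fn == truth.sum()

    def test_tree_routing_matches_oracle(self, rng):
        x = rng.normal(size=(200, 3))
        labels = rng.choice(["a", "b", "c"], size=200)
        names = ["m0", "m1", "m2"]
        tree = TreeSplit("m0", 0.1,
                         TreeLeaf("a"),
                         TreeSplit("m2", -0.5, TreeLeaf("b"), TreeLeaf("c")))
        scheme = GatingScheme(kind="tree", tree=tree)
        results = evaluate_gate(scheme, x, labels, marker_names=names)
        routed = route_oracle(scheme, x, names)
        for r in results:
            assert r["metrics"].tp + r["metrics"].fn == np.sum(labels == r["label"])
        # leaf gates partition the events
        assert sum(r["metrics"].gate_size for r in results) == 200
        # per-label gate totals agree with event-by-event oracle routing
        counts = {lab: np.sum(routed == lab) for lab in set(routed)}
        sizes = {}
        for r in results:
            sizes[r["label"]] = sizes.get(r["label"], 0) + r["metrics"].gate_size
        assert sizes == {k: int(v) for k, v in counts.items()}

    def test_unknown_marker_errors(self):
        scheme = GatingScheme(kind="hyperrectangle",
                              bounds=[Bound("missing", "min", 0.0)],
                              target_population="t")
        with pytest.raises(KeyError):
            evaluate_gate(scheme, np.zeros((3, 1)), np.array([True, False, False]),
                          marker_names=["m0"])


def cart_oracle_depth2(x, labels, min_leaf):
    """Exhaustive-split CART oracle at depth <= 2 (Gini), predicting labels."""
    def gini(y):
        _, c = np.unique(y, return_counts=True)
        p = c / c.sum()
        return 1 - (p**2).sum()

    def best_split(idx):
        y = labels[idx]
        best = None
        for j in range(x.shape[1]):
            vs = np.unique(x[idx, j])
            for t in (vs[:-1] + vs[1:]) / 2:
                left = idx[x[idx, j] <= t]
                right = idx[x[idx, j] > t]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                score = (len(left) * gini(labels[left])
                         + len(right) * gini(labels[right])) / len(idx)
                if best is None or score < best[0] - 1e-12:
                    best = (score, j, t, left, right)
        return best

    def majority(idx):
        vals, counts = np.unique(labels[idx], return_counts=True)
        return vals[np.argmax(counts)]

    pred = np.empty(len(labels), dtype=object)
    root = best_split(np.arange(len(labels)))
    if root is None:
        pred[:] = majority(np.arange(len(labels)))
        return pred
    for side in (root[3], root[4]):
        if gini(labels[side]) > 0:
            sub = best_split(side)
            if sub is not None:
                pred[sub[3]] = majority(sub[3])
                pred[sub[4]] = majority(sub[4])
                continue
        pred[side] = majority(side)
    return pred


class TestFitTree:
    def test_perfectly_separable_single_split(self, rng):
        x = np.concatenate([rng.normal(0, 0.5, 50), rng.normal(10, 0.5, 50)])[:, None]
        labels = np.array(["neg"] * 50 + ["pos"] * 50)
        scheme = fit_tree(x, labels, max_markers=5, min_leaf=5, marker_names=["A"])
        assert isinstance(scheme.tree, TreeSplit)
        assert isinstance(scheme.tree.left, TreeLeaf)
        assert isinstance(scheme.tree.right, TreeLeaf)
        for r in evaluate_gate(scheme, x, labels, marker_names=["A"]):
            assert r["metrics"].purity == 1.0

    def test_marker_budget_binds(self, rng):
        # classes need two markers; budget of 1 forces an impure leaf
        x = rng.uniform(0, 1, size=(300, 2))
        labels = np.where(x[:, 0] > 0.5, "a", np.where(x[:, 1] > 0.5, "b", "c"))
        scheme = fit_tree(x, labels, max_markers=1, min_leaf=10,
                          marker_names=["m0", "m1"])
        assert len(scheme.markers_used()) <= 1
        purities = [r["metrics"].purity
                    for r in evaluate_gate(scheme, x, labels, marker_names=["m0", "m1"])]
        assert min(purities) < 1.0

    def test_budget_never_exceeded(self, rng):
        x = rng.normal(size=(400, 6))
        labels = rng.choice(["a", "b", "c", "d"], size=400)
        for budget in (1, 2, 3):
            scheme = fit_tree(x, labels, max_markers=budget, min_leaf=20)
            assert len(scheme.markers_used()) <= budget

    def test_continuous_beats_otsu_binarized(self, rng):
        """Fully grown continuous trees reach training purity at least that
        of the Otsu-binarized variant: continuous splits are a superset of
        the single binarized split per marker."""
        def training_purity(scheme, x, labels, names):
            res = evaluate_gate(scheme, x, labels, marker_names=names)
            correct = sum(r["metrics"].tp for r in res)
            return correct / len(labels)

        for seed in range(8):
            r2 = np.random.default_rng(seed)
            centers = r2.uniform(0, 6, size=(3, 4))
            x = np.concatenate([r2.normal(c, 1.0, size=(60, 4)) for c in centers])
            labels = np.repeat(["a", "b", "c"], 60)
            names = [f"m{j}" for j in range(4)]
            cont = fit_tree(x, labels, max_markers=4, min_leaf=1, marker_names=names)
            otsu = fit_tree(x, labels, max_markers=4, min_leaf=1, marker_names=names,
                            binarize=True)
            assert (training_purity(cont, x, labels, names)
                    >= training_purity(otsu, x, labels, names) - 1e-12)

    def test_matches_exhaustive_cart_oracle_depth2(self):
        rng = np.random.default_rng(7)
        # 3-class axis-aligned structure recoverable at depth 2
        n = 90
        a = np.column_stack([rng.uniform(0, 1, n), rng.uniform(0, 2, n)])
        b = np.column_stack([rng.uniform(2, 3, n), rng.uniform(0, 1, n)])
        c = np.column_stack([rng.uniform(2, 3, n), rng.uniform(1.5, 2, n)])
        x = np.concatenate([a, b, c])
        labels = np.repeat(["a", "b", "c"], n)
        scheme = fit_tree(x, labels, max_markers=2, min_leaf=20,
                          marker_names=["m0", "m1"])
        pred = route_oracle(scheme, x, ["m0", "m1"])
        oracle_pred = cart_oracle_depth2(x, labels, min_leaf=20)
        assert np.array_equal(pred, oracle_pred)

    def test_degenerate_input_single_leaf(self):
        x = np.ones((50, 3))
        labels = np.array(["a", "b"] * 25)
        with pytest.warns(UserWarning, match="single leaf"):
            scheme = fit_tree(x, labels, min_leaf=5)
        assert isinstance(scheme.tree, TreeLeaf)


class TestFitHypergate:
    def test_recovers_planted_rectangle(self, rng):
        x = rng.uniform(0, 10, size=(400, 3))
        target = (x[:, 0] >= 3) & (x[:, 0] <= 7) & (x[:, 1] >= 2) & (x[:, 1] <= 6)
        res = fit_hypergate(x, target, beta=1.0, marker_names=["a", "b", "c"])
        gate = hyperrectangle_mask(res.scheme.bounds, x, marker_names=["a", "b", "c"])
        assert np.array_equal(gate, target)
        m = evaluate_gate(res.scheme, x, target, marker_names=["a", "b", "c"])
        assert m.purity == 1.0 and m.recall == 1.0
        assert res.f_beta == pytest.approx(1.0)

    def test_monotone_ascent_history(self, rng):
        x = rng.normal(size=(300, 4))
        target = (x[:, 0] > 0.3) & (x[:, 2] < 0.5)
        res = fit_hypergate(x, target)
        assert all(b >= a - 1e-12 for a, b in zip(res.history, res.history[1:]))

    def test_uncorrelated_marker_dropped(self, rng):
        x = rng.uniform(0, 10, size=(500, 3))
        target = (x[:, 0] >= 4) & (x[:, 0] <= 8)
        res = fit_hypergate(x, target, max_markers=1, marker_names=["sig", "n1", "n2"])
        assert res.contributions["n1"] <= res.contributions["sig"]
        assert set(res.scheme.markers_used()) <= {"sig"}

    def test_budget_respected(self, rng):
        x = rng.normal(size=(300, 5))
        target = (x[:, 0] > 0) & (x[:, 1] > 0) & (x[:, 2] > 0)
        for budget in (1, 2, 3):
            res = fit_hypergate(x, target, max_markers=budget)
            assert len(res.scheme.markers_used()) <= budget

    def test_beats_every_single_threshold_gate(self, rng):
        """Final F1 >= the best exhaustive one-bound gate (lower-bound oracle)."""
        x = rng.normal(size=(200, 3))
        target = (x[:, 0] + 0.5 * x[:, 1] > 0.3)
        res = fit_hypergate(x, target)
        n_target = target.sum()

        def f1(gate):
            tp = np.sum(gate & target)
            if tp == 0:
                return 0.0
            purity = tp / gate.sum()
            recall = tp / n_target
            return 2 * purity * recall / (purity + recall)

        best = 0.0
        for j in range(3):
            for t in x[:, j]:
                best = max(best, f1(x[:, j] >= t), f1(x[:, j] <= t))
        assert res.f_beta >= best - 1e-12

    def test_degenerate_target_errors(self, rng):
        x = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_hypergate(x, np.zeros(10, dtype=bool))


class TestBalancedSubsample:
    def test_sizes(self):
        labels = np.array(["a"] * 10 + ["b"] * 20 + ["c"] * 30)
        idx = balanced_subsample(labels, seed=0)
        assert len(idx) == 30
        vals, counts = np.unique(labels[idx], return_counts=True)
        assert np.all(counts == 10)

    def test_equal_classes_keep_everything(self):
        labels = np.array(["a"] * 15 + ["b"] * 15)
        idx = balanced_subsample(labels, seed=3)
        assert np.array_equal(idx, np.arange(30))

    def test_deterministic_under_seed(self):
        labels = np.repeat(["a", "b", "c"], [50, 80, 120])
        assert np.array_equal(balanced_subsample(labels, seed=17),
                              balanced_subsample(labels, seed=17))


class TestSplitByCd34:
    def test_example(self):
        x = np.array([[0.9], [0.96]])
        pos, neg = split_by_cd34(x, cd34_marker="CD34", marker_names=["CD34"])
        assert list(pos) == [1] and list(neg) == [0]

    def test_all_below_warns(self):
        with pytest.warns(UserWarning, match="cutoff"):
            pos, neg = split_by_cd34(np.zeros((5, 1)), cd34_marker="CD34",
                                     marker_names=["CD34"])
        assert len(pos) == 0 and len(neg) == 5

    def test_matches_direct_comparison(self, rng):
        x = rng.uniform(0, 2, size=(100, 1))
        pos, neg = split_by_cd34(x, cd34_marker="CD34", cutoff=0.95,
                                 marker_names=["CD34"])
        assert np.array_equal(pos, np.flatnonzero(x[:, 0] > 0.95))
        assert np.array_equal(neg, np.flatnonzero(x[:, 0] <= 0.95))

    def test_missing_marker_errors(self):
        with pytest.raises(KeyError):
            split_by_cd34(np.zeros((3, 1)), cd34_marker="CD34", marker_names=["other"])


class TestExpertScheme:
    def test_single_positive_predicate_equals_upper_otsu_class(self, rng):
        a = np.concatenate([rng.normal(0, 1, 300), rng.normal(8, 1, 300)])
        x = a[:, None]
        truth = a > 4
        m = evaluate_expert_scheme([("A", "+")], x, truth, marker_names=["A"])
        t = otsu_threshold(a)
        expected = a > t
        assert m.tp + m.fp == expected.sum()

    def test_contradictory_predicates_empty_gate(self, rng):
        # under fixed thresholds, A+ then A- is an empty conjunction
        a = np.concatenate([rng.normal(0, 1, 100), rng.normal(8, 1, 100)])
        t = otsu_threshold(a)
        with pytest.warns(UserWarning, match="empty gate"):
            m = evaluate_expert_scheme([("A", "+"), ("A", "-")], a[:, None],
                                       a > 4, marker_names=["A"],
                                       fixed_thresholds={"A": t})
        assert m.recall == 0.0 and m.gate_size == 0

    def test_three_step_matches_manual_oracle(self, rng):
        x = np.column_stack([
            np.concatenate([rng.normal(0, 1, 200), rng.normal(6, 1, 200)]),
            rng.normal(3, 2, 400),
            np.concatenate([rng.normal(5, 1, 100), rng.normal(0, 1, 300)]),
        ])
        truth = rng.random(400) < 0.4
        preds = [("m0", "+"), ("m1", "-"), ("m2", "+")]
        got = evaluate_expert_scheme(preds, x, truth, marker_names=["m0", "m1", "m2"])
        # manual sequential oracle with recomputed thresholds
        retained = np.ones(400, dtype=bool)
        for marker, sign in preds:
            j = ["m0", "m1", "m2"].index(marker)
            t = otsu_threshold(x[retained, j])
            retained &= (x[:, j] > t) if sign == "+" else (x[:, j] <= t)
        assert got.tp == np.sum(retained & truth)
        assert got.fp == np.sum(retained & ~truth)

    def test_degenerate_step_reports_index(self):
        x = np.column_stack([np.concatenate([np.zeros(50), np.ones(50)]),
                             np.ones(100)])
        with pytest.raises(ValueError, match="step 1"):
            evaluate_expert_scheme([("m0", "+"), ("m1", "+")], x,
                                   np.ones(100, dtype=bool), marker_names=["m0", "m1"])
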