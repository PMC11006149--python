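"""Rule extraction: Gini trees over literals, pruning, rules, metrics."""

import numpy as np
import pytest

import _oracles
from conftest import make_literal_table
from convrules.rules import (
    EvaluationReport,
    apply_rules,
    evaluate,
    induce_tree,
    intervene,
    prune_tree,
    tree_to_dot,
    tree_to_rules,
)


def random_literals(rng, n, k):
    return rng.choice([-1, 1], size=(n, k))


def planted_targets(values, a=0, b=1):
    # planted rule: literal a positive AND literal b negative -> class 1
    return ((values[:, a] == 1) & (values[:, b] == -1)).astype(int)


class TestInduction:
    def test_planted_rule_recovered_exactly(self):
        rng = np.random.default_rng(0)
        lit = make_literal_table(random_literals(rng, 64, 6))
        targets = planted_targets(lit.values)
        tree = induce_tree(lit, targets, max_depth=3)
        assert np.array_equal(tree.predict(lit), targets)
        used = tree_to_rules(tree).kernel_vocabulary
        assert set(used) <= {0, 1}

    def test_pure_targets_single_leaf(self):
        lit = make_literal_table(random_literals(np.random.default_rng(1), 20, 3))
        tree = induce_tree(lit, np.ones(20, dtype=int))
        assert tree.root.is_leaf and tree.root.prediction == 1

    def test_xor_not_separable_at_depth_one(self):
        rng = np.random.default_rng(2)
        values = random_literals(rng, 80, 2)
        targets = (values[:, 0] != values[:, 1]).astype(int)
        lit = make_literal_table(values)
        shallow = induce_tree(lit, targets, max_depth=1)
        assert np.mean(shallow.predict(lit) == targets) < 1.0
        deep = induce_tree(lit, targets, max_depth=2)
        assert np.mean(deep.predict(lit) == targets) == 1.0

    def test_no_kernel_repeats_on_any_path(self):
        rng = np.random.default_rng(3)
        lit = make_literal_table(random_literals(rng, 100, 5))
        targets = rng.integers(0, 2, 100)
        tree = induce_tree(lit, targets, max_depth=4, min_leaf=1)

        def walk(node, seen):
            if node.is_leaf:
                return
            assert node.kernel not in seen
            walk(node.neg, seen | {node.kernel})
            walk(node.pos, seen | {node.kernel})

        walk(tree.root, set())

    def test_empty_or_denied_everything_rejected(self):
        lit = make_literal_table(random_literals(np.random.default_rng(4), 10, 2))
        with pytest.raises(ValueError, match="empty"):
            induce_tree(make_literal_table(np.empty((0, 2))), np.array([], dtype=int))
        with pytest.raises(ValueError, match="vocabulary"):
            induce_tree(lit, np.zeros(10, dtype=int), denied_kernels=[0, 1])

    def test_greedy_near_exhaustive_optimum(self):
        """Greedy Gini induction lands within 5 points of the best depth-3
        tree found by exhaustive search, over random small tables."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            values = random_literals(rng, 48, 5)
            noise = rng.random(48) < 0.05
            targets = planted_targets(values) ^ noise
            lit = make_literal_table(values)
            tree = induce_tree(lit, targets.astype(int), max_depth=3, min_leaf=1)
            greedy_err = int(np.sum(tree.predict(lit) != targets))
            best_err = _oracles.best_tree_errors(values, targets.astype(int), 3)
            assert greedy_err <= best_err + 0.05 * len(targets)

    def test_agrees_with_sklearn_on_unconstrained_fit(self):
        """Independent cross-check: sklearn's Gini tree at the same depth
        reaches the same training fidelity on random tables."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(6)
        for _ in range(5):
            values = random_literals(rng, 120, 6)
            targets = ((values[:, 2] == 1) | (values[:, 4] == -1)).astype(int)
            lit = make_literal_table(values)
            ours = induce_tree(lit, targets, max_depth=3, min_leaf=1)
            acc_ours = np.mean(ours.predict(lit) == targets)
            sk = DecisionTreeClassifier(criterion="gini", max_depth=3, random_state=0)
            sk.fit(values, targets)
            acc_sk = sk.score(values, targets)
            assert abs(acc_ours - acc_sk) <= 0.05


class TestPruning:
    def test_single_leaf_unchanged(self):
        lit = make_literal_table(random_literals(np.random.default_rng(7), 12, 2))
        tree = induce_tree(lit, np.zeros(12, dtype=int))
        pruned = prune_tree(tree, lit, np.zeros(12, dtype=int))
        assert pruned.root.is_leaf

    def test_same_class_leaves_collapse(self):
        rng = np.random.default_rng(8)
        values = random_literals(rng, 60, 3)
        targets = (values[:, 0] == 1).astype(int)
        lit = make_literal_table(values)
        # force an overgrown tree, then prune on the training data itself:
        # subtrees whose leaves agree must merge
        tree = induce_tree(lit, targets, max_depth=3, min_leaf=1)
        pruned = prune_tree(tree, lit, targets)
        assert pruned.n_nodes() <= 3  # root split on kernel 0 plus two leaves

    def test_reduced_error_pruning_on_noisy_data(self):
        rng = np.random.default_rng(9)
        values = random_literals(rng, 200, 6)
        clean = planted_targets(values)
        noisy = clean ^ (rng.random(200) < 0.05)
        lit_train = make_literal_table(values[:150])
        lit_val = make_literal_table(values[150:])
        tree = induce_tree(lit_train, noisy[:150].astype(int), max_depth=4, min_leaf=1)
        pruned = prune_tree(tree, lit_val, noisy[150:].astype(int))
        assert pruned.n_nodes() <= tree.n_nodes()
        fid_before = np.mean(tree.predict(lit_val) == noisy[150:])
        fid_after = np.mean(pruned.predict(lit_val) == noisy[150:])
        assert fid_after >= fid_before - 0.01

    def test_empty_validation_warns_and_skips(self):
        lit = make_literal_table(random_literals(np.random.default_rng(10), 20, 3))
        targets = (lit.values[:, 0] == 1).astype(int)
        tree = induce_tree(lit, targets)
        with pytest.warns(UserWarning, match="empty"):
            pruned = prune_tree(tree, make_literal_table(np.empty((0, 3))), np.array([], dtype=int))
        assert pruned.n_nodes() == tree.n_nodes()


class TestRules:
    def test_complete_depth_two_tree_gives_four_rules(self):
        rng = np.random.default_rng(11)
        values = random_literals(rng, 200, 2)
        targets = (values[:, 0] != values[:, 1]).astype(int)  # XOR needs full tree
        rules = tree_to_rules(induce_tree(make_literal_table(values), targets, max_depth=2))
        assert len(rules.rules) == 4
        assert all(len(r.body) == 2 for r in rules.rules)

    def test_negative_conjunction_rule_formatting(self):
        # the characteristic shape: both literals negated implying the disease
        values = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]] * 10)
        targets = ((values[:, 0] == -1) & (values[:, 1] == -1)).astype(int)
        rules = tree_to_rules(induce_tree(make_literal_table(values), targets, max_depth=2))
        codes = {0: "ET", 1: "PA"}
        formatted = [r.format(codes) for r in rules.rules]
        assert "¬ET ∧ ¬PA → Effusion" in formatted

    def test_rules_partition_and_match_tree(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            values = random_literals(rng, 50, 4)
            targets = rng.integers(0, 2, 50)
            lit = make_literal_table(values)
            tree = induce_tree(lit, targets, max_depth=3, min_leaf=1)
            rules = tree_to_rules(tree)
            fresh = make_literal_table(random_literals(rng, 80, 4))
            assert np.array_equal(apply_rules(rules, fresh), tree.predict(fresh))

    def test_round_trip_reinduction(self):
        rng = np.random.default_rng(13)
        values = random_literals(rng, 64, 4)
        targets = planted_targets(values, 2, 3)
        lit = make_literal_table(values)
        rules = tree_to_rules(induce_tree(lit, targets, max_depth=3))
        preds = apply_rules(rules, lit)
        retree = induce_tree(lit, preds, max_depth=3)
        assert np.array_equal(retree.predict(lit), preds)

    def test_missing_kernel_column_rejected(self):
        rng = np.random.default_rng(17)
        values = np.column_stack([rng.choice([-1, 1], 20), np.tile([1, -1], 10)])
        rules = tree_to_rules(
            induce_tree(make_literal_table(values), (values[:, 1] == 1).astype(int))
        )
        assert rules.kernels_used() == {1}
        with pytest.raises(KeyError):
            apply_rules(rules, make_literal_table(values[:, :1]))

    def test_dot_export_mentions_codes(self):
        values = np.array([[1], [-1]] * 8)
        tree = induce_tree(make_literal_table(values), (values[:, 0] == 1).astype(int))
        dot = tree_to_dot(tree, {0: "QN"})
        assert dot.startswith("digraph") and "QN" in dot


class TestEvaluate:
    def test_confusion_count_formulas(self):
        """Sensitivity/specificity formulas on constructed counts:
        TP=93, FN=7, TN=96, FP=4 per 100 images/class."""
        labels = np.array([1] * 100 + [0] * 100)
        preds = np.array([1] * 93 + [0] * 7 + [0] * 96 + [1] * 4)
        rep = EvaluationReport.from_predictions(preds, labels, preds)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (93, 7, 96, 4)
        assert rep.sensitivity == pytest.approx(0.930)
        assert rep.specificity == pytest.approx(0.960)
        assert rep.accuracy == pytest.approx(0.945)
        assert rep.fidelity == 1.0

    def test_fidelity_is_against_cnn_not_labels(self):
        labels = np.array([0, 0, 1, 1])
        cnn = np.array([0, 1, 1, 0])
        preds = cnn.copy()
        rep = EvaluationReport.from_predictions(preds, labels, cnn)
        assert rep.fidelity == 1.0
        assert rep.accuracy == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EvaluationReport.from_predictions(np.zeros(3), np.zeros(4), np.zeros(3))


class TestIntervention:
    def test_no_constraints_match_baseline(self):
        rng = np.random.default_rng(14)
        values = random_literals(rng, 60, 5)
        targets = planted_targets(values)
        lit = make_literal_table(values, labels=targets)
        res = intervene(lit, targets, targets)
        assert res.fidelity_delta == 0.0
        assert res.rules.to_json() == res.baseline_rules.to_json()

    def test_denied_root_kernel_never_reappears(self):
        rng = np.random.default_rng(15)
        values = random_literals(rng, 80, 6)
        targets = planted_targets(values)
        lit = make_literal_table(values, labels=targets)
        root = induce_tree(lit, targets).root.kernel
        res = intervene(lit, targets, targets, deny=[root])
        assert root not in res.rules.kernels_used()

    def test_redundant_signal_supports_reformation(self):
        """With two redundant planted signals, denying the first signal's
        kernel re-forms the rule set on the second at similar fidelity."""
        rng = np.random.default_rng(16)
        base = rng.choice([-1, 1], size=(120, 1))
        noise = random_literals(rng, 120, 4)
        values = np.hstack([base, base.copy(), noise])  # kernels 0 and 1 redundant
        targets = (values[:, 0] == 1).astype(int)
        lit = make_literal_table(values, labels=targets)
        res = intervene(lit, targets, targets, deny=[0])
        assert 0 not in res.rules.kernels_used()
        assert 1 in res.rules.kernels_used()
        assert abs(res.fidelity_delta) <= 0.05

    def test_conflicting_allow_deny_rejected(self):
        values = np.array([[1, -1], [-1, 1]] * 5)
        lit = make_literal_table(values)
        with pytest.raises(ValueError, match="allowed and denied"):
            induce_tree(lit, np.zeros(10, dtype=int), allowed_kernels=[0], denied_kernels=[0])
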