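"""Alternating decision tree: training, traversal scoring, rule export.

The reference oracle used here retrains the tree in pure Python with
explicit instance subsets and an exhaustive scan of every (prediction
node, condition) candidate, fully independent of the vectorized learner.
"""

import math

import numpy as np
import pytest

from hexamyloid.adtree import (
    ADTreeModel,
    Condition,
    PredictionNode,
    SplitterNode,
    train_adtree,
)
from hexamyloid.alphabet import AMINO_ACIDS

from conftest import random_dataset


# ---------------------------------------------------------------------------
# pure-Python reference trainer (independent oracle)


def oracle_train(sequences, labels, iterations, smoothing):
    """Reference ADTree boosting with explicit sets and loops.

    Returns a list of (parent_node_index, position, residue, a, b) per
    iteration plus the root value and the per-iteration exponential loss.
    """
    n = len(sequences)
    y = [1.0 if l else -1.0 for l in labels]

    def half_log_odds(wp, wn):
        return 0.5 * math.log((wp + smoothing) / (wn + smoothing))

    w = [1.0] * n
    wp0 = sum(w[i] for i in range(n) if y[i] > 0)
    wn0 = sum(w[i] for i in range(n) if y[i] < 0)
    root_value = half_log_odds(wp0, wn0)
    for i in range(n):
        w[i] *= math.exp(-y[i] * root_value)

    # prediction nodes as explicit instance index sets, creation order
    node_sets = [set(range(n))]
    steps = []
    losses = []
    for _ in range(iterations):
        total_w = sum(w)
        best = None  # (Z, cond_index, node_index, data)
        for j, members in enumerate(node_sets):
            w_node = sum(w[i] for i in members)
            for c in range(120):
                pos, res = c // 20, AMINO_ACIDS[c % 20]
                inside = {i for i in members if sequences[i][pos] == res}
                outside = members - inside
                wp_in = sum(w[i] for i in inside if y[i] > 0)
                wn_in = sum(w[i] for i in inside if y[i] < 0)
                wp_out = sum(w[i] for i in outside if y[i] > 0)
                wn_out = sum(w[i] for i in outside if y[i] < 0)
                Z = (
                    2.0 * (math.sqrt(wp_in * wn_in) + math.sqrt(wp_out * wn_out))
                    + (total_w - w_node)
                )
                cand = (Z, c, j, (inside, outside, wp_in, wn_in, wp_out, wn_out))
                if best is None:
                    best = cand
                else:
                    tol = 1e-9 * (1.0 + abs(min(best[0], Z)))
                    if Z < best[0] - tol:
                        best = cand
                    elif abs(Z - best[0]) <= tol and (c, j) < (best[1], best[2]):
                        best = (best[0], c, j, cand[3])

        _, c, j, (inside, outside, wp_in, wn_in, wp_out, wn_out) = best
        a = half_log_odds(wp_in, wn_in)
        b = half_log_odds(wp_out, wn_out)
        steps.append((j, c // 20 + 1, AMINO_ACIDS[c % 20], a, b))
        node_sets.append(inside)
        node_sets.append(outside)
        for i in inside:
            w[i] *= math.exp(-y[i] * a)
        for i in outside:
            w[i] *= math.exp(-y[i] * b)
        losses.append(sum(w))  # w_i == exp(-y_i * F(x_i))
    return root_value, steps, losses


def model_steps(model: ADTreeModel):
    """(parent_node_creation_index, position, residue, a, b) per splitter.

    Prediction nodes are numbered in creation order: root first, then the
    true/false children of each splitter in boosting order.
    """
    index_of = {id(model.root): 0}
    counter = 1
    out = []
    for sp in model.splitters():  # sorted by boosting order
        parent = _find_parent(model.root, sp)
        out.append(
            (
                index_of[id(parent)],
                sp.condition.position,
                sp.condition.residue,
                sp.true_child.value,
                sp.false_child.value,
            )
        )
        index_of[id(sp.true_child)] = counter
        index_of[id(sp.false_child)] = counter + 1
        counter += 2
    return out


def _find_parent(node, splitter):
    for sp in node.children:
        if sp is splitter:
            return node
        for child in (sp.true_child, sp.false_child):
            found = _find_parent(child, splitter)
            if found is not None:
                return found
    return None


# ---------------------------------------------------------------------------
# tests


class TestTraining:
    def test_zero_iterations_balanced_root_zero(self):
        seqs = ["NNQQNY", "AAAAAA"]
        model = train_adtree((seqs, [True, False]), iterations=0)
        assert model.root.value == 0.0
        assert model.splitters() == []

    def test_toy_first_condition_is_aa4_i(self, toy_signal_data):
        seqs, labels = toy_signal_data
        model = train_adtree((seqs, labels), iterations=1)
        rule = model.rules()[0]
        assert rule.condition == Condition(4, "I")
        assert rule.true_value > 0 > rule.false_value

    def test_matches_exhaustive_oracle_on_toy(self, toy_signal_data):
        seqs, labels = toy_signal_data
        model = train_adtree((seqs, labels), iterations=3)
        root_ref, steps_ref, _ = oracle_train(seqs, labels, 3, 1.0)
        assert model.root.value == pytest.approx(root_ref)
        got = model_steps(model)
        for (pj, pp, pr, pa, pb), (oj, op, osr, oa, ob) in zip(got, steps_ref):
            assert (pj, pp, pr) == (oj, op, osr)
            assert pa == pytest.approx(oa)
            assert pb == pytest.approx(ob)

    def test_deterministic(self, rng):
        ds = random_dataset(rng, 40)
        m1 = train_adtree(ds, iterations=5)
        m2 = train_adtree(ds, iterations=5)
        assert m1.to_json() == m2.to_json()

    def test_exponential_loss_non_increasing(self, rng):
        for smoothing in (1.0, 1e-6):
            ds = random_dataset(rng, 40)
            seqs, labels = ds.sequences, list(ds.labels)
            y = np.where(ds.labels, 1.0, -1.0)
            losses = []
            for t in range(0, 6):
                model = train_adtree((seqs, labels), iterations=t, smoothing=smoothing)
                scores = model.decision_function(seqs)
                losses.append(float(np.exp(-y * scores).sum()))
            assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            train_adtree((["NNQQNY", "AAAAAA"], [True, True]), iterations=1)

    def test_negative_iterations_error(self):
        with pytest.raises(ValueError):
            train_adtree((["NNQQNY", "AAAAAA"], [True, False]), iterations=-1)

    def test_unknown_tie_policy_error(self):
        with pytest.raises(ValueError):
            train_adtree((["NNQQNY"], [True]), iterations=0, tie_policy="random")


class TestScoring:
    def test_root_only_model_constant(self):
        model = ADTreeModel(PredictionNode(0.37), iterations=0, smoothing=1.0)
        assert model.predict_score("NNQQNY") == 0.37
        assert model.predict_score("AAAAAA") == 0.37

    def test_single_splitter_traversal(self):
        root = PredictionNode(0.1)
        root.children.append(
            SplitterNode(Condition(4, "I"), PredictionNode(0.9), PredictionNode(-0.2), 0)
        )
        model = ADTreeModel(root, iterations=1, smoothing=1.0)
        assert model.predict_score("NNQINY") == pytest.approx(1.0)
        assert model.predict_score("NNQQNY") == pytest.approx(-0.1)

    def test_traversal_equals_path_predicate_oracle(self, rng):
        ds = random_dataset(rng, 60)
        model = train_adtree(ds, iterations=6)

        # brute force: every prediction node contributes iff its full path
        # predicate (conjunction of branch conditions from the root) holds
        def collect(node, path, out):
            out.append((path, node.value))
            for sp in node.children:
                collect(sp.true_child, path + [(sp.condition, True)], out)
                collect(sp.false_child, path + [(sp.condition, False)], out)

        nodes: list = []
        collect(model.root, [], nodes)

        from conftest import random_peptides

        for pep in random_peptides(rng, 200):
            brute = sum(
                value
                for path, value in nodes
                if all(cond.matches(pep) == branch for cond, branch in path)
            )
            assert model.predict_score(pep) == pytest.approx(brute, abs=1e-12)

    def test_score_decomposition_on_subtree_removal(self, rng):
        ds = random_dataset(rng, 60)
        model = train_adtree(ds, iterations=5)
        # remove the deepest splitter (largest order) from its parent
        target = model.splitters()[-1]
        parent = _find_parent(model.root, target)
        before = {p: model.predict_score(p) for p in ds.sequences}
        parent.children.remove(target)
        after = {p: model.predict_score(p) for p in ds.sequences}
        # collect the parent's path predicate
        def path_of(node, goal, acc):
            if node is goal:
                return acc
            for sp in node.children:
                for child, branch in ((sp.true_child, True), (sp.false_child, False)):
                    found = path_of(child, goal, acc + [(sp.condition, branch)])
                    if found is not None:
                        return found
            return None

        path = path_of(model.root, parent, [])
        for pep in ds.sequences:
            on_path = all(cond.matches(pep) == branch for cond, branch in path)
            if not on_path:
                assert after[pep] == pytest.approx(before[pep])

    def test_probability_is_logistic_of_margin(self, rng):
        ds = random_dataset(rng, 30)
        model = train_adtree(ds, iterations=3)
        scores = model.decision_function(ds.sequences)
        probs = model.predict_proba(ds.sequences)
        np.testing.assert_allclose(probs, 1.0 / (1.0 + np.exp(-2.0 * scores)))
        assert ((probs > 0.5) == (scores > 0)).all()


class TestExport:
    def test_single_splitter_format(self):
        root = PredictionNode(0.0)
        root.children.append(
            SplitterNode(Condition(4, "I"), PredictionNode(0.9), PredictionNode(-0.2), 0)
        )
        model = ADTreeModel(root, iterations=1, smoothing=1.0)
        assert str(model.rules()[0]) == "1: AA4 | I 0.900 | !I -0.200"

    def test_rule_count_equals_iterations(self, rng):
        ds = random_dataset(rng, 40)
        for k in (0, 3, 7):
            assert len(train_adtree(ds, iterations=k).rules()) == k

    def test_rules_ordered_by_boosting_iteration(self, rng):
        ds = random_dataset(rng, 40)
        model = train_adtree(ds, iterations=5)
        assert [r.number for r in model.rules()] == [1, 2, 3, 4, 5]

    def test_json_round_trip(self, rng):
        ds = random_dataset(rng, 40)
        model = train_adtree(ds, iterations=5)
        back = ADTreeModel.from_json(model.to_json())
        assert back.format_rules() == model.format_rules()
        peps = ds.sequences[:20]
        np.testing.assert_allclose(
            back.decision_function(peps), model.decision_function(peps)
        )
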