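"""Decision-tree representation, routing semantics, and greedy induction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from schwannoma.trees import (
    NO,
    YES,
    DecisionNode,
    DecisionTree,
    RoutingError,
    cbr_reference_tree,
    learn_tree,
    learn_tree_validated,
    pda_reference_tree,
    route,
    tree_predictions,
)


class TestStructure:
    def test_cbr_reference_shape(self):
        tree = cbr_reference_tree()
        assert len(tree) == 13
        assert len(tree.leaves()) == 7
        assert tree.root_id == 1
        assert tree.root.variable == "PTA_VS_SR8"
        assert tree.nodes[5].leaf_decision == YES

    def test_pda_reference_shape(self):
        tree = pda_reference_tree()
        assert len(tree) == 5
        assert {n.node_id: n.leaf_decision for n in tree.leaves()} == {3: YES, 4: NO, 5: YES}

    def test_node_must_be_leaf_xor_internal(self):
        with pytest.raises(ValueError):
            DecisionNode(1)
        with pytest.raises(ValueError):
            DecisionNode(1, "x", ">=", 0.0, true_child=2, false_child=3, leaf_decision=YES)

    def test_rejects_cycle_and_double_parent(self):
        with pytest.raises(ValueError):
            DecisionTree([
                DecisionNode(1, "x", ">=", 0, true_child=2, false_child=2),
                DecisionNode(2, leaf_decision=YES),
            ])

    def test_json_roundtrip(self):
        tree = cbr_reference_tree()
        back = DecisionTree.from_json(tree.to_json())
        assert back.to_json() == tree.to_json()
        assert back.root_id == tree.root_id

    def test_dot_rendering_mentions_every_node(self):
        dot = pda_reference_tree().to_dot()
        for nid in range(1, 6):
            assert f"{nid}: " in dot


class TestRouting:
    def test_missing_routes_to_na_side(self):
        tree = cbr_reference_tree()
        trace = route(tree, {"PTA_VS_SR8": None, "PTA_H_SR8": 0.0, "PTA_D_AR4": 0.0,
                             "SRT": 10.0, "Koos": 1})
        assert trace.path[:2] == (1, 3)  # N/A goes with the >= side

    def test_missing_without_route_errors(self):
        tree = cbr_reference_tree()
        with pytest.raises(RoutingError, match="PTA_H_SR8"):
            route(tree, {"PTA_VS_SR8": 5.0})  # node 3 has no N/A clause

    def test_inputs_used_subset_of_tree_variables(self):
        tree = cbr_reference_tree()
        trace = route(tree, {"PTA_VS_SR8": 1.0, "SRT": 40.0, "irrelevant": 1e9})
        assert trace.inputs_used <= tree.variables()
        assert "irrelevant" not in trace.inputs_used

    def test_only_path_variables_inspected(self):
        # a short route must not touch variables deeper in the other branch
        tree = cbr_reference_tree()
        trace = route(tree, {"PTA_VS_SR8": 0.0, "SRT": 50.0})
        assert trace.path == (1, 2, 5)
        assert trace.inputs_used == {"PTA_VS_SR8", "SRT"}

    def test_equality_comparator_is_exact(self):
        tree = cbr_reference_tree()
        base = {"PTA_VS_SR8": 8.0, "PTA_H_SR8": 0.0, "PTA_D_AR4": 30.0, "SRT": 50.0}
        yes = route(tree, {**base, "Koos": 2})
        no = route(tree, {**base, "Koos": 2.001})
        assert (yes.decision, no.decision) == (YES, NO)

    def test_every_leaf_reachable(self):
        cases = {
            # CBR tree: constructed inputs reaching each of the 7 leaves
            4: dict(PTA_VS_SR8=0, SRT=10, Koos=1),
            5: dict(PTA_VS_SR8=0, SRT=50, Koos=1),
            7: dict(PTA_VS_SR8=5, PTA_H_SR8=10, Koos=1),
            8: dict(PTA_VS_SR8=5, PTA_H_SR8=0, PTA_D_AR4=0, Koos=1),
            10: dict(PTA_VS_SR8=5, PTA_H_SR8=0, PTA_D_AR4=30, Koos=1),
            12: dict(PTA_VS_SR8=8, PTA_H_SR8=0, PTA_D_AR4=30, Koos=1),
            13: dict(PTA_VS_SR8=8, PTA_H_SR8=0, PTA_D_AR4=30, Koos=2),
        }
        tree = cbr_reference_tree()
        reached = set()
        for leaf, feats in cases.items():
            trace = route(tree, feats)
            assert trace.path[-1] == leaf
            reached.add(leaf)
        assert reached == {n.node_id for n in tree.leaves()}

        pda = pda_reference_tree()
        for leaf, feats in {3: dict(Koos_LD=1, Size_SC=0.0),
                            4: dict(Koos_LD=0, Size_SC=0.0),
                            5: dict(Koos_LD=0, Size_SC=0.01)}.items():
            assert route(pda, feats).path[-1] == leaf


class TestLearnTree:
    def test_perfect_1d_split(self):
        df = pd.DataFrame({"x": [-3.0, -2.0, -1.0, 1.0, 2.0, 3.0],
                           "y": [0, 0, 0, 1, 1, 1]})
        tree = learn_tree(df, "y", positive=1)
        assert len(tree) == 3
        assert tree.root.variable == "x"
        assert -1.0 < tree.root.threshold < 1.0

    @pytest.mark.parametrize("criterion", ["chi_square", "gini"])
    def test_planted_rule_recovery(self, criterion, rng):
        # Active iff Koos_LD >= 1 or Size_SC > g, effects far above noise
        n = 200
        koos_ld = rng.integers(0, 2, n).astype(float)
        size_sc = np.where(rng.random(n) < 0.3, rng.uniform(0.009, 0.03, n),
                           rng.normal(0, 0.001, n))
        y = ((koos_ld >= 1) | (size_sc > 0.0064)).astype(int)
        df = pd.DataFrame({"Koos_LD": koos_ld, "Size_SC": size_sc,
                           "noise": rng.normal(size=n), "y": y})
        tree = learn_tree(df, "y", criterion=criterion, max_depth=3, positive=1)
        assert tree.root.variable == "Koos_LD"
        preds = tree_predictions(tree, df, "y")
        assert all(p == (YES if t else NO) for p, t in zip(preds, y))

    def test_depth_bound(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50),
                           "y": rng.integers(0, 2, 50)})
        tree = learn_tree(df, "y", max_depth=1, positive=1)
        assert len(tree) <= 3

    def test_pure_node_becomes_leaf(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [1, 1, 1]})
        tree = learn_tree(df, "y", positive=1)
        assert len(tree) == 1
        assert tree.root.leaf_decision == YES

    def test_missing_values_follow_majority_branch(self):
        df = pd.DataFrame({
            "x": [0.0, 0.1, 0.2, 0.3, np.nan, 10.0, 10.1, 10.2],
            "y": [0, 0, 0, 0, 0, 1, 1, 1],
        })
        tree = learn_tree(df, "y", positive=1)
        assert tree.root.missing_to == "false"  # majority of non-missing rows sit below
        trace = route(tree, {"x": None})
        assert trace.decision == NO

    def test_oracle_equivalence_on_reference_labeled_grid(self):
        # labels generated BY the reference tree; the learner must recover a
        # tree with the identical decision function on that grid
        ref = pda_reference_tree()
        grid = pd.DataFrame(
            [(k, s) for k in np.arange(0.0, 2.5, 0.5) for s in np.arange(-0.01, 0.021, 0.001)],
            columns=["Koos_LD", "Size_SC"],
        )
        grid["y"] = tree_predictions(ref, grid)
        learned = learn_tree(grid, "y", positive=YES)
        assert tree_predictions(learned, grid, "y") == grid["y"].tolist()

    def test_validated_learner_picks_generalizing_depth(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = (x > 0).astype(int)
        df = pd.DataFrame({"x": x, "n1": rng.normal(size=n), "y": y})
        train, valid = df.iloc[:200], df.iloc[200:]
        tree = learn_tree_validated(train, valid, "y", depths=(1, 2, 3), positive=1)
        preds = tree_predictions(tree, valid, "y")
        want = [YES if v else NO for v in valid["y"]]
        assert np.mean([p == w for p, w in zip(preds, want)]) == 1.0
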