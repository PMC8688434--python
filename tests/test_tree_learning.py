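import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from grntopo.tree_learning import (
    ConsensusError,
    ConsensusModel,
    DecisionTree,
    Internal,
    Leaf,
    _gain_ratio,
    _partition,
    _pessimistic_errors,
    assign_to_leaves,
    build_consensus,
    classify_instances,
    compare_performance,
    cross_validate,
    extract_consensus_tree,
    group_assignments,
    induce_tree,
)

from conftest import make_table


# --- independent gain-ratio oracle -----------------------------------------

def oracle_entropy(labels) -> float:
    c = Counter(labels)
    n = len(labels)
    return -sum((v / n) * math.log2(v / n) for v in c.values())


def oracle_gain_ratio(values, labels) -> float:
    n = len(labels)
    groups = {}
    for v, y in zip(values, labels):
        groups.setdefault(v, []).append(y)
    gain = oracle_entropy(labels) - sum(
        len(g) / n * oracle_entropy(g) for g in groups.values()
    )
    split_info = -sum(
        (len(g) / n) * math.log2(len(g) / n) for g in groups.values()
    )
    return gain / split_info if split_info > 0 else 0.0


def forty_row_table() -> pd.DataFrame:
    """X predicts the class strongly (30/40 correct), Y weakly (24/40)."""
    rows = []
    for i in range(20):
        rows.append(("A" if i < 15 else "B", "A" if i < 12 else "B", "regulator"))
    for i in range(20):
        rows.append(("B" if i < 15 else "A", "B" if i < 12 else "A", "target"))
    return pd.DataFrame(rows, columns=["X", "Y", "class"])


def test_root_split_matches_hand_computed_gain_ratios():
    t = forty_row_table()
    y = t["class"].tolist()
    gr_x = oracle_gain_ratio(t["X"], y)
    gr_y = oracle_gain_ratio(t["Y"], y)
    assert gr_x > gr_y  # construction sanity
    tree = induce_tree(t, min_leaf=5, prune=False)
    assert isinstance(tree.root, Internal)
    assert tree.root.attribute == "X"


def test_gain_ratio_matches_oracle_on_random_partitions():
    rng = np.random.default_rng(8)
    for _ in range(50):
        n = int(rng.integers(6, 30))
        vals = rng.choice(list("ABC"), n)
        labels = rng.choice(["regulator", "target"], n)
        parts = _partition(vals, labels)
        gr, _ = _gain_ratio(labels, parts)
        assert gr == pytest.approx(oracle_gain_ratio(vals, labels), abs=1e-12)


def test_separable_table_training_cci_100(separable_table):
    tree = induce_tree(separable_table, min_leaf=20)
    preds = tree.predict(separable_table)
    assert (preds == separable_table["class"].to_numpy()).mean() == 1.0
    assert tree.n_leaves == 2


def test_uniform_features_give_single_majority_leaf():
    t = pd.DataFrame(
        {"X": ["C"] * 30, "class": ["regulator"] * 10 + ["target"] * 20}
    )
    tree = induce_tree(t, min_leaf=5)
    assert isinstance(tree.root, Leaf)
    assert tree.root.klass == "target"


def test_single_class_table_is_single_leaf():
    t = pd.DataFrame({"X": ["A", "B", "C"], "class": ["regulator"] * 3})
    tree = induce_tree(t, min_leaf=1)
    assert isinstance(tree.root, Leaf)


def test_empty_table_and_bad_min_leaf():
    with pytest.raises(ValueError):
        induce_tree(pd.DataFrame({"X": [], "class": []}))
    with pytest.raises(ValueError):
        induce_tree(pd.DataFrame({"X": ["A"], "class": ["t"]}), min_leaf=0)


def test_pruning_never_increases_pessimistic_error(noise_table):
    grown = induce_tree(noise_table, min_leaf=5, prune=False)
    pruned = induce_tree(noise_table, min_leaf=5, prune=True)
    assert _pessimistic_errors(pruned.root, 0.25) <= _pessimistic_errors(
        grown.root, 0.25
    ) + 1e-9


def test_unpruned_training_accuracy_at_least_pruned(noise_table):
    grown = induce_tree(noise_table, min_leaf=5, prune=False)
    pruned = induce_tree(noise_table, min_leaf=5, prune=True)
    y = noise_table["class"].to_numpy()
    acc_g = (grown.predict(noise_table) == y).mean()
    acc_p = (pruned.predict(noise_table) == y).mean()
    assert acc_g >= acc_p - 1e-12


def test_missing_values_route_to_majority_child(separable_table):
    tree = induce_tree(separable_table, min_leaf=20)
    probe = pd.DataFrame({"X": [math.nan], "Y": ["A"], "Z": ["A"], "class": ["regulator"]})
    leaf, _ = tree.route(probe.iloc[0])
    assert leaf.n > 0  # routed somewhere deterministic


def test_cross_validation_on_separable_data(separable_table):
    report = cross_validate(separable_table, folds=10, seed=0, min_leaf=10)
    assert report.cci == pytest.approx(100.0)
    assert report.mcc == pytest.approx(1.0)
    assert set(report.per_fold[0]) == {"CCI", "TPR", "1-FPR", "MCC", "ROC_area", "PRC_area"}


def test_cross_validation_stratification_error():
    t = make_table(6, "separable")
    with pytest.raises(ValueError, match="stratification"):
        cross_validate(t, folds=10, seed=0)


def test_consensus_of_single_tree_is_identity(separable_table):
    tree = induce_tree(separable_table, min_leaf=20)
    model = build_consensus([tree])
    assert np.allclose(
        model.predict_proba(separable_table), tree.predict_proba(separable_table)
    )


def test_consensus_probability_average_and_tie_rule():
    t_reg = pd.DataFrame({"X": ["A"] * 8 + ["B"] * 2, "class": ["regulator"] * 8 + ["target"] * 2})
    t_tar = pd.DataFrame({"X": ["A"] * 2 + ["B"] * 8, "class": ["regulator"] * 2 + ["target"] * 8})
    a = induce_tree(t_reg, min_leaf=10)  # single leaf, P(reg)=9/12
    b = induce_tree(t_tar, min_leaf=10)  # single leaf, P(reg)=3/12
    model = build_consensus([a, b])
    probe = pd.DataFrame({"X": ["A"], "class": ["target"]})
    probs = model.predict_proba(probe)
    assert probs[0] == pytest.approx([0.5, 0.5])
    assert model.predict(probe)[0] == "regulator"  # tie -> regulator
    assert probs.sum(axis=1) == pytest.approx(1.0)


def test_consensus_attribute_mismatch_rejected(separable_table):
    t2 = separable_table.rename(columns={"X": "W"})
    with pytest.raises(ValueError, match="attribute"):
        build_consensus([
            induce_tree(separable_table, min_leaf=20),
            induce_tree(t2, min_leaf=20),
        ])


def test_degenerate_all_regulator_predictor_scores_cci_50():
    leaf = Leaf(class_counts={"regulator": 99, "target": 1})
    tree = DecisionTree(root=leaf, attributes=("X",), min_leaf=1)
    test = pd.DataFrame(
        {"X": ["A"] * 20, "class": ["regulator"] * 10 + ["target"] * 10}
    )
    _, report = classify_instances(tree, test)
    assert report.cci == pytest.approx(50.0)
    assert report.mcc == pytest.approx(0.0)


def test_compare_performance_separated_groups():
    rep = compare_performance([0.9, 0.92, 0.88, 0.91], [0.5, 0.49, 0.52, 0.51])
    assert rep["p_value"] < 0.05
    assert rep["direction"] == "normal>random"
    assert rep["tests"] == ["shapiro-wilk", "mann-whitney-u"]


def test_compare_performance_identical_and_degenerate():
    rep = compare_performance([1, 2, 3, 4], [1, 2, 3, 4])
    assert rep["p_value"] > 0.5
    degenerate = compare_performance([1.0] * 4, [1.0] * 4)
    assert degenerate["p_value"] is None and "note" in degenerate


def test_consensus_tree_of_identical_trees(separable_table):
    tree = induce_tree(separable_table, min_leaf=20)
    consensus = extract_consensus_tree([tree] * 12, majority=0.5)
    assert consensus.n_leaves == tree.n_leaves
    assert isinstance(consensus.root, Internal)
    assert consensus.root.attribute == tree.root.attribute


def test_consensus_tree_modal_root_wins():
    ta = make_table(60, "separable", seed=1)
    tb = ta.rename(columns={"X": "Y", "Y": "X"})  # same signal under attribute Y
    tree_a = induce_tree(ta, min_leaf=10)
    tree_b = induce_tree(tb[["X", "Y", "Z", "class"]], min_leaf=10)
    trees = [tree_a] * 7 + [tree_b] * 5
    consensus = extract_consensus_tree(trees, majority=0.5)
    assert consensus.root.attribute == "X"
    with pytest.raises(ConsensusError):
        extract_consensus_tree([tree_a] * 5 + [tree_b] * 5, majority=0.9)


def test_assignments_partition_all_instances(separable_table):
    tree = induce_tree(separable_table, min_leaf=20)
    consensus = extract_consensus_tree([tree, tree], majority=0.5)
    assignments = assign_to_leaves(consensus, separable_table)
    assert len(assignments) == len(separable_table)
    assert {a.gene_id for a in assignments} == set(map(str, separable_table.index))
    groups = group_assignments(assignments)
    assert sum(len(v) for v in groups.values()) == len(separable_table)
    # the leading feature of every leaf here is the root attribute X
    assert all(a.leading_feature == "X" for a in assignments)


def test_tree_json_round_trip(separable_table):
    tree = induce_tree(separable_table, min_leaf=20)
    back = DecisionTree.from_dict(tree.to_dict())
    assert np.array_equal(back.predict(separable_table), tree.predict(separable_table))
    model = build_consensus([tree, back])
    model2 = ConsensusModel.from_dict(model.to_dict())
    assert np.allclose(
        model2.predict_proba(separable_table), model.predict_proba(separable_table)
    )
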