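import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from grntopo.feature_selection import (
    cfs_merit,
    entropy,
    exhaustive_cfs_subset,
    precompute_correlations,
    rank_information_gain,
    select_cfs_subset,
    symmetrical_uncertainty,
)


def h(values) -> float:
    """Independent entropy oracle (plain counting, no shared code path)."""
    counts = Counter(values)
    n = len(values)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def test_su_identity_is_one():
    a = ["A", "B", "A", "B", "A", "B"]
    assert symmetrical_uncertainty(a, list(a)) == pytest.approx(1.0)


def test_su_independent_product_table_is_zero():
    # every (a,b) combination equally often -> exact independence
    a = ["A", "A", "B", "B"] * 3
    b = ["X", "Y", "X", "Y"] * 3
    assert symmetrical_uncertainty(a, b) == pytest.approx(0.0, abs=1e-12)


def test_su_one_flipped_row_of_eight_matches_hand_entropies():
    a = ["r", "r", "r", "r", "t", "t", "t", "t"]
    b = ["r", "r", "r", "r", "t", "t", "t", "r"]  # last row flipped
    # oracle: H(a)=1; H(b)=h(b); H(a,b) by joint counting
    joint = [f"{x}|{y}" for x, y in zip(a, b)]
    mi = h(a) + h(b) - h(joint)
    expected = 2 * mi / (h(a) + h(b))
    assert symmetrical_uncertainty(a, b) == pytest.approx(expected, abs=1e-12)


def test_su_zero_entropy_and_length_mismatch():
    assert symmetrical_uncertainty(["A"] * 4, ["X", "Y", "X", "Y"]) == 0.0
    with pytest.raises(ValueError):
        symmetrical_uncertainty(["A"], ["A", "B"])


def test_missing_is_its_own_category():
    a = ["A", math.nan, "A", math.nan]
    assert entropy(a) == pytest.approx(1.0)  # two equally likely categories


def test_info_gain_perfect_attribute_tops_ranking():
    t = pd.DataFrame(
        {
            "perfect": ["A"] * 50 + ["B"] * 50,
            "noise": ["A", "B"] * 50,
            "class": ["regulator"] * 50 + ["target"] * 50,
        }
    )
    scores = rank_information_gain(t)
    assert scores[0].attribute == "perfect"
    assert scores[0].info_gain == pytest.approx(1.0)  # H(class) on balanced table
    assert [s.rank for s in scores] == [1, 2]


def test_info_gain_of_random_attribute_is_tiny():
    rng = np.random.default_rng(0)
    n = 10_000
    t = pd.DataFrame(
        {
            "rand": rng.choice(list("ABCDEF"), n),
            "class": rng.choice(["regulator", "target"], n),
        }
    )
    assert rank_information_gain(t)[0].info_gain < 0.01


def test_info_gain_invariant_to_value_renaming():
    t = pd.DataFrame(
        {
            "x": ["A", "A", "B", "B", "C", "C"],
            "class": ["regulator", "regulator", "target", "target", "regulator", "target"],
        }
    )
    renamed = t.assign(x=t["x"].map({"A": "Q", "B": "R", "C": "S"}))
    g1 = rank_information_gain(t)[0].info_gain
    g2 = rank_information_gain(renamed)[0].info_gain
    assert g1 == pytest.approx(g2)
    assert g1 >= 0


def test_cfs_selects_single_perfect_attribute():
    rng = np.random.default_rng(1)
    n = 200
    cls = ["regulator", "target"] * (n // 2)
    t = pd.DataFrame({"class": cls})
    t.insert(0, "signal", ["A" if c == "regulator" else "D" for c in cls])
    for i in range(5):
        t[f"noise{i}"] = rng.choice(list("ABCDEF"), n)
    sel = select_cfs_subset(t)
    assert sel.selected == frozenset({"signal"})


def test_cfs_rejects_duplicated_informative_attribute():
    rng = np.random.default_rng(2)
    n = 300
    cls = rng.choice(["regulator", "target"], n)
    informative = np.where(
        rng.random(n) < 0.85, np.where(cls == "regulator", "A", "D"), "C"
    )
    t = pd.DataFrame(
        {
            "inf1": informative,
            "inf2": informative.copy(),  # exact duplicate
            "noise": rng.choice(list("ABCDEF"), n),
            "class": cls,
        }
    )
    sel = select_cfs_subset(t)
    oracle = exhaustive_cfs_subset(t)
    assert sel.selected == oracle.selected
    assert len(sel.selected & {"inf1", "inf2"}) == 1


def test_merit_of_singleton_is_class_correlation():
    t = pd.DataFrame(
        {
            "x": ["A", "B", "A", "B"],
            "y": ["A", "A", "B", "B"],
            "class": ["regulator", "target", "regulator", "target"],
        }
    )
    class_su, pair_su = precompute_correlations(t)
    assert cfs_merit({"x"}, class_su, pair_su) == pytest.approx(class_su["x"])


def test_best_first_matches_exhaustive_on_random_tables():
    rng = np.random.default_rng(99)
    agree = 0
    n_tables = 30
    for _ in range(n_tables):
        n = 60
        n_attr = int(rng.integers(3, 8))
        cls = rng.choice(["regulator", "target"], n)
        t = pd.DataFrame({"class": cls})
        for i in range(n_attr):
            if rng.random() < 0.5:  # weakly informative
                t[f"a{i}"] = np.where(
                    rng.random(n) < 0.6, np.where(cls == "regulator", "A", "B"),
                    rng.choice(list("ABC"), n),
                )
            else:
                t[f"a{i}"] = rng.choice(list("ABC"), n)
        bf = select_cfs_subset(t)
        ex = exhaustive_cfs_subset(t)
        if abs(bf.merit - ex.merit) < 1e-9:
            agree += 1
    assert agree / n_tables >= 0.95


def test_trace_merit_bound():
    t = pd.DataFrame(
        {
            "x": ["A", "B"] * 20,
            "y": ["A", "A", "B", "B"] * 10,
            "class": ["regulator", "target"] * 20,
        }
    )
    sel = select_cfs_subset(t)
    assert all(sel.merit >= m - 1e-12 for _, m in sel.trace)
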