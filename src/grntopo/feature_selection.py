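"""Information-gain ranking and correlation-based feature selection (CFS).

Both selectors work on the discretized instance table.  Information gain
I(attribute; class) ranks attributes individually; CFS searches for a subset
that is highly correlated with the class but weakly intercorrelated, scoring a
size-k subset S by the merit

    M_S = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

where r̄_cf is the mean attribute–class symmetrical uncertainty over S and
r̄_ff the mean pairwise attribute–attribute one.  The search is forward
best-first hill climbing with backtracking, stopping after a fixed number of
consecutive non-improving expansions.  Missing cells are treated as their own
category throughout, matching how the learner consumes them.
"""

from __future__ import annotations

import heapq
import math
from collections import Counter
from dataclasses import dataclass
from itertools import count

import numpy as np
import pandas as pd

from .dataset_builder import CLASS_COLUMN

_MISSING = "<missing>"


def _as_categories(col: pd.Series, missing: str = "category") -> np.ndarray:
    vals = col.to_numpy(dtype=object)
    out = np.array(
        [_MISSING if (v is None or (isinstance(v, float) and math.isnan(v))) else v for v in vals],
        dtype=object,
    )
    return out


def entropy(column, missing: str = "category") -> float:
    """Shannon entropy in bits of a categorical column.

    ``missing="category"`` treats NaN as its own value; ``missing="drop"``
    discards missing entries first.
    """
    vals = _as_categories(pd.Series(column))
    if missing == "drop":
        vals = vals[vals != _MISSING]
    n = len(vals)
    if n == 0:
        return 0.0
    counts = np.array(list(Counter(vals.tolist()).values()), dtype=float)
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def mutual_information(a, b, missing: str = "category") -> float:
    """I(a;b) in bits: H(a) + H(b) − H(a,b)."""
    av = _as_categories(pd.Series(a))
    bv = _as_categories(pd.Series(b))
    if len(av) != len(bv):
        raise ValueError(f"column length mismatch: {len(av)} vs {len(bv)}")
    if missing == "drop":
        keep = (av != _MISSING) & (bv != _MISSING)
        av, bv = av[keep], bv[keep]
    joint = np.array([f"{x}\x00{y}" for x, y in zip(av, bv)], dtype=object)
    return max(0.0, entropy(av) + entropy(bv) - entropy(joint))


def symmetrical_uncertainty(a, b, missing: str = "category") -> float:
    """SU(a,b) = 2·I(a;b) / (H(a)+H(b)) ∈ [0,1]; 0 when either entropy is 0."""
    av = _as_categories(pd.Series(a))
    bv = _as_categories(pd.Series(b))
    if len(av) != len(bv):
        raise ValueError(f"column length mismatch: {len(av)} vs {len(bv)}")
    if missing == "drop":
        keep = (av != _MISSING) & (bv != _MISSING)
        av, bv = av[keep], bv[keep]
    ha, hb = entropy(av), entropy(bv)
    if ha == 0.0 or hb == 0.0:
        return 0.0
    return min(1.0, 2.0 * mutual_information(av, bv) / (ha + hb))


@dataclass(frozen=True)
class AttributeScore:
    attribute: str
    info_gain: float
    rank: int


@dataclass
class SubsetSelection:
    selected: frozenset[str]
    merit: float
    trace: list[tuple[frozenset[str], float]]

    def to_dict(self) -> dict:
        return {
            "selected": sorted(self.selected),
            "merit": self.merit,
            "trace": [[sorted(s), m] for s, m in self.trace],
        }


def _attribute_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != CLASS_COLUMN]


def rank_information_gain(table: pd.DataFrame) -> list[AttributeScore]:
    """Attributes sorted by decreasing I(attribute; class), ties lexicographic."""
    attrs = _attribute_columns(table)
    if not attrs:
        raise ValueError("table has no attribute columns")
    cls = table[CLASS_COLUMN]
    gains = {a: mutual_information(table[a], cls) for a in attrs}
    ordered = sorted(attrs, key=lambda a: (-gains[a], a))
    return [AttributeScore(a, gains[a], i + 1) for i, a in enumerate(ordered)]


def cfs_merit(
    subset: frozenset[str] | set[str],
    class_su: dict[str, float],
    pair_su: dict[frozenset[str], float],
) -> float:
    """CFS merit of a subset given precomputed SU correlations."""
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = sum(class_su[a] for a in subset) / k
    if k == 1:
        return r_cf
    pairs = [pair_su[frozenset((a, b))] for a in subset for b in subset if a < b]
    r_ff = sum(pairs) / len(pairs)
    denom = math.sqrt(k + k * (k - 1) * r_ff)
    return k * r_cf / denom if denom > 0 else 0.0


def precompute_correlations(
    table: pd.DataFrame, attrs: list[str] | None = None
) -> tuple[dict[str, float], dict[frozenset[str], float]]:
    attrs = attrs if attrs is not None else _attribute_columns(table)
    cls = table[CLASS_COLUMN]
    class_su = {a: symmetrical_uncertainty(table[a], cls) for a in attrs}
    pair_su: dict[frozenset[str], float] = {}
    for i, a in enumerate(attrs):
        for b in attrs[i + 1 :]:
            pair_su[frozenset((a, b))] = symmetrical_uncertainty(table[a], table[b])
    return class_su, pair_su


def select_cfs_subset(table: pd.DataFrame, max_stale: int = 5) -> SubsetSelection:
    """Forward best-first CFS subset search with a stale-expansion cutoff.

    Expands the open subset of highest merit, adding one attribute at a time;
    backtracking falls out of the priority queue.  Stops after ``max_stale``
    consecutive expansions that fail to improve on the best merit seen.
    Attributes whose cells are all missing carry zero correlation and are
    effectively never selected.
    """
    attrs = _attribute_columns(table)
    if len(attrs) < 2:
        raise ValueError("CFS needs at least 2 attributes")
    class_su, pair_su = precompute_correlations(table, attrs)

    start: frozenset[str] = frozenset()
    best_subset, best_merit = start, 0.0
    trace: list[tuple[frozenset[str], float]] = []
    tick = count()
    heap: list[tuple[float, int, frozenset[str]]] = [(0.0, next(tick), start)]
    visited: set[frozenset[str]] = {start}
    stale = 0
    while heap and stale < max_stale:
        neg_merit, _, subset = heapq.heappop(heap)
        improved = False
        for a in attrs:
            if a in subset:
                continue
            child = subset | {a}
            if child in visited:
                continue
            visited.add(child)
            merit = cfs_merit(child, class_su, pair_su)
            trace.append((child, merit))
            heapq.heappush(heap, (-merit, next(tick), child))
            if merit > best_merit + 1e-12:
                best_subset, best_merit = child, merit
                improved = True
        stale = 0 if improved else stale + 1
    return SubsetSelection(selected=best_subset, merit=best_merit, trace=trace)


def exhaustive_cfs_subset(table: pd.DataFrame) -> SubsetSelection:
    """Exact merit maximization by enumerating all non-empty subsets.

    Exponential in the attribute count; intended as an oracle for small
    tables (≤ ~15 attributes).
    """
    from itertools import combinations

    attrs = _attribute_columns(table)
    class_su, pair_su = precompute_correlations(table, attrs)
    best: frozenset[str] = frozenset()
    best_merit = 0.0
    for k in range(1, len(attrs) + 1):
        for combo in combinations(attrs, k):
            s = frozenset(combo)
            m = cfs_merit(s, class_su, pair_su)
            if m > best_merit + 1e-12:
                best, best_merit = s, m
    return SubsetSelection(selected=best, merit=best_merit, trace=[])
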