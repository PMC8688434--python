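"""Gain-ratio decision trees, probability-averaging consensus, and scoring.

Trees are induced C4.5-style on the categorical (binned) attributes: each
internal node splits multiway on the attribute maximizing the gain ratio
(information gain divided by the split information), subject to a minimum
leaf size (default 20 instances, the classical "20 objects per leaf"
setting), followed by pessimistic-error subtree-replacement pruning at
confidence 0.25.  Missing values are routed down the majority child — a
deterministic simplification of C4.5's fractional instances, defensible here
because missing cells are rare after discretization.

Member trees trained on the balanced sets are combined into a consensus model
that averages their Laplace-smoothed leaf class probabilities (ties resolved
to "regulator").  Performance is reported as CCI (% correctly classified
instances), TPR, 1−FPR, MCC, ROC area and PRC area.  A majority-rule merged
consensus tree summarizes the ensemble's rules, and instances can be routed
to its leaves grouped by the attribute that leads to each leaf.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import matthews_corrcoef, precision_recall_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dataset_builder import CLASS_COLUMN
from .feature_selection import entropy
from .grn_io import ROLE_REGULATOR, ROLE_TARGET

CLASSES = (ROLE_REGULATOR, ROLE_TARGET)
_MISSING = "<missing>"


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class Leaf:
    class_counts: dict[str, int]
    leading: str | None = None  # attribute tested at the parent (consensus trees)
    leaf_id: int = -1

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())

    @property
    def klass(self) -> str:
        # majority class; ties resolve to the first entry of CLASSES (regulator)
        return max(CLASSES, key=lambda c: (self.class_counts.get(c, 0), c == CLASSES[0]))

    def proba(self) -> dict[str, float]:
        """Laplace-smoothed class probabilities."""
        n = self.n
        return {
            c: (self.class_counts.get(c, 0) + 1) / (n + len(CLASSES)) for c in CLASSES
        }

    def to_dict(self) -> dict:
        return {"leaf": True, "counts": dict(self.class_counts), "leading": self.leading}


@dataclass
class Internal:
    attribute: str
    children: dict[str, "Leaf | Internal"]
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def majority_value(self) -> str:
        """Child key holding the most training instances (missing-value route)."""
        return max(
            self.children, key=lambda v: (_subtree_n(self.children[v]), str(v))
        )

    def to_dict(self) -> dict:
        return {
            "leaf": False,
            "attribute": self.attribute,
            "counts": dict(self.class_counts),
            "children": {str(v): c.to_dict() for v, c in self.children.items()},
        }


Node = Leaf | Internal


def _subtree_n(node: Node) -> int:
    if isinstance(node, Leaf):
        return node.n
    return sum(_subtree_n(c) for c in node.children.values())


def _subtree_counts(node: Node) -> Counter:
    if isinstance(node, Leaf):
        return Counter(node.class_counts)
    total: Counter = Counter()
    for c in node.children.values():
        total += _subtree_counts(c)
    return total


def _node_from_dict(d: dict) -> Node:
    if d["leaf"]:
        return Leaf(class_counts=dict(d["counts"]), leading=d.get("leading"))
    return Internal(
        attribute=d["attribute"],
        children={v: _node_from_dict(c) for v, c in d["children"].items()},
        class_counts=dict(d.get("counts", {})),
    )


@dataclass
class DecisionTree:
    """A fitted gain-ratio tree over a fixed set of categorical attributes."""

    root: Node
    attributes: tuple[str, ...]
    min_leaf: int = 20

    def __post_init__(self) -> None:
        self._number_leaves()

    def _number_leaves(self) -> None:
        i = 0

        def walk(node: Node) -> None:
            nonlocal i
            if isinstance(node, Leaf):
                node.leaf_id = i
                i += 1
            else:
                for v in sorted(node.children, key=str):
                    walk(node.children[v])

        walk(self.root)
        self._n_leaves = i

    @property
    def n_leaves(self) -> int:
        return self._n_leaves

    def route(self, row) -> tuple[Leaf, str | None]:
        """Leaf reached by an instance and the attribute tested at its parent."""
        node = self.root
        leading: str | None = None
        while isinstance(node, Internal):
            leading = node.attribute
            v = row.get(node.attribute) if hasattr(row, "get") else row[node.attribute]
            key = _MISSING if _is_missing(v) else str(v)
            node = node.children.get(key, node.children[node.majority_value])
        return node, leading

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        probs = np.empty((len(table), len(CLASSES)))
        for i, (_, row) in enumerate(table.iterrows()):
            leaf, _ = self.route(row)
            p = leaf.proba()
            probs[i] = [p[c] for c in CLASSES]
        return probs

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return _argmax_classes(self.predict_proba(table))

    def to_dict(self) -> dict:
        return {
            "attributes": list(self.attributes),
            "min_leaf": self.min_leaf,
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        return cls(
            root=_node_from_dict(d["root"]),
            attributes=tuple(d["attributes"]),
            min_leaf=d.get("min_leaf", 20),
        )

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: Node, indent: str) -> None:
            if isinstance(node, Leaf):
                lines.append(f"{indent}-> {node.klass} {dict(node.class_counts)}")
            else:
                for v in sorted(node.children, key=str):
                    lines.append(f"{indent}{node.attribute} = {v}")
                    walk(node.children[v], indent + "    ")

        walk(self.root, "")
        return "\n".join(lines)


def _argmax_classes(probs: np.ndarray) -> np.ndarray:
    # tie -> regulator, which CLASSES order plus argmax's first-max rule gives
    return np.array([CLASSES[i] for i in np.argmax(probs, axis=1)], dtype=object)


# ---------------------------------------------------------------------------
# induction


def _partition(values: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """Group row indices by attribute value; missing rows join the largest group."""
    groups: dict[str, list[int]] = {}
    missing_rows: list[int] = []
    for i, v in enumerate(values):
        if _is_missing(v):
            missing_rows.append(i)
        else:
            groups.setdefault(str(v), []).append(i)
    if not groups:
        return {}
    if missing_rows:
        biggest = max(groups, key=lambda k: (len(groups[k]), k))
        groups[biggest].extend(missing_rows)
    return {k: np.array(ix) for k, ix in groups.items()}


def _gain_ratio(y: np.ndarray, parts: dict[str, np.ndarray]) -> tuple[float, float]:
    """(gain ratio, information gain) of a candidate partition of labels y."""
    n = len(y)
    h_parent = entropy(pd.Series(y))
    h_children = 0.0
    split_fracs = []
    for ix in parts.values():
        frac = len(ix) / n
        split_fracs.append(frac)
        h_children += frac * entropy(pd.Series(y[ix]))
    gain = h_parent - h_children
    split_info = -sum(f * math.log2(f) for f in split_fracs if f > 0)
    if split_info <= 0:
        return 0.0, gain
    return gain / split_info, gain


def _added_errors(n: float, e: float, cf: float = 0.25) -> float:
    """C4.5's pessimistic extra-error estimate for a leaf with n cases, e errors."""
    if n <= 0:
        return 0.0
    if e == 0:
        return n * (1.0 - cf ** (1.0 / n))
    if e < 1:
        base = n * (1.0 - cf ** (1.0 / n))
        return base + e * (_added_errors(n, 1.0, cf) - base)
    if e + 0.5 >= n:
        return max(n - e, 0.0)
    z = float(sstats.norm.ppf(1.0 - cf))
    f = (e + 0.5) / n
    ub = (f + z * z / (2 * n) + z * math.sqrt(f / n - f * f / n + z * z / (4 * n * n))) / (
        1 + z * z / n
    )
    return ub * n - e


def _pessimistic_errors(node: Node, cf: float) -> float:
    if isinstance(node, Leaf):
        n = node.n
        e = n - node.class_counts.get(node.klass, 0)
        return e + _added_errors(n, e, cf)
    return sum(_pessimistic_errors(c, cf) for c in node.children.values())


def _prune(node: Node, cf: float) -> Node:
    """Bottom-up subtree replacement when a collapsed leaf is no worse."""
    if isinstance(node, Leaf):
        return node
    node.children = {v: _prune(c, cf) for v, c in node.children.items()}
    counts = _subtree_counts(node)
    as_leaf = Leaf(class_counts=dict(counts))
    n = as_leaf.n
    e = n - counts.get(as_leaf.klass, 0)
    leaf_err = e + _added_errors(n, e, cf)
    subtree_err = _pessimistic_errors(node, cf)
    if leaf_err <= subtree_err + 0.1:
        return as_leaf
    return node


def induce_tree(
    table: pd.DataFrame,
    min_leaf: int = 20,
    *,
    prune: bool = True,
    confidence: float = 0.25,
) -> DecisionTree:
    """Grow (and by default prune) a gain-ratio tree on a discretized table.

    Splits are multiway over observed bin values; a split is admissible only
    when every resulting child holds at least ``min_leaf`` instances and its
    information gain is positive.  A single-class table yields a single leaf.
    """
    if len(table) == 0:
        raise ValueError("cannot induce a tree on an empty table")
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    attrs = tuple(c for c in table.columns if c != CLASS_COLUMN)
    y = table[CLASS_COLUMN].to_numpy(dtype=object)
    cols = {a: table[a].to_numpy(dtype=object) for a in attrs}

    def grow(rows: np.ndarray, remaining: tuple[str, ...]) -> Node:
        labels = y[rows]
        counts = dict(Counter(labels.tolist()))
        if len(counts) == 1 or not remaining:
            return Leaf(class_counts=counts)
        best: tuple[float, float, str, dict[str, np.ndarray]] | None = None
        for a in remaining:
            parts = _partition(cols[a][rows], labels)
            if len(parts) < 2:
                continue
            # classical C4.5/J48 admissibility: at least two branches must
            # hold min_leaf instances (smaller side-branches are allowed)
            if sum(len(ix) >= min_leaf for ix in parts.values()) < 2:
                continue
            gr, gain = _gain_ratio(labels, parts)
            if gain <= 1e-12:
                continue
            # deterministic tie-break: higher gain ratio, then name
            if best is None or (gr, a) > (best[0], best[2]):
                best = (gr, gain, a, parts)
        if best is None:
            return Leaf(class_counts=counts)
        _, _, attr, parts = best
        rest = tuple(a for a in remaining if a != attr)
        children = {
            v: grow(rows[ix], rest) for v, ix in sorted(parts.items())
        }
        return Internal(attribute=attr, children=children, class_counts=counts)

    root = grow(np.arange(len(table)), attrs)
    if prune:
        root = _prune(root, confidence)
    return DecisionTree(root=root, attributes=attrs, min_leaf=min_leaf)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class PerformanceReport:
    """CCI (%) plus the rate/area metrics of a binary regulator-vs-target run."""

    cci: float
    tpr: float
    one_minus_fpr: float
    mcc: float
    roc_area: float
    prc_area: float
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "CCI": self.cci,
            "TPR": self.tpr,
            "1-FPR": self.one_minus_fpr,
            "MCC": self.mcc,
            "ROC_area": self.roc_area,
            "PRC_area": self.prc_area,
        }
        if self.per_fold:
            d["per_fold"] = self.per_fold
        return d


def score_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], scores: Sequence[float]
) -> dict[str, float]:
    """Metric dict for one evaluation; ``scores`` is P(regulator) per instance."""
    yt = np.asarray(y_true, dtype=object)
    yp = np.asarray(y_pred, dtype=object)
    pos = yt == ROLE_REGULATOR
    tp = int(np.sum(pos & (yp == ROLE_REGULATOR)))
    fn = int(np.sum(pos & (yp == ROLE_TARGET)))
    tn = int(np.sum(~pos & (yp == ROLE_TARGET)))
    fp = int(np.sum(~pos & (yp == ROLE_REGULATOR)))
    cci = 100.0 * (tp + tn) / len(yt)
    tpr = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    mcc = matthews_corrcoef(yt.astype(str), yp.astype(str)) if len(set(yt)) > 0 else math.nan
    s = np.asarray(scores, dtype=float)
    if len(set(yt.tolist())) == 2:
        roc = float(roc_auc_score(pos.astype(int), s))
        prec, rec, _ = precision_recall_curve(pos.astype(int), s)
        order = np.argsort(rec)
        prc = float(np.trapezoid(prec[order], rec[order]))
    else:
        roc = math.nan
        prc = math.nan
    return {
        "CCI": cci,
        "TPR": tpr,
        "1-FPR": spec,
        "MCC": float(mcc),
        "ROC_area": roc,
        "PRC_area": prc,
    }


def _mean_report(fold_metrics: list[dict]) -> PerformanceReport:
    def m(key: str) -> float:
        return float(np.nanmean([f[key] for f in fold_metrics]))

    return PerformanceReport(
        cci=m("CCI"),
        tpr=m("TPR"),
        one_minus_fpr=m("1-FPR"),
        mcc=m("MCC"),
        roc_area=m("ROC_area"),
        prc_area=m("PRC_area"),
        per_fold=fold_metrics,
    )


def cross_validate(
    table: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    *,
    min_leaf: int = 20,
    prune: bool = True,
) -> PerformanceReport:
    """Stratified k-fold cross-validation, a fresh tree per fold."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(table) < folds:
        raise ValueError("fewer rows than folds")
    y = table[CLASS_COLUMN].to_numpy(dtype=object)
    class_counts = Counter(y.tolist())
    if min(class_counts.values()) < folds:
        raise ValueError(
            f"stratification impossible: a class has fewer members "
            f"({min(class_counts.values())}) than folds ({folds})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics = []
    for train_ix, test_ix in skf.split(np.zeros(len(table)), y.astype(str)):
        tree = induce_tree(table.iloc[train_ix], min_leaf=min_leaf, prune=prune)
        test = table.iloc[test_ix]
        probs = tree.predict_proba(test)
        preds = _argmax_classes(probs)
        fold_metrics.append(
            score_predictions(test[CLASS_COLUMN], preds, probs[:, 0])
        )
    return _mean_report(fold_metrics)


# ---------------------------------------------------------------------------
# consensus model


@dataclass
class ConsensusModel:
    """Probability-averaging ensemble of member trees on one attribute set."""

    trees: list[DecisionTree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("consensus needs at least one member tree")
        first = set(self.trees[0].attributes)
        for t in self.trees[1:]:
            if set(t.attributes) != first:
                raise ValueError(
                    "member trees were trained on different attribute sets"
                )

    @property
    def attributes(self) -> tuple[str, ...]:
        return self.trees[0].attributes

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        acc = np.zeros((len(table), len(CLASSES)))
        for t in self.trees:
            acc += t.predict_proba(table)
        return acc / len(self.trees)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return _argmax_classes(self.predict_proba(table))

    def to_dict(self) -> dict:
        return {"combination": "average", "trees": [t.to_dict() for t in self.trees]}

    @classmethod
    def from_dict(cls, d: dict) -> "ConsensusModel":
        return cls(trees=[DecisionTree.from_dict(t) for t in d["trees"]])


def build_consensus(trees: Sequence[DecisionTree]) -> ConsensusModel:
    """Average-of-probabilities ensemble (argmax prediction, ties → regulator)."""
    return ConsensusModel(trees=list(trees))


def classify_instances(
    model: ConsensusModel | DecisionTree, test: pd.DataFrame
) -> tuple[pd.DataFrame, PerformanceReport]:
    """Score a held-out discretized table against its retained true labels."""
    probs = model.predict_proba(test)
    preds = _argmax_classes(probs)
    out = pd.DataFrame(
        {
            "prob_regulator": probs[:, 0],
            "prob_target": probs[:, 1],
            "predicted": preds,
            "actual": test[CLASS_COLUMN].to_numpy(dtype=object),
        },
        index=test.index,
    )
    m = score_predictions(out["actual"], preds, probs[:, 0])
    report = PerformanceReport(
        cci=m["CCI"],
        tpr=m["TPR"],
        one_minus_fpr=m["1-FPR"],
        mcc=m["MCC"],
        roc_area=m["ROC_area"],
        prc_area=m["PRC_area"],
    )
    return out, report


# ---------------------------------------------------------------------------
# normal-vs-random comparison


def compare_performance(
    normal: Sequence[float], random: Sequence[float]
) -> dict:
    """Shapiro–Wilk normality per group, then a two-sided Mann–Whitney U test.

    Returns a dict with both test names, their statistics and p-values, and
    the effect direction.  Degenerate (constant, identical) inputs yield
    ``p_value=None`` with an explanatory note.
    """
    a = np.asarray(normal, dtype=float)
    b = np.asarray(random, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 scores per group")

    def shapiro_p(x: np.ndarray) -> float | None:
        if np.ptp(x) == 0:
            return None
        return float(sstats.shapiro(x).pvalue)

    report: dict = {
        "tests": ["shapiro-wilk", "mann-whitney-u"],
        "shapiro_normal_p": shapiro_p(a),
        "shapiro_random_p": shapiro_p(b),
        "mean_normal": float(a.mean()),
        "mean_random": float(b.mean()),
        "direction": "normal>random"
        if a.mean() > b.mean()
        else ("normal<random" if a.mean() < b.mean() else "equal"),
    }
    if np.ptp(np.concatenate([a, b])) == 0:
        report["u_statistic"] = None
        report["p_value"] = None
        report["note"] = "identical constant groups: U test undefined"
        return report
    u = sstats.mannwhitneyu(a, b, alternative="two-sided")
    report["u_statistic"] = float(u.statistic)
    report["p_value"] = float(u.pvalue)
    return report


# ---------------------------------------------------------------------------
# consensus rule tree & leaf assignment


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusTree:
    """Majority-rule merge of the member trees' split structure."""

    root: Node
    majority: float
    n_members: int

    def __post_init__(self) -> None:
        # reuse DecisionTree numbering/routing machinery
        self._tree = DecisionTree(root=self.root, attributes=(), min_leaf=1)

    @property
    def n_leaves(self) -> int:
        return self._tree.n_leaves

    def route(self, row) -> tuple[Leaf, str | None]:
        return self._tree.route(row)

    def to_dict(self) -> dict:
        return {
            "majority": self.majority,
            "n_members": self.n_members,
            "root": self.root.to_dict(),
        }

    def to_text(self) -> str:
        return self._tree.to_text()


def _resolve(node: Node, context: dict[str, str]) -> Node:
    while isinstance(node, Internal) and node.attribute in context:
        node = node.children.get(
            context[node.attribute], node.children[node.majority_value]
        )
    return node


def extract_consensus_tree(
    trees: Sequence[DecisionTree], majority: float = 0.5
) -> ConsensusTree:
    """Merge member trees keeping splits shared by ≥ ``majority`` of them.

    At each context (a partial assignment of attribute values), member trees
    vote with the attribute they test there; the modal attribute wins when it
    reaches the majority fraction, otherwise the node collapses to a leaf
    whose class is the modal member vote.  Each path tests an attribute at
    most once.  Raises :class:`ConsensusError` when not even the root reaches
    a majority.
    """
    if len(trees) < 2:
        raise ValueError("consensus tree extraction needs at least 2 trees")
    n = len(trees)
    roots = [t.root for t in trees]

    def merge(context: dict[str, str], leading: str | None) -> Node:
        resolved = [_resolve(r, context) for r in roots]
        votes = Counter(
            node.attribute for node in resolved if isinstance(node, Internal)
        )
        counts: Counter = Counter()
        for node in resolved:
            counts += _subtree_counts(node)
        if votes:
            modal_attr, modal_n = sorted(
                votes.items(), key=lambda kv: (-kv[1], kv[0])
            )[0]
            if modal_n / n >= majority:
                values: set[str] = set()
                for node in resolved:
                    if isinstance(node, Internal) and node.attribute == modal_attr:
                        values.update(node.children.keys())
                children = {
                    v: merge({**context, modal_attr: v}, modal_attr)
                    for v in sorted(values)
                }
                return Internal(
                    attribute=modal_attr, children=children, class_counts=dict(counts)
                )
            if not context:
                raise ConsensusError(
                    f"no attribute reaches the {majority:.0%} majority at the root "
                    f"(best: {modal_attr} in {modal_n}/{n} trees); lower the threshold"
                )
        return Leaf(class_counts=dict(counts), leading=leading)

    root = merge({}, None)
    return ConsensusTree(root=root, majority=majority, n_members=n)


@dataclass(frozen=True)
class LeafAssignment:
    gene_id: str
    leaf_id: int
    klass: str
    leading_feature: str | None


def assign_to_leaves(
    tree: ConsensusTree | DecisionTree, table: pd.DataFrame
) -> list[LeafAssignment]:
    """Route every instance to exactly one leaf of the (consensus) tree."""
    out = []
    for gene, row in table.iterrows():
        leaf, leading = tree.route(row)
        out.append(
            LeafAssignment(
                gene_id=str(gene),
                leaf_id=leaf.leaf_id,
                klass=leaf.klass,
                leading_feature=leaf.leading if getattr(leaf, "leading", None) else leading,
            )
        )
    return out


def group_assignments(
    assignments: Sequence[LeafAssignment],
) -> dict[tuple[str, str], list[str]]:
    """Group genes by (leading feature, leaf class) — the leaf-report columns."""
    groups: dict[tuple[str, str], list[str]] = {}
    for a in assignments:
        groups.setdefault((a.leading_feature or "root", a.klass), []).append(a.gene_id)
    return groups


def save_model_json(model: ConsensusModel | DecisionTree | ConsensusTree, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
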