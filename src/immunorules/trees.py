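"""Divide-and-conquer: decision trees with Cohen's-kappa stopping.

Binary recursive partitioning on elementary conditions (``attr <= v`` for
graded markers, ``attr = 1`` for binary ones), splits chosen by Gini
impurity decrease. Growth is best-first: the committed split is always the
admissible one with the largest impurity decrease anywhere in the current
frontier, and after each committed split Cohen's kappa of the whole tree is
evaluated on the entire training set -- growth halts once it reaches the
``kappa_stop`` threshold (default 0.8), keeping trees small enough to read
while accurate enough to trust.

Cohen's kappa corrects classifier accuracy for the agreement a
class-distribution random classifier would reach:

    kappa = (ACC - RAND) / (1 - RAND)
    ACC   = (TP + TN) / total
    RAND  = ((TN+FP)(TN+FN) + (FN+TP)(FP+TP)) / total^2

Examples with a missing value at a split follow the branch that received
the majority of the node's observed examples (no surrogate splits).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .data_model import DecisionProblem, ImmunoDataset
from .rules import ElementaryCondition, Rule, evaluate_rule

__all__ = [
    "ConfusionMatrix",
    "kappa",
    "TreeNode",
    "DecisionTree",
    "TreeParams",
    "grow_tree",
    "tree_to_rules",
    "tree_feature_importance",
    "grid_search_tree",
    "render_tree",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary-classifier confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement with the true labels."""
    tot = cm.total
    if tot == 0:
        raise ValueError("kappa undefined for an empty confusion matrix")
    acc = (cm.tp + cm.tn) / tot
    rand = ((cm.tn + cm.fp) * (cm.tn + cm.fn)
            + (cm.fn + cm.tp) * (cm.fp + cm.tp)) / tot ** 2
    if rand == 1.0:
        raise ValueError("kappa undefined: degenerate single-class matrix")
    return (acc - rand) / (1.0 - rand)


@dataclass
class TreeParams:
    """Growth constraints (rpart-style defaults).

    ``complexity`` is the minimum impurity decrease of a split relative to
    the root node's Gini impurity (the rpart cp analogue).
    """

    min_split: int = 20
    min_leaf: int = 7
    max_depth: int = 30
    complexity: float = 0.01


@dataclass
class TreeNode:
    """One node; internal nodes carry the split, leaves a prediction."""

    n_primary: int
    n_secondary: int
    depth: int
    condition: ElementaryCondition | None = None
    yes: "TreeNode | None" = None
    no: "TreeNode | None" = None
    missing_to_yes: bool = True  # branch missing values follow

    @property
    def is_leaf(self) -> bool:
        return self.condition is None

    @property
    def n(self) -> int:
        return self.n_primary + self.n_secondary

    @property
    def majority_primary(self) -> bool:
        # ties predict the secondary (overall majority) class
        return self.n_primary > self.n_secondary


@dataclass
class DecisionTree:
    """A grown tree plus its bookkeeping."""

    root: TreeNode
    primary_class_name: str
    secondary_class_name: str
    feature_names: list[str]
    importances: dict[str, float]
    params: TreeParams
    kappa_: float | None = None

    @property
    def n_leaves(self) -> int:
        def count(node):
            return 1 if node.is_leaf else count(node.yes) + count(node.no)
        return count(self.root)

    @property
    def depth(self) -> int:
        def d(node):
            return node.depth if node.is_leaf else max(d(node.yes), d(node.no))
        return d(self.root)

    def predict_primary(self, columns: dict[str, np.ndarray],
                        n_rows: int) -> np.ndarray:
        """Boolean array: True where the predicted class is primary."""
        out = np.zeros(n_rows, dtype=bool)

        def walk(node, idx):
            if idx.size == 0:
                return
            if node.is_leaf:
                out[idx] = node.majority_primary
                return
            col = columns[node.condition.attribute][idx]
            sat = node.condition.holds(col)
            miss = np.isnan(col)
            to_yes = sat | (miss & node.missing_to_yes)
            walk(node.yes, idx[to_yes])
            walk(node.no, idx[~to_yes])

        walk(self.root, np.arange(n_rows))
        return out


def _gini(n_pos: int, n_neg: int) -> float:
    n = n_pos + n_neg
    if n == 0:
        return 0.0
    f = n_pos / n
    return 2.0 * f * (1.0 - f)


def _confusion(y_pos: np.ndarray, pred_pos: np.ndarray) -> ConfusionMatrix:
    return ConfusionMatrix(
        tp=int((pred_pos & y_pos).sum()),
        tn=int((~pred_pos & ~y_pos).sum()),
        fp=int((pred_pos & ~y_pos).sum()),
        fn=int((~pred_pos & y_pos).sum()),
    )


def _best_split(columns, binary, y_pos, idx, params: TreeParams,
                root_gini_total: float):
    """Best admissible split of the rows ``idx``; None if no split qualifies.

    Returns ``(decrease, condition, missing_to_yes, yes_idx, no_idx)``.
    Missing rows are routed with the majority of observed rows. The
    decrease is the node-weighted Gini decrease; admissibility requires
    min_leaf on both children and decrease >= complexity * root impurity.
    Ties break by attribute name then smaller threshold.
    """
    n_node = idx.size
    node_pos = int(y_pos[idx].sum())
    node_gini = _gini(node_pos, n_node - node_pos)
    if node_gini == 0.0 or n_node < params.min_split:
        return None
    best = None
    for name in sorted(columns):
        col = columns[name][idx]
        miss = np.isnan(col)
        obs = np.unique(col[~miss])
        if name in binary:
            conds = [ElementaryCondition(name, "=", 1.0)] if len(obs) > 1 else []
        else:
            conds = [ElementaryCondition(name, "<=", float(v)) for v in obs[:-1]]
        for cond in conds:
            sat = cond.holds(col)
            n_sat, n_unsat = int(sat.sum()), int((~sat & ~miss).sum())
            missing_to_yes = n_sat >= n_unsat
            to_yes = sat | (miss & missing_to_yes)
            n_yes = int(to_yes.sum())
            n_no = n_node - n_yes
            if min(n_yes, n_no) < params.min_leaf:
                continue
            yes_pos = int(y_pos[idx[to_yes]].sum())
            no_pos = node_pos - yes_pos
            child = (n_yes * _gini(yes_pos, n_yes - yes_pos)
                     + n_no * _gini(no_pos, n_no - no_pos)) / n_node
            decrease = (n_node / y_pos.size) * (node_gini - child)
            if decrease < params.complexity * root_gini_total - 1e-15:
                continue
            key = (decrease, _KeyName(name), -cond.value)
            if best is None or key > best[0]:
                best = (key, decrease, cond, missing_to_yes,
                        idx[to_yes], idx[~to_yes])
    if best is None:
        return None
    return best[1:]


class _KeyName:
    """Smaller strings compare greater, for max-keyed deterministic ties."""

    __slots__ = ("s",)

    def __init__(self, s):
        self.s = s

    def __gt__(self, other):
        return self.s < other.s

    def __lt__(self, other):
        return self.s > other.s

    def __eq__(self, other):
        return self.s == other.s


def grow_tree(ds: ImmunoDataset, problem: DecisionProblem,
              params: TreeParams | dict | None = None,
              kappa_stop: float = 0.8) -> DecisionTree:
    """Grow a kappa-stopped binary decision tree on the problem's examples.

    Best-first growth by Gini impurity decrease; before every committed
    split the current tree's kappa on the entire training set is checked
    against ``kappa_stop`` (so ``kappa_stop=0`` yields a root leaf).
    Single-class input yields a single leaf.
    """
    if params is None:
        params = TreeParams()
    elif isinstance(params, dict):
        params = TreeParams(**params)
    sub = ds.subset(problem.assigned)
    y_pos = (problem.y.loc[problem.assigned] == 1).to_numpy()
    columns = {m.name: sub.values[m.name].to_numpy(float) for m in sub.markers}
    binary = {m.name for m in sub.markers if m.scale == "binary"}
    n_rows = sub.n_patients
    root = TreeNode(int(y_pos.sum()), int((~y_pos).sum()), depth=0)
    tree = DecisionTree(root, problem.primary_class_name,
                        problem.secondary_class_name, sub.marker_names,
                        {m: 0.0 for m in sub.marker_names}, params)
    if root.n_primary == 0 or root.n_secondary == 0:
        tree.kappa_ = None  # kappa undefined on a single class
        return tree
    root_gini_total = _gini(root.n_primary, root.n_secondary)

    # frontier: leaf -> (rows, best split or None)
    frontier: list[tuple[TreeNode, np.ndarray]] = [(root, np.arange(n_rows))]

    def current_kappa() -> float:
        pred = tree.predict_primary(columns, n_rows)
        return kappa(_confusion(y_pos, pred))

    while True:
        k = current_kappa()
        tree.kappa_ = k
        if k >= kappa_stop:
            break
        best = None  # (decrease, leaf_i, split)
        for i, (leaf, rows) in enumerate(frontier):
            if leaf.depth >= params.max_depth:
                continue
            split = _best_split(columns, binary, y_pos, rows, params,
                                root_gini_total)
            if split is None:
                continue
            if best is None or split[0] > best[0]:
                best = (split[0], i, split)
        if best is None:
            break
        decrease, i, (_, cond, miss_yes, yes_idx, no_idx) = best
        leaf, rows = frontier.pop(i)
        leaf.condition = cond
        leaf.missing_to_yes = miss_yes
        yes_pos = int(y_pos[yes_idx].sum())
        no_pos = int(y_pos[no_idx].sum())
        leaf.yes = TreeNode(yes_pos, yes_idx.size - yes_pos, leaf.depth + 1)
        leaf.no = TreeNode(no_pos, no_idx.size - no_pos, leaf.depth + 1)
        tree.importances[cond.attribute] += decrease
        frontier.append((leaf.yes, yes_idx))
        frontier.append((leaf.no, no_idx))
    return tree


def tree_to_rules(tree: DecisionTree, ds: ImmunoDataset | None = None,
                  problem: DecisionProblem | None = None) -> list[Rule]:
    """One rule per leaf: the conjunction of conditions on the path.

    Conditions on the "not satisfied" branch enter complemented. On
    complete data the premises partition the example space. If ``ds`` and
    ``problem`` are given, rule statistics are evaluated on them.
    """
    rules: list[Rule] = []

    def walk(node: TreeNode, premise: tuple):
        if node.is_leaf:
            cls = (tree.primary_class_name if node.majority_primary
                   else tree.secondary_class_name)
            rules.append(Rule(premise, cls))
            return
        walk(node.yes, premise + (node.condition,))
        walk(node.no, premise + (node.condition.negate(),))

    walk(tree.root, ())
    if ds is not None and problem is not None:
        rules = [evaluate_rule(r, ds, problem) for r in rules]
    return rules


def tree_feature_importance(tree: DecisionTree) -> list[tuple[str, float]]:
    """Markers ranked by total Gini decrease; unused markers score 0."""
    return sorted(tree.importances.items(), key=lambda kv: (-kv[1], kv[0]))


def grid_search_tree(ds: ImmunoDataset, problem: DecisionProblem,
                     grid: dict[str, list], kappa_stop: float = 0.8):
    """Exhaustive search of the parameter lattice.

    ``grid`` maps TreeParams field names to candidate values. The tree
    maximizing full-training-set kappa is selected, ties broken by fewer
    leaves, then by lattice order. Returns ``(best_params, best_tree)``.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    names = list(grid)
    best = None  # (kappa, -n_leaves, -order, params, tree)
    for order, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        params = TreeParams(**dict(zip(names, combo)))
        tree = grow_tree(ds, problem, params, kappa_stop)
        k = tree.kappa_ if tree.kappa_ is not None else -math.inf
        key = (k, -tree.n_leaves, -order)
        if best is None or key > best[0]:
            best = (key, params, tree)
    return best[1], best[2]


def render_tree(tree: DecisionTree, indent: str = "  ") -> str:
    """Indented text rendering of the tree."""
    lines: list[str] = []

    def walk(node: TreeNode, prefix: str, label: str):
        counts = f"[{tree.primary_class_name}: {node.n_primary}, " \
                 f"{tree.secondary_class_name}: {node.n_secondary}]"
        if node.is_leaf:
            cls = (tree.primary_class_name if node.majority_primary
                   else tree.secondary_class_name)
            lines.append(f"{prefix}{label}-> {cls} {counts}")
        else:
            miss = "yes" if node.missing_to_yes else "no"
            lines.append(f"{prefix}{label}{node.condition} {counts} "
                         f"(missing -> {miss})")
            walk(node.yes, prefix + indent, "yes: ")
            walk(node.no, prefix + indent, "no:  ")

    walk(tree.root, "", "")
    return "\n".join(lines)
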