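"""Decision-tree rule extraction over binarized kernel literals.

A surrogate model M* of the CNN is grown as a binary decision tree on the
literal table: each internal node tests one kernel's literal (branching on its
sign), chosen greedily to minimize the weighted Gini impurity of the children.
Trees are induced against the CNN's *own* predictions, so each root-to-leaf
path is a conjunction of literals implying a class — a symbolic rule — and
agreement with the CNN (fidelity) is the quantity the tree optimizes.
Accuracy against ground-truth labels is reported but never optimized.

Reduced-error pruning on a held-out fold collapses subtrees whose removal does
not increase held-out misclassifications.  The default depth cap of three
literals per rule body keeps rule sets human-readable while retaining high
fidelity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .quantization import LiteralTable

__all__ = [
    "DecisionTree",
    "TreeNode",
    "Rule",
    "RuleSet",
    "EvaluationReport",
    "InterventionResult",
    "induce_tree",
    "prune_tree",
    "tree_to_rules",
    "apply_rules",
    "evaluate",
    "intervene",
    "tree_to_dot",
]

_GAIN_TOL = 1e-12


@dataclass
class TreeNode:
    counts: np.ndarray  # training class counts reaching this node
    kernel: int | None = None  # None -> leaf; else original kernel id tested
    neg: "TreeNode | None" = None  # branch literal == -1
    pos: "TreeNode | None" = None  # branch literal == +1

    @property
    def is_leaf(self) -> bool:
        return self.kernel is None

    @property
    def prediction(self) -> int:
        # majority class; ties resolve to the lower class index
        return int(np.argmax(self.counts))

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.neg.n_nodes() + self.pos.n_nodes()


@dataclass
class DecisionTree:
    root: TreeNode
    max_depth: int
    n_classes: int = 2

    def n_nodes(self) -> int:
        return self.root.n_nodes()

    def predict(self, literals: LiteralTable) -> np.ndarray:
        values = literals.values
        out = np.empty(len(values), dtype=np.int64)
        for i, row in enumerate(values):
            node = self.root
            while not node.is_leaf:
                col = literals.column_of(node.kernel)
                node = node.pos if row[col] == 1 else node.neg
            out[i] = node.prediction
        return out


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.dot(p, p))


def _class_counts(targets: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(targets, minlength=n_classes).astype(float)


def _grow(
    values: np.ndarray,
    targets: np.ndarray,
    candidates: list[int],
    kernel_ids: np.ndarray,
    depth_left: int,
    min_leaf: int,
    n_classes: int,
) -> TreeNode:
    counts = _class_counts(targets, n_classes)
    node = TreeNode(counts=counts)
    n = len(targets)
    if depth_left == 0 or n < 2 * min_leaf or np.count_nonzero(counts) <= 1:
        return node
    parent_gini = _gini(counts)
    best = None  # (weighted_gini, column)
    for col in candidates:
        mask_pos = values[:, col] == 1
        n_pos = int(mask_pos.sum())
        n_neg = n - n_pos
        if n_pos < min_leaf or n_neg < min_leaf:
            continue
        g = (
            n_neg * _gini(_class_counts(targets[~mask_pos], n_classes))
            + n_pos * _gini(_class_counts(targets[mask_pos], n_classes))
        ) / n
        if parent_gini - g <= _GAIN_TOL:
            continue
        # ties among equal-Gini kernels break to the lowest kernel id
        if best is None or g < best[0] - _GAIN_TOL:
            best = (g, col)
    if best is None:
        return node
    col = best[1]
    mask_pos = values[:, col] == 1
    remaining = [c for c in candidates if c != col]  # no kernel repeats on a path
    node.kernel = int(kernel_ids[col])
    node.neg = _grow(
        values[~mask_pos], targets[~mask_pos], remaining, kernel_ids, depth_left - 1, min_leaf, n_classes
    )
    node.pos = _grow(
        values[mask_pos], targets[mask_pos], remaining, kernel_ids, depth_left - 1, min_leaf, n_classes
    )
    return node


def induce_tree(
    literals: LiteralTable,
    targets: np.ndarray,
    max_depth: int = 3,
    allowed_kernels=None,
    denied_kernels=None,
    min_leaf: int = 2,
    n_classes: int = 2,
) -> DecisionTree:
    """Greedy Gini induction of a depth-capped tree over the literal columns.

    ``targets`` are normally the CNN's predictions ``h(g(x))`` (fidelity-first
    surrogate); passing ground-truth labels fits a plain classifier instead.
    ``allowed_kernels`` / ``denied_kernels`` constrain the vocabulary by
    original kernel id.
    """
    targets = np.asarray(targets, dtype=np.int64)
    if len(targets) != len(literals.values):
        raise ValueError("targets misaligned with literal table")
    if len(targets) == 0:
        raise ValueError("cannot induce a tree from empty data")
    denied = set(int(k) for k in denied_kernels) if denied_kernels is not None else set()
    if allowed_kernels is not None:
        allowed = set(int(k) for k in allowed_kernels)
        if allowed & denied:
            raise ValueError(f"kernels both allowed and denied: {sorted(allowed & denied)}")
    else:
        allowed = set(int(k) for k in literals.kernel_ids) - denied
    candidates = [
        j for j, kid in enumerate(literals.kernel_ids) if int(kid) in allowed and int(kid) not in denied
    ]
    if not candidates:
        raise ValueError("no kernels left in the vocabulary after allow/deny filtering")
    root = _grow(
        literals.values, targets, candidates, np.asarray(literals.kernel_ids), max_depth, min_leaf, n_classes
    )
    return DecisionTree(root=root, max_depth=max_depth, n_classes=n_classes)


def _prune(node: TreeNode, literals: LiteralTable, idx: np.ndarray, targets: np.ndarray) -> tuple[TreeNode, int]:
    """Reduced-error pruning; returns (pruned node, held-out errors of it)."""
    if node.is_leaf:
        return node, int(np.sum(targets[idx] != node.prediction))
    col = literals.column_of(node.kernel)
    mask_pos = literals.values[idx, col] == 1
    neg, err_neg = _prune(node.neg, literals, idx[~mask_pos], targets)
    pos, err_pos = _prune(node.pos, literals, idx[mask_pos], targets)
    node = TreeNode(counts=node.counts, kernel=node.kernel, neg=neg, pos=pos)
    subtree_err = err_neg + err_pos
    leaf_err = int(np.sum(targets[idx] != node.prediction))
    if leaf_err <= subtree_err:
        return TreeNode(counts=node.counts), leaf_err
    return node, subtree_err


def prune_tree(tree: DecisionTree, literals: LiteralTable, targets: np.ndarray) -> DecisionTree:
    """Collapse subtrees whenever held-out misclassifications do not increase.

    Applied bottom-up in one pass, which reaches the fixed point.  An empty
    held-out split skips pruning with a warning.
    """
    targets = np.asarray(targets, dtype=np.int64)
    if len(targets) == 0:
        warnings.warn("empty held-out split: skipping pruning", stacklevel=2)
        return tree
    root, _ = _prune(tree.root, literals, np.arange(len(targets)), targets)
    return DecisionTree(root=root, max_depth=tree.max_depth, n_classes=tree.n_classes)


@dataclass(frozen=True)
class Rule:
    """body: conjunction of (kernel id, sign) literals; head: predicted class."""

    body: tuple[tuple[int, int], ...]
    head: int
    support: int = 0
    confidence: float = float("nan")

    def format(self, codes: dict[int, str], class_names=("Healthy", "Effusion")) -> str:
        if not self.body:
            return f"TRUE → {class_names[self.head]}"
        lits = " ∧ ".join(
            (codes[k] if s > 0 else "¬" + codes[k]) for k, s in self.body
        )
        return f"{lits} → {class_names[self.head]}"


@dataclass
class RuleSet:
    """The exhaustive, mutually exclusive path set of one decision tree."""

    rules: list[Rule]
    kernel_vocabulary: tuple[int, ...] = field(default_factory=tuple)

    def kernels_used(self) -> set[int]:
        return {k for r in self.rules for k, _ in r.body}

    def to_json(self, codes: dict[int, str] | None = None) -> str:
        payload = {
            "rules": [
                {
                    "body": [
                        {
                            "kernel": k,
                            "sign": s,
                            **({"code": codes[k]} if codes else {}),
                        }
                        for k, s in r.body
                    ],
                    "head": r.head,
                    "support": r.support,
                    "confidence": None if np.isnan(r.confidence) else r.confidence,
                }
                for r in self.rules
            ],
            "kernel_vocabulary": list(self.kernel_vocabulary),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def tree_to_rules(tree: DecisionTree) -> RuleSet:
    """One rule per leaf; bodies are root-to-leaf conjunctions."""
    rules: list[Rule] = []
    vocab: set[int] = set()

    def walk(node: TreeNode, body: tuple) -> None:
        if node.is_leaf:
            n = node.counts.sum()
            rules.append(
                Rule(
                    body=body,
                    head=node.prediction,
                    support=int(n),
                    confidence=float(node.counts[node.prediction] / n) if n else float("nan"),
                )
            )
            return
        vocab.add(node.kernel)
        walk(node.neg, body + ((node.kernel, -1),))
        walk(node.pos, body + ((node.kernel, +1),))

    walk(tree.root, ())
    return RuleSet(rules=rules, kernel_vocabulary=tuple(sorted(vocab)))


def apply_rules(rules: RuleSet, literals: LiteralTable) -> np.ndarray:
    """Predict by firing the single matching rule body per image.

    Raises if a rule references a kernel missing from the table, or if the
    bodies fail to partition the inputs (which cannot happen for rule sets
    derived from one tree).
    """
    n = len(literals.values)
    fired = np.zeros(n, dtype=int)
    out = np.empty(n, dtype=np.int64)
    for rule in rules.rules:
        mask = np.ones(n, dtype=bool)
        for kernel, sign in rule.body:
            col = literals.column_of(kernel)  # KeyError if missing
            mask &= literals.values[:, col] == sign
        fired += mask
        out[mask] = rule.head
    if not np.all(fired == 1):
        raise ValueError("rule bodies do not partition the input table")
    return out


@dataclass
class EvaluationReport:
    """Accuracy/sensitivity/specificity vs labels; fidelity vs CNN predictions."""

    accuracy: float
    fidelity: float
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int
    split: str = "train"

    @staticmethod
    def from_predictions(
        predictions: np.ndarray,
        labels: np.ndarray,
        cnn_predictions: np.ndarray,
        split: str = "train",
    ) -> "EvaluationReport":
        predictions = np.asarray(predictions)
        labels = np.asarray(labels)
        cnn_predictions = np.asarray(cnn_predictions)
        if not (len(predictions) == len(labels) == len(cnn_predictions)):
            raise ValueError("predictions, labels and CNN predictions must align")
        tp = int(np.sum((predictions == 1) & (labels == 1)))
        fn = int(np.sum((predictions == 0) & (labels == 1)))
        tn = int(np.sum((predictions == 0) & (labels == 0)))
        fp = int(np.sum((predictions == 1) & (labels == 0)))
        return EvaluationReport(
            accuracy=(tp + tn) / len(labels),
            fidelity=float(np.mean(predictions == cnn_predictions)),
            sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
            specificity=tn / (tn + fp) if tn + fp else float("nan"),
            tp=tp,
            fn=fn,
            tn=tn,
            fp=fp,
            split=split,
        )


def evaluate(
    rules: RuleSet,
    literals: LiteralTable,
    labels: np.ndarray,
    cnn_predictions: np.ndarray,
    split: str = "train",
) -> EvaluationReport:
    """Score a rule set: accuracy vs labels, fidelity vs the CNN (class 1 positive)."""
    preds = apply_rules(rules, literals)
    return EvaluationReport.from_predictions(preds, labels, cnn_predictions, split=split)


@dataclass
class InterventionResult:
    """Side-by-side outcome of re-inducing under a constrained vocabulary."""

    baseline_rules: RuleSet
    baseline_report: EvaluationReport
    rules: RuleSet
    report: EvaluationReport

    @property
    def fidelity_delta(self) -> float:
        return self.report.fidelity - self.baseline_report.fidelity

    @property
    def accuracy_delta(self) -> float:
        return self.report.accuracy - self.baseline_report.accuracy


def intervene(
    literals: LiteralTable,
    cnn_predictions: np.ndarray,
    labels: np.ndarray,
    allow=None,
    deny=None,
    max_depth: int = 3,
    min_leaf: int = 2,
) -> InterventionResult:
    """The what-if workflow: re-induce with an allow/deny-constrained kernel
    vocabulary and report against the unconstrained baseline."""
    base_tree = induce_tree(literals, cnn_predictions, max_depth=max_depth, min_leaf=min_leaf)
    base_rules = tree_to_rules(base_tree)
    base_report = evaluate(base_rules, literals, labels, cnn_predictions)
    tree = induce_tree(
        literals,
        cnn_predictions,
        max_depth=max_depth,
        allowed_kernels=allow,
        denied_kernels=deny,
        min_leaf=min_leaf,
    )
    rules = tree_to_rules(tree)
    report = evaluate(rules, literals, labels, cnn_predictions)
    return InterventionResult(
        baseline_rules=base_rules, baseline_report=base_report, rules=rules, report=report
    )


def tree_to_dot(tree: DecisionTree, codes: dict[int, str], class_names=("Healthy", "Effusion")) -> str:
    """Graphviz DOT rendering of the tree (negative branch left, labeled '-')."""
    lines = ["digraph rules {", "  node [shape=box];"]
    counter = [0]

    def walk(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        if node.is_leaf:
            lines.append(
                f'  n{nid} [label="{class_names[node.prediction]}\\n'
                f'counts={node.counts.astype(int).tolist()}", style=filled, fillcolor=lightgray];'
            )
            return nid
        lines.append(f'  n{nid} [label="{codes[node.kernel]}"];')
        left = walk(node.neg)
        right = walk(node.pos)
        lines.append(f'  n{nid} -> n{left} [label="¬"];')
        lines.append(f'  n{nid} -> n{right} [label="+"];')
        return nid

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)
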