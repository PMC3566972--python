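"""Alternating decision tree over position-residue conditions.

An alternating decision tree (ADTree) is a boosted classifier that
alternates *prediction nodes*, each carrying a real value, with *splitter
(decision) nodes*, each testing a predicate. To score a hexapeptide the
tree is traversed along **all** paths whose predicates hold, and the
values of every prediction node visited are summed; the sign of the sum
is the class (positive = amyloidogenic).

The base predicates are the 120 equality tests ``AA_position == residue``
(6 positions x 20 residues). Training is boosting: instances carry
weights w_i (initially 1); each iteration scans every existing prediction
node's path predicate c1 and every base condition c2 and adds, at the
pair minimizing

    Z(c1, c2) = 2*( sqrt(W+(c1&c2) * W-(c1&c2))
                  + sqrt(W+(c1&~c2) * W-(c1&~c2)) ) + W(~c1),

a splitter whose two prediction values are the half-log-odds of the
smoothed class-weight ratio on their weight subsets,

    a = 1/2 * ln((W+(c1&c2) + eps) / (W-(c1&c2) + eps)),

after which the weights of the instances reaching either new prediction
node are multiplied by exp(-y * value). The search is exhaustive over all
(prediction node, base condition) pairs; ties in Z are broken by lowest
position, then alphabetical residue, then earliest-added prediction node,
so training is fully deterministic.

Smoothing eps (default 1.0) keeps prediction values finite on pure weight
subsets. The additive score is a boosting margin; ``predict_proba``
exposes the standard logistic calibration 1/(1+exp(-2*score)) for ROC
ranking.
"""

from __future__ import annotations

import json
import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .hexdata import HexDataset, validate_hexapeptide

N_POSITIONS = 6
N_CONDITIONS = N_POSITIONS * len(AMINO_ACIDS)


@dataclass(frozen=True)
class Condition:
    """Predicate ``AA_position == residue`` (position is 1-based)."""

    position: int
    residue: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= N_POSITIONS:
            raise ValueError(f"position must be 1..6, got {self.position}")
        if self.residue not in AA_INDEX:
            raise ValueError(f"unknown residue {self.residue!r}")

    def matches(self, sequence: str) -> bool:
        return sequence[self.position - 1] == self.residue

    def __str__(self) -> str:
        return f"AA{self.position}={self.residue}"


@dataclass
class SplitterNode:
    condition: Condition
    true_child: "PredictionNode"
    false_child: "PredictionNode"
    order: int  # boosting iteration at which the splitter was added


@dataclass
class PredictionNode:
    value: float
    children: list[SplitterNode] = field(default_factory=list)


@dataclass(frozen=True)
class Rule:
    """One splitter in export notation, numbered by boosting order."""

    number: int
    condition: Condition
    true_value: float
    false_value: float

    def __str__(self) -> str:
        c = self.condition
        return (
            f"{self.number}: AA{c.position} | {c.residue} {self.true_value:.3f}"
            f" | !{c.residue} {self.false_value:.3f}"
        )


class ADTreeModel:
    """A trained alternating decision tree."""

    def __init__(self, root: PredictionNode, iterations: int, smoothing: float):
        self.root = root
        self.iterations = iterations
        self.smoothing = smoothing

    # -- scoring --

    def predict_score(self, peptide: str) -> float:
        """Sum of all prediction-node values on satisfied paths."""
        validate_hexapeptide(peptide)
        return self._walk(self.root, peptide)

    def _walk(self, node: PredictionNode, peptide: str) -> float:
        total = node.value
        for sp in node.children:
            child = sp.true_child if sp.condition.matches(peptide) else sp.false_child
            total += self._walk(child, peptide)
        return total

    def decision_function(self, peptides: Sequence[str]) -> np.ndarray:
        return np.array([self.predict_score(p) for p in peptides])

    def predict(self, peptides: Sequence[str]) -> np.ndarray:
        """Class labels: amyloidogenic iff score > 0."""
        return self.decision_function(peptides) > 0.0

    def predict_proba(self, peptides: Sequence[str]) -> np.ndarray:
        """Logistic calibration of the boosting margin, for ROC ranking."""
        scores = self.decision_function(peptides)
        return 1.0 / (1.0 + np.exp(-2.0 * scores))

    # -- introspection --

    def splitters(self) -> list[SplitterNode]:
        out: list[SplitterNode] = []

        def visit(node: PredictionNode) -> None:
            for sp in node.children:
                out.append(sp)
                visit(sp.true_child)
                visit(sp.false_child)

        visit(self.root)
        return sorted(out, key=lambda sp: sp.order)

    def rules(self) -> list[Rule]:
        """Rule listing ordered by boosting iteration (significance)."""
        return [
            Rule(sp.order + 1, sp.condition, sp.true_child.value, sp.false_child.value)
            for sp in self.splitters()
        ]

    def format_rules(self) -> str:
        lines = [f"root {self.root.value:.3f}"]
        lines.extend(str(r) for r in self.rules())
        return "\n".join(lines)

    # -- serialization --

    def to_dict(self) -> dict:
        def node_dict(node: PredictionNode) -> dict:
            return {
                "value": node.value,
                "children": [
                    {
                        "position": sp.condition.position,
                        "residue": sp.condition.residue,
                        "order": sp.order,
                        "true": node_dict(sp.true_child),
                        "false": node_dict(sp.false_child),
                    }
                    for sp in node.children
                ],
            }

        return {
            "kind": "adtree",
            "iterations": self.iterations,
            "smoothing": self.smoothing,
            "root": node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ADTreeModel":
        def build(d: dict) -> PredictionNode:
            node = PredictionNode(float(d["value"]))
            for ch in d["children"]:
                node.children.append(
                    SplitterNode(
                        Condition(int(ch["position"]), str(ch["residue"])),
                        build(ch["true"]),
                        build(ch["false"]),
                        int(ch["order"]),
                    )
                )
            return node

        return cls(build(payload["root"]), int(payload["iterations"]), float(payload["smoothing"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ADTreeModel":
        return cls.from_dict(json.loads(text))


def _half_log_odds(w_pos: float, w_neg: float, eps: float) -> float:
    return 0.5 * math.log((w_pos + eps) / (w_neg + eps))


def train_adtree(
    train: HexDataset | tuple[Sequence[str], Sequence[bool]],
    iterations: int = 50,
    smoothing: float = 1.0,
    tie_policy: str = "position-residue-path",
) -> ADTreeModel:
    """Boost an alternating decision tree on labeled hexapeptides.

    Parameters
    ----------
    train
        A :class:`HexDataset`, or a ``(sequences, labels)`` pair.
    iterations
        Number of splitter nodes to add (one per boosting round). The
        interpretable regime uses 50; 250 gives the strongest classifier.
    smoothing
        eps added inside every half-log-odds ratio; keeps values finite.
    tie_policy
        Only ``"position-residue-path"`` is implemented: ties in Z fall to
        the lowest position, then alphabetical residue, then the earliest
        added prediction node.
    """
    if tie_policy != "position-residue-path":
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if isinstance(train, HexDataset):
        sequences, labels = train.sequences, train.labels
    else:
        sequences, labels = list(train[0]), np.asarray(train[1], dtype=bool)
    n = len(sequences)
    if n == 0:
        raise ValueError("empty training set")
    y = np.where(labels, 1.0, -1.0)
    if iterations > 0 and (labels.all() or not labels.any()):
        raise ValueError("training set must contain both classes")

    # one-hot condition matrix: X[i, 20*p + r] == 1 iff residue r at position p
    X = np.zeros((n, N_CONDITIONS))
    for i, seq in enumerate(sequences):
        validate_hexapeptide(seq)
        for p, ch in enumerate(seq):
            X[i, 20 * p + AA_INDEX[ch]] = 1.0

    pos = labels.astype(float)
    neg = 1.0 - pos
    w = np.ones(n)

    root_value = _half_log_odds(float(w[labels].sum()), float(w[~labels].sum()), smoothing)
    root = PredictionNode(root_value)
    w *= np.exp(-y * root_value)

    # prediction-node registry in creation order; column j of `paths` marks
    # the instances satisfying node j's full path predicate
    nodes: list[PredictionNode] = [root]
    paths = np.ones((n, 1))

    for t in range(iterations):
        wp = w * pos
        wn = w * neg
        w_total = float(w.sum())

        wp_nc = paths.T @ (wp[:, None] * X)  # (m, 120): W+(c1 & c2)
        wn_nc = paths.T @ (wn[:, None] * X)
        wp_node = paths.T @ wp  # W+(c1)
        wn_node = paths.T @ wn
        w_node = paths.T @ w  # W(c1)
        # subtraction can undershoot zero by an ulp; clip before sqrt
        wp_not = np.maximum(wp_node[:, None] - wp_nc, 0.0)  # W+(c1 & ~c2)
        wn_not = np.maximum(wn_node[:, None] - wn_nc, 0.0)

        Z = (
            2.0 * (np.sqrt(wp_nc * wn_nc) + np.sqrt(wp_not * wn_not))
            + (w_total - w_node)[:, None]
        )

        best = np.min(Z)
        # deterministic tie-break: (position, residue, node creation order);
        # condition index 20*p + r already orders by position then residue.
        # Candidates within a relative 1e-9 of the minimum count as tied so
        # the choice is stable against last-ulp summation-order noise.
        tol = 1e-9 * (1.0 + abs(best))
        tie_nodes, tie_conds = np.nonzero(Z <= best + tol)
        order = np.lexsort((tie_nodes, tie_conds))
        j = int(tie_nodes[order[0]])
        c = int(tie_conds[order[0]])

        condition = Condition(c // 20 + 1, AMINO_ACIDS[c % 20])
        a = _half_log_odds(float(wp_nc[j, c]), float(wn_nc[j, c]), smoothing)
        b = _half_log_odds(float(wp_not[j, c]), float(wn_not[j, c]), smoothing)

        true_node = PredictionNode(a)
        false_node = PredictionNode(b)
        splitter = SplitterNode(condition, true_node, false_node, order=t)
        nodes[j].children.append(splitter)

        mask_true = paths[:, j] * X[:, c]
        mask_false = paths[:, j] * (1.0 - X[:, c])
        paths = np.column_stack([paths, mask_true, mask_false])
        nodes.extend([true_node, false_node])

        w *= np.exp(-y * (a * mask_true + b * mask_false))

    return ADTreeModel(root, iterations, smoothing)


def save_model(model: ADTreeModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(model.to_json())


def load_model(path) -> ADTreeModel:
    with open(path, encoding="utf-8") as fh:
        return ADTreeModel.from_json(fh.read())
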