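"""C4.5-style binary decision trees on continuous features.

Splits are chosen by gain ratio among candidate thresholds with positive
information gain; optionally (on by default, as in C4.5) a per-feature
pre-filter keeps only thresholds whose raw gain is at least the mean gain
over that feature's positive-gain candidates.  ``<=`` routes left, ``>``
routes right, everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._splits import GAIN_TOL, split_scan
from .matrix import ExpressionMatrix, ExpressionError


@dataclass
class TreeNode:
    feature_id: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None
    class_counts: dict | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature_id is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"label": self.label, "counts": self.class_counts}
        return {
            "feature": self.feature_id,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "label" in d:
            return cls(label=d["label"], class_counts=dict(d["counts"]))
        return cls(
            feature_id=d["feature"],
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass(frozen=True)
class Split:
    feature_id: str
    threshold: float
    gain_ratio: float
    gain: float


@dataclass
class DecisionTree:
    root: TreeNode
    feature_ids_used: set = field(default_factory=set)
    params: dict = field(default_factory=dict)

    @property
    def is_single_leaf(self) -> bool:
        return self.root.is_leaf

    @property
    def root_feature(self) -> str | None:
        return self.root.feature_id

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def classify(self, sample: dict, positive_class: str) -> tuple[str, float]:
        """Route one sample; score is the Laplace-smoothed positive fraction
        ``(count_pos + 1) / (count_total + 2)`` at the reached leaf."""
        node = self.root
        while not node.is_leaf:
            if node.feature_id not in sample:
                raise ExpressionError(
                    f"sample missing tested feature {node.feature_id!r}"
                )
            node = node.left if sample[node.feature_id] <= node.threshold else node.right
        counts = node.class_counts or {}
        total = sum(counts.values())
        pos = counts.get(positive_class, 0)
        return node.label, (pos + 1) / (total + 2)

    def predict_matrix(self, m: ExpressionMatrix, positive_class: str):
        """Vectorized-ish classification of every sample in a matrix."""
        labels, scores = [], []
        cols = m.values.columns
        sub = m.values
        for s in cols:
            sample = sub[s].to_dict()
            lab, sc = self.classify(sample, positive_class)
            labels.append(lab)
            scores.append(sc)
        return np.array(labels), np.array(scores)

    def training_accuracy(self) -> float:
        correct = total = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                c = node.class_counts or {}
                correct += c.get(node.label, 0)
                total += sum(c.values())
            else:
                stack.extend([node.left, node.right])
        return correct / total if total else 0.0

    def paths(self):
        """Yield ``(conditions, leaf)`` for every root-to-leaf path, where
        conditions is a list of ``(feature_id, op, threshold)`` with op in
        {'<=', '>'}."""

        def walk(node, conds):
            if node.is_leaf:
                yield list(conds), node
                return
            yield from walk(node.left, conds + [(node.feature_id, "<=", node.threshold)])
            yield from walk(node.right, conds + [(node.feature_id, ">", node.threshold)])

        yield from walk(self.root, [])

    def to_json(self) -> str:
        return json.dumps({"params": self.params, "root": self.root.to_dict()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        d = json.loads(text)
        root = TreeNode.from_dict(d["root"])
        used = set()
        stack = [root]
        while stack:
            n = stack.pop()
            if not n.is_leaf:
                used.add(n.feature_id)
                stack.extend([n.left, n.right])
        return cls(root=root, feature_ids_used=used, params=d.get("params", {}))


def best_split(
    values_by_feature: dict,
    labels: np.ndarray,
    allowed_features,
    min_child: int = 1,
    gain_mean_filter: bool = True,
    threshold_style: str = "midpoint",
) -> Split | None:
    """Best (feature, threshold) by gain ratio among positive-gain candidates.

    Returns None when no candidate has positive gain (e.g. a pure node),
    which is a valid outcome, not an error.
    """
    allowed = sorted(allowed_features)
    if not allowed:
        raise ExpressionError("no allowed features for splitting")
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        return None
    y = (labels == classes[-1]).astype(np.int64)
    best: Split | None = None
    for fid in allowed:
        vals = np.asarray(values_by_feature[fid], dtype=float)
        thr, gains, sinfo, left_n = split_scan(vals, y, threshold_style)
        if thr.size == 0:
            continue
        ok = gains > GAIN_TOL
        if min_child > 1:
            n = len(vals)
            ok &= (left_n >= min_child) & ((n - left_n) >= min_child)
        if not ok.any():
            continue
        if gain_mean_filter:
            mean_gain = gains[gains > GAIN_TOL].mean()
            ok &= gains >= mean_gain - GAIN_TOL
            if not ok.any():
                continue
        ratios = np.where(ok, gains / np.maximum(sinfo, 1e-300), -np.inf)
        i = int(np.argmax(ratios))
        cand = Split(fid, float(thr[i]), float(ratios[i]), float(gains[i]))
        if (
            best is None
            or cand.gain_ratio > best.gain_ratio + GAIN_TOL
            or (
                abs(cand.gain_ratio - best.gain_ratio) <= GAIN_TOL
                and (cand.feature_id, cand.threshold)
                < (best.feature_id, best.threshold)
            )
        ):
            best = cand
    return best


def _majority(counts: dict, priors: dict) -> str:
    best = max(counts.values())
    tied = [c for c, k in counts.items() if k == best]
    if len(tied) == 1:
        return tied[0]
    # tie: larger class prior in the full training set, then lexicographic
    best_prior = max(priors.get(c, 0) for c in tied)
    tied = sorted(c for c in tied if priors.get(c, 0) == best_prior)
    return tied[0]


def build_tree(
    m: ExpressionMatrix,
    allowed_features,
    min_leaf: int = 2,
    gain_mean_filter: bool = True,
    threshold_style: str = "midpoint",
) -> DecisionTree:
    """Recursively induce a gain-ratio tree on the allowed features.

    Stops at pure nodes, nodes smaller than ``2 * min_leaf``, or when no
    split has positive gain.  Deterministic given its inputs.
    """
    allowed = sorted(allowed_features)
    if not allowed:
        raise ExpressionError("allowed_features must be non-empty")
    missing = [f for f in allowed if f not in m.values.index]
    if missing:
        raise ExpressionError(f"unknown feature(s): {missing}")
    values = {f: m.feature_values(f) for f in allowed}
    labels = m.label_array()
    classes = sorted(set(labels.tolist()))
    priors = {c: int((labels == c).sum()) for c in classes}
    used: set = set()

    def counts_of(idx) -> dict:
        sub = labels[idx]
        return {c: int((sub == c).sum()) for c in classes}

    def grow(idx: np.ndarray) -> TreeNode:
        counts = counts_of(idx)
        present = [c for c in classes if counts[c] > 0]
        if len(present) == 1 or len(idx) < 2 * min_leaf:
            return TreeNode(label=_majority(counts, priors), class_counts=counts)
        sub_vals = {f: values[f][idx] for f in allowed}
        split = best_split(
            sub_vals,
            labels[idx],
            allowed,
            min_child=min_leaf,
            gain_mean_filter=gain_mean_filter,
            threshold_style=threshold_style,
        )
        if split is None:
            return TreeNode(label=_majority(counts, priors), class_counts=counts)
        used.add(split.feature_id)
        go_left = values[split.feature_id][idx] <= split.threshold
        return TreeNode(
            feature_id=split.feature_id,
            threshold=split.threshold,
            left=grow(idx[go_left]),
            right=grow(idx[~go_left]),
        )

    root = grow(np.arange(m.n_samples))
    return DecisionTree(
        root=root,
        feature_ids_used=used,
        params={
            "min_leaf": min_leaf,
            "gain_mean_filter": gain_mean_filter,
            "threshold_style": threshold_style,
        },
    )
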