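"""Decision-tree committee by iterative root-feature removal.

The first tree is induced on the full candidate set; each subsequent tree
is induced after deleting the previous tree's root feature, until only
two candidate features remain (or a tree degenerates to a single leaf).
100%-frequency rules are harvested from the root-to-pure-leaf paths of
every committee tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .matrix import ExpressionMatrix, ExpressionError
from .rules import (
    NEG_INF,
    POS_INF,
    Conjunct,
    ConjunctiveRule,
    attach_coverage,
    is_frequency_rule,
)
from .tree import DecisionTree, build_tree


@dataclass
class Committee:
    trees: list = field(default_factory=list)
    removed_features: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trees)


def build_committee(
    m: ExpressionMatrix,
    candidate_features,
    min_leaf: int = 2,
    gain_mean_filter: bool = True,
    threshold_style: str = "midpoint",
) -> Committee:
    """Iteratively induce trees, deleting each tree's root feature.

    With ``k`` candidates and every tree producing a root split the
    committee holds ``k - 1`` trees (the last is induced on 2 features).
    """
    candidates = sorted(set(candidate_features))
    if len(candidates) < 2:
        raise ExpressionError("committee needs at least 2 candidate features")
    missing = [f for f in candidates if f not in m.values.index]
    if missing:
        raise ExpressionError(f"unknown candidate feature(s): {missing}")
    committee = Committee()
    remaining = list(candidates)
    while len(remaining) >= 2:
        tree = build_tree(
            m,
            remaining,
            min_leaf=min_leaf,
            gain_mean_filter=gain_mean_filter,
            threshold_style=threshold_style,
        )
        if tree.is_single_leaf:
            warnings.warn(
                "committee stopped early: induced tree is a single leaf "
                f"with {len(remaining)} candidate features remaining",
                stacklevel=2,
            )
            break
        committee.trees.append(tree)
        committee.removed_features.append(tree.root_feature)
        remaining.remove(tree.root_feature)
    return committee


def _path_to_conjuncts(conditions) -> tuple:
    """Merge a path's per-feature conditions into closed intervals."""
    bounds: dict = {}
    for fid, op, thr in conditions:
        lo, hi = bounds.get(fid, (NEG_INF, POS_INF))
        if op == "<=":
            hi = min(hi, thr)
        else:  # '>' branch; represent as a closed lower bound at the midpoint
            lo = max(lo, thr)
        bounds[fid] = (lo, hi)
    return tuple(
        Conjunct(feature_id=fid, lower=lo, upper=hi)
        for fid, (lo, hi) in sorted(bounds.items())
    )


def harvest_rules(
    committee: Committee,
    m: ExpressionMatrix,
    arity_range=(2, 3),
) -> list:
    """Collect 100%-frequency rules from pure-leaf paths of all trees.

    Only paths ending in a pure leaf can satisfy the zero-other-coverage
    requirement; the frequency check is always re-done on the full matrix.
    Exact duplicates (same features, bounds, class) are collapsed, keeping
    the earliest tree's provenance.
    """
    lo_arity, hi_arity = min(arity_range), max(arity_range)
    seen: dict = {}
    for t_idx, tree in enumerate(committee.trees, start=1):
        for conditions, leaf in tree.paths():
            counts = leaf.class_counts or {}
            nonzero = [c for c, k in counts.items() if k > 0]
            if len(nonzero) != 1:
                continue  # impure leaf can never give zero other-class coverage
            target = nonzero[0]
            conjuncts = _path_to_conjuncts(conditions)
            if not lo_arity <= len(conjuncts) <= hi_arity:
                continue
            rule = ConjunctiveRule(
                conjuncts=conjuncts,
                target_class=target,
                provenance={"method": "committee", "tree_index": t_idx},
            )
            if not is_frequency_rule(rule, m)["valid"]:
                continue
            key = rule.key()
            if key not in seen:
                seen[key] = attach_coverage(rule, m)
    return list(seen.values())
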