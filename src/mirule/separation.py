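"""Max-Min distance separation: rank rules by the shortest inter-class
Euclidean distance in their 2D/3D feature subspace.

The margin of a rule is the minimum over all (class-1 sample, class-2
sample) pairs of the Euclidean distance restricted to the rule's
features, computed over ALL samples of both classes.  Wider margins
indicate more reliable rules; within each arity stratum rules are ranked
by margin descending and the top ceil(k/3) are selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .matrix import ExpressionMatrix, ExpressionError
from .rules import ConjunctiveRule


@dataclass
class SeparationResult:
    rule: ConjunctiveRule
    min_distance: float
    rank: int = 0
    selected: bool = False

    def to_dict(self) -> dict:
        d = self.rule.to_dict()
        d.update(
            {"min_distance": self.min_distance, "rank": self.rank, "selected": self.selected}
        )
        return d


def min_interclass_distance(
    m: ExpressionMatrix, features, scale: str = "none"
) -> float:
    """Shortest pairwise Euclidean distance between the two classes in the
    subspace spanned by ``features`` (2 or 3 ids).

    ``scale='minmax'`` rescales each feature to [0, 1] over all samples
    first; the default uses the expression values as-is.
    """
    features = list(features)
    if not 1 <= len(features) <= 3:
        raise ExpressionError(f"expected 1-3 features, got {len(features)}")
    missing = [f for f in features if f not in m.values.index]
    if missing:
        raise ExpressionError(f"unknown feature(s): {missing}")
    if scale not in ("none", "minmax"):
        raise ExpressionError(f"unknown scale {scale!r}")
    arr = m.values.loc[features].to_numpy(dtype=float)
    if scale == "minmax":
        lo = arr.min(axis=1, keepdims=True)
        span = arr.max(axis=1, keepdims=True) - lo
        span[span == 0] = 1.0
        arr = (arr - lo) / span
    a, b = m.classes
    mask = m.class_mask(a)
    xa = arr[:, mask].T
    xb = arr[:, ~mask].T
    if len(xa) == 0 or len(xb) == 0:
        raise ExpressionError("both classes must be non-empty")
    return float(cdist(xa, xb).min())


def rank_rules_by_separation(
    rules, m: ExpressionMatrix, scale: str = "none"
) -> list:
    """Score every rule's subspace margin and rank within arity strata.

    Ranks are 1..k per stratum (2D and 3D separately), margin descending,
    ties broken by feature ids lexicographically.
    """
    results = [
        SeparationResult(rule=r, min_distance=min_interclass_distance(m, r.feature_ids, scale))
        for r in rules
    ]
    out = []
    for arity in (2, 3):
        stratum = [r for r in results if r.rule.arity == arity]
        stratum.sort(key=lambda s: (-s.min_distance, s.rule.feature_ids))
        for rank, s in enumerate(stratum, start=1):
            s.rank = rank
        n_top = math.ceil(len(stratum) / 3) if stratum else 0
        for s in stratum[:n_top]:
            s.selected = True
        out.extend(stratum)
    return out


def select_top(results) -> list:
    """First ceil(k/3) results of an already-ranked stratum."""
    results = sorted(results, key=lambda s: s.rank)
    if not results:
        return []
    return results[: math.ceil(len(results) / 3)]
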