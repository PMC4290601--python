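"""Conjunctive interval rules over 2-3 features and their coverage checks.

A rule is a conjunction of per-feature intervals (closed on finite sides)
plus a target class.  A *100%-frequency* rule covers every sample of its
target class and no sample of the other class on the full training
matrix — the jumping-emerging-pattern notion of full-coverage rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix, ExpressionError

NEG_INF = float("-inf")
POS_INF = float("inf")


@dataclass(frozen=True)
class Conjunct:
    """``lower <= x_feature <= upper`` with infinite sides allowed."""

    feature_id: str
    lower: float = NEG_INF
    upper: float = POS_INF

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ExpressionError(
                f"conjunct on {self.feature_id!r}: lower {self.lower} must be "
                f"< upper {self.upper}"
            )
        if math.isinf(self.lower) and math.isinf(self.upper):
            raise ExpressionError(
                f"conjunct on {self.feature_id!r} has no finite bound"
            )

    @property
    def one_sided(self) -> bool:
        return math.isinf(self.lower) or math.isinf(self.upper)

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= self.lower) & (x <= self.upper)

    def describe(self) -> str:
        if math.isinf(self.lower):
            return f"{self.feature_id} <= {self.upper:g}"
        if math.isinf(self.upper):
            return f"{self.lower:g} <= {self.feature_id}"
        return f"{self.lower:g} <= {self.feature_id} <= {self.upper:g}"


@dataclass
class ConjunctiveRule:
    """Conjunction of 2-3 interval conjuncts implying a target class."""

    conjuncts: tuple
    target_class: str
    provenance: dict = field(default_factory=dict)
    coverage: dict | None = None

    def __post_init__(self):
        conjs = tuple(sorted(self.conjuncts, key=lambda c: c.feature_id))
        feats = [c.feature_id for c in conjs]
        if len(set(feats)) != len(feats):
            raise ExpressionError(f"duplicate feature in rule: {feats}")
        if not 2 <= len(feats) <= 3:
            raise ExpressionError(
                f"rule must use 2-3 distinct features, got {len(feats)}"
            )
        self.conjuncts = conjs

    @property
    def feature_ids(self) -> tuple:
        return tuple(c.feature_id for c in self.conjuncts)

    @property
    def arity(self) -> int:
        return len(self.conjuncts)

    def key(self):
        """Identity for exact-duplicate collapsing: features, bounds, class."""
        return (
            tuple((c.feature_id, c.lower, c.upper) for c in self.conjuncts),
            self.target_class,
        )

    def covers(self, m: ExpressionMatrix) -> np.ndarray:
        """Boolean mask over the matrix samples satisfying every conjunct."""
        mask = np.ones(m.n_samples, dtype=bool)
        for c in self.conjuncts:
            mask &= c.contains(m.feature_values(c.feature_id))
        return mask

    def predict(self, m: ExpressionMatrix) -> np.ndarray:
        """Use the rule as a classifier: satisfied -> target class, else other."""
        other = m.other_class(self.target_class)
        return np.where(self.covers(m), self.target_class, other)

    def describe(self) -> str:
        body = "  AND  ".join(c.describe() for c in self.conjuncts)
        return f"{body}  ->  {self.target_class} (100%)"

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_ids),
            "conjuncts": [
                {
                    "feature": c.feature_id,
                    "lower": None if math.isinf(c.lower) else c.lower,
                    "upper": None if math.isinf(c.upper) else c.upper,
                }
                for c in self.conjuncts
            ],
            "class": self.target_class,
            "provenance": self.provenance,
            "coverage": self.coverage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConjunctiveRule":
        conjs = tuple(
            Conjunct(
                feature_id=c["feature"],
                lower=NEG_INF if c.get("lower") is None else float(c["lower"]),
                upper=POS_INF if c.get("upper") is None else float(c["upper"]),
            )
            for c in d["conjuncts"]
        )
        return cls(
            conjuncts=conjs,
            target_class=d["class"],
            provenance=d.get("provenance", {}),
            coverage=d.get("coverage"),
        )


def is_frequency_rule(rule: ConjunctiveRule, m: ExpressionMatrix) -> dict:
    """Check the 100%-frequency property on the full matrix.

    Returns ``{"valid": bool, "covered_target": int, "covered_other": int}``
    where valid means every target-class sample and zero other-class
    samples satisfy the rule.
    """
    if rule.target_class not in m.classes:
        raise ExpressionError(
            f"rule class {rule.target_class!r} not in matrix classes {m.classes}"
        )
    covered = rule.covers(m)
    target_mask = m.class_mask(rule.target_class)
    covered_target = int((covered & target_mask).sum())
    covered_other = int((covered & ~target_mask).sum())
    return {
        "valid": covered_target == int(target_mask.sum()) and covered_other == 0,
        "covered_target": covered_target,
        "covered_other": covered_other,
    }


def attach_coverage(rule: ConjunctiveRule, m: ExpressionMatrix) -> ConjunctiveRule:
    chk = is_frequency_rule(rule, m)
    rule.coverage = {"target": chk["covered_target"], "other": chk["covered_other"]}
    return rule
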