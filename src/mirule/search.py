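"""Exhaustive mining of 2-/3-feature one-sided 100%-frequency rules.

For every feature subset of the requested arity, every orientation vector
in {<=, >=}^arity and each target class, the tightest one-sided bounds
covering all target-class samples are computed; a rule is emitted iff no
other-class sample satisfies all conjuncts.  Each conjunct keeps one
infinite side.  A minimality filter removes rules that are subsumed by a
single separating feature or, for triples, by a valid pair-subset rule.
"""

from __future__ import annotations

import itertools

import numpy as np

from .matrix import ExpressionMatrix, ExpressionError
from .rules import (
    NEG_INF,
    POS_INF,
    Conjunct,
    ConjunctiveRule,
    attach_coverage,
)

_ORIENTS = {2: list(itertools.product(("le", "ge"), repeat=2)),
            3: list(itertools.product(("le", "ge"), repeat=3))}


class _ClassView:
    """Per-target-class precomputation reused across feature subsets."""

    def __init__(self, values: np.ndarray, target_mask: np.ndarray):
        self.target = values[:, target_mask]
        self.other = values[:, ~target_mask]
        self.max_t = self.target.max(axis=1)
        self.min_t = self.target.min(axis=1)
        # other-class sample satisfies the tightest 'le'/'ge' conjunct of feature f
        self.sat_le = self.other <= self.max_t[:, None]
        self.sat_ge = self.other >= self.min_t[:, None]

    def satisfies(self, fi: int, orient: str) -> np.ndarray:
        return self.sat_le[fi] if orient == "le" else self.sat_ge[fi]

    def bound(self, fi: int, orient: str, style: str) -> float:
        """Finite bound of the conjunct under the given placement style."""
        if orient == "le":
            b0 = self.max_t[fi]
            if style == "midpoint":
                above = self.other[fi][self.other[fi] > b0]
                if above.size:
                    return float((b0 + above.min()) / 2.0)
            return float(b0)
        b0 = self.min_t[fi]
        if style == "midpoint":
            below = self.other[fi][self.other[fi] < b0]
            if below.size:
                return float((b0 + below.max()) / 2.0)
        return float(b0)


def _conjunct(fid: str, orient: str, bound: float) -> Conjunct:
    if orient == "le":
        return Conjunct(feature_id=fid, lower=NEG_INF, upper=bound)
    return Conjunct(feature_id=fid, lower=bound, upper=POS_INF)


def single_feature_separators(m: ExpressionMatrix) -> set:
    """Features whose single one-sided threshold already separates the classes."""
    a, b = m.classes
    arr = m.values.to_numpy(dtype=float)
    ma = m.class_mask(a)
    va, vb = arr[:, ma], arr[:, ~ma]
    sep = (va.max(axis=1) < vb.min(axis=1)) | (va.min(axis=1) > vb.max(axis=1))
    return {fid for fid, s in zip(m.feature_ids, sep) if s}


def exhaustive_search(
    m: ExpressionMatrix,
    arity: int,
    target_class: str | None = None,
    bound_style: str = "midpoint",
    minimal: bool = True,
    max_features: int | None = None,
) -> list:
    """Mine all minimal one-sided conjunctive 100%-frequency rules of one arity.

    ``target_class=None`` searches both classes.  ``bound_style`` is
    ``midpoint`` (finite bound halfway toward the nearest excluded sample,
    matching the tree threshold dialect) or ``extreme`` (at the target-class
    extreme).  ``max_features`` caps the search to the top gain-ratio
    features for very wide matrices.
    """
    if arity not in (2, 3):
        raise ExpressionError(f"arity must be 2 or 3, got {arity}")
    if bound_style not in ("midpoint", "extreme"):
        raise ExpressionError(f"unknown bound_style {bound_style!r}")
    targets = sorted(m.classes) if target_class is None else [target_class]
    for t in targets:
        if t not in m.classes:
            raise ExpressionError(f"unknown class {t!r}")

    feature_ids = sorted(m.feature_ids)
    if max_features is not None and len(feature_ids) > max_features:
        from .ranking import rank_features

        ranked = rank_features(m)
        keep = {r.feature_id for r in ranked[:max_features]}
        feature_ids = sorted(keep)

    sub = m.values.loc[feature_ids]
    values = sub.to_numpy(dtype=float)
    views = {t: _ClassView(values, m.class_mask(t)) for t in targets}
    separators = single_feature_separators(m) if minimal else set()

    rules = []
    for combo in itertools.combinations(range(len(feature_ids)), arity):
        fids = [feature_ids[i] for i in combo]
        if minimal and any(f in separators for f in fids):
            continue
        for target in targets:
            view = views[target]
            if minimal and arity == 3:
                if any(
                    _pair_admits_rule(view, pair)
                    for pair in itertools.combinations(combo, 2)
                ):
                    continue
            for orient in _ORIENTS[arity]:
                sat = view.satisfies(combo[0], orient[0]).copy()
                for fi, o in zip(combo[1:], orient[1:]):
                    sat &= view.satisfies(fi, o)
                if sat.any():
                    continue  # some other-class sample inside the box
                conjs = tuple(
                    _conjunct(fid, o, view.bound(fi, o, bound_style))
                    for fid, fi, o in zip(fids, combo, orient)
                )
                rule = ConjunctiveRule(
                    conjuncts=conjs,
                    target_class=target,
                    provenance={
                        "method": "exhaustive",
                        "orientation": list(orient),
                        "bound_style": bound_style,
                    },
                )
                rules.append(attach_coverage(rule, m))
    return rules


def _pair_admits_rule(view: _ClassView, pair) -> bool:
    for o1, o2 in _ORIENTS[2]:
        if not (view.satisfies(pair[0], o1) & view.satisfies(pair[1], o2)).any():
            return True
    return False


def minimality_filter(rules: list, m: ExpressionMatrix) -> list:
    """Drop non-minimal and duplicate rules from a pooled rule list.

    An arity-2 rule is dropped if one of its features alone separates the
    classes; an arity-3 rule is dropped if some 2-feature subset admits a
    valid rule for the same class.  Exact duplicates (same features, same
    bounds, same class) collapse to one entry with merged provenance.
    """
    separators = single_feature_separators(m)
    values = m.values.loc[sorted(m.feature_ids)].to_numpy(dtype=float)
    order = {f: i for i, f in enumerate(sorted(m.feature_ids))}
    views = {c: _ClassView(values, m.class_mask(c)) for c in m.classes}

    kept: dict = {}
    for rule in rules:
        if any(f in separators for f in rule.feature_ids):
            continue
        if rule.arity == 3:
            view = views[rule.target_class]
            idx = [order[f] for f in rule.feature_ids]
            if any(
                _pair_admits_rule(view, pair)
                for pair in itertools.combinations(idx, 2)
            ):
                continue
        key = rule.key()
        if key in kept:
            prev = kept[key]
            prov = prev.provenance
            if prov.get("method") != rule.provenance.get("method"):
                merged = dict(prov)
                merged["method"] = "+".join(
                    sorted({prov.get("method", "?"), rule.provenance.get("method", "?")})
                )
                merged["merged_from"] = [prov, rule.provenance]
                prev.provenance = merged
        else:
            kept[key] = rule
    return list(kept.values())


def pool_rules(committee_rules: list, exhaustive_rules: list, m: ExpressionMatrix) -> list:
    """Pool committee-harvested and exhaustively mined rules, minimally filtered."""
    return minimality_filter(list(committee_rules) + list(exhaustive_rules), m)
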