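import itertools
import math

import numpy as np
import pytest

import mirule as mr
from mirule.matrix import ExpressionError

from conftest import make_matrix


def brute_force_rules(m, arity):
    """Independent oracle: plain-Python loops over feature subsets,
    orientation vectors and target classes; bounds at the target-class
    extremes (the tightest grid values that cover the class)."""
    found = set()
    classes = sorted(m.classes)
    samples = {
        c: [
            {f: m.values.at[f, s] for f in m.feature_ids}
            for s in m.sample_ids
            if m.labels[s] == c
        ]
        for c in classes
    }
    for feats in itertools.combinations(sorted(m.feature_ids), arity):
        for orient in itertools.product(("le", "ge"), repeat=arity):
            for target in classes:
                other = [c for c in classes if c != target][0]
                bounds = []
                for f, o in zip(feats, orient):
                    vals = [s[f] for s in samples[target]]
                    bounds.append(max(vals) if o == "le" else min(vals))

                def inside(sample):
                    ok = True
                    for f, o, b in zip(feats, orient, bounds):
                        if o == "le" and not sample[f] <= b:
                            ok = False
                        if o == "ge" and not sample[f] >= b:
                            ok = False
                    return ok

                if all(inside(s) for s in samples[target]) and not any(
                    inside(s) for s in samples[other]
                ):
                    found.add((feats, orient, target, tuple(bounds)))
    return found


def rule_signature(rule):
    feats, orient, bounds = [], [], []
    for c in rule.conjuncts:
        feats.append(c.feature_id)
        if math.isinf(c.lower):
            orient.append("le")
            bounds.append(c.upper)
        else:
            orient.append("ge")
            bounds.append(c.lower)
    return tuple(feats), tuple(orient), rule.target_class, tuple(bounds)


class TestExhaustiveSearch:
    def test_corner_example_single_normal_rule(self):
        # cancer at (5,1) and (1,5); normal at (2,2) and (6,6): only the
        # lower-left-excluding corner x1>=2 & x2>=2 isolates the normals
        m = make_matrix(
            [[5, 1, 2, 6], [1, 5, 2, 6]],
            ["cancer", "cancer", "normal", "normal"],
            feature_ids=["x1", "x2"],
        )
        rules = mr.exhaustive_search(m, 2, bound_style="extreme")
        assert len(rules) == 1
        rule = rules[0]
        assert rule.target_class == "normal"
        sig = rule_signature(rule)
        assert sig == (("x1", "x2"), ("ge", "ge"), "normal", (2.0, 2.0))

    def test_corner_example_midpoint_bounds(self):
        m = make_matrix(
            [[5, 1, 2, 6], [1, 5, 2, 6]],
            ["cancer", "cancer", "normal", "normal"],
            feature_ids=["x1", "x2"],
        )
        (rule,) = mr.exhaustive_search(m, 2, bound_style="midpoint")
        # nearest excluded cancer value below the normal minimum of 2 is 1
        assert rule_signature(rule)[3] == (1.5, 1.5)

    def test_rules_are_one_sided(self, planted_pair_and_triple_matrix):
        m, _ = planted_pair_and_triple_matrix
        for arity in (2, 3):
            for rule in mr.exhaustive_search(m, arity):
                for c in rule.conjuncts:
                    assert c.one_sided

    def test_every_rule_revalidates(self, planted_pair_and_triple_matrix):
        m, _ = planted_pair_and_triple_matrix
        for arity in (2, 3):
            for rule in mr.exhaustive_search(m, arity):
                assert mr.is_frequency_rule(rule, m)["valid"]

    def test_matches_grid_brute_force_oracle(self):
        """Exact agreement with grid enumeration on <= 12 samples x 6 features."""
        rng = np.random.default_rng(17)
        for trial in range(8):
            n1, n2 = int(rng.integers(3, 6)), int(rng.integers(4, 8))
            vals = np.round(rng.normal(8, 1, (6, n1 + n2)), 2)
            m = make_matrix(vals, ["A"] * n1 + ["B"] * n2)
            for arity in (2, 3):
                got = {
                    rule_signature(r)
                    for r in mr.exhaustive_search(
                        m, arity, bound_style="extreme", minimal=False
                    )
                }
                assert got == brute_force_rules(m, arity)

    def test_invalid_arity_rejected(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        with pytest.raises(ExpressionError):
            mr.exhaustive_search(m, 4)

    def test_max_features_caps_search_space(self, planted_pair_matrix):
        m, truth = planted_pair_matrix
        rules = mr.exhaustive_search(m, 2, max_features=4)
        used = {f for r in rules for f in r.feature_ids}
        # planted features dominate the gain-ratio ranking, so they survive the cap
        assert set(truth["planted"][0]["features"]) <= used or not rules

    def test_widening_monotonicity(self, planted_pair_matrix):
        """Widening a finite bound keeps full target coverage and first
        admits other-class samples only past the nearest excluded value."""
        m, _ = planted_pair_matrix
        (rule, *_) = sorted(
            mr.exhaustive_search(m, 2, bound_style="extreme"),
            key=lambda r: r.feature_ids,
        )
        n_target = m.class_size(rule.target_class)
        for i, c in enumerate(rule.conjuncts):
            for delta in (0.0, 0.01, 0.1):
                if math.isinf(c.lower):
                    widened = mr.Conjunct(c.feature_id, upper=c.upper + delta)
                else:
                    widened = mr.Conjunct(c.feature_id, lower=c.lower - delta)
                conjs = list(rule.conjuncts)
                conjs[i] = widened
                chk = mr.is_frequency_rule(
                    mr.ConjunctiveRule(tuple(conjs), rule.target_class), m
                )
                assert chk["covered_target"] == n_target


class TestMinimality:
    def test_separating_feature_excludes_its_pairs(self):
        # f1 alone separates; f2/f3 only jointly
        m = make_matrix(
            [[1, 2, 9, 8], [5, 1, 5.5, 0.5], [1, 5, 0.5, 5.5]],
            ["A", "A", "B", "B"],
            feature_ids=["f1", "f2", "f3"],
        )
        rules = mr.exhaustive_search(m, 2)
        assert all("f1" not in r.feature_ids for r in rules)

    def test_pair_subset_excludes_triples(self, planted_pair_matrix):
        m, truth = planted_pair_matrix
        planted = set(truth["planted"][0]["features"])
        target = truth["planted"][0]["target_class"]
        triples = mr.exhaustive_search(m, 3)
        for r in triples:
            if r.target_class == target:
                assert not planted <= set(r.feature_ids)

    def test_no_subset_rules_filter_is_identity(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        pairs = mr.exhaustive_search(m, 2)
        assert mr.minimality_filter(pairs, m) == pairs

    def test_pooled_duplicates_merge_provenance(self, planted_pair_matrix):
        m, truth = planted_pair_matrix
        planted = truth["planted"][0]["features"]
        committee = mr.build_committee(m, planted + ["null_001", "null_002"])
        committee_rules = mr.harvest_rules(committee, m)
        exhaustive_rules = mr.exhaustive_search(m, 2)
        pooled = mr.pool_rules(committee_rules, exhaustive_rules, m)
        keys = [r.key() for r in pooled]
        assert len(keys) == len(set(keys))
        shared = [
            r for r in pooled if "+" in r.provenance.get("method", "")
        ]
        # committee thresholds and exhaustive midpoint bounds share the same
        # dialect, so the planted rule is found by both routes and merged
        assert any(set(r.feature_ids) == set(planted) for r in shared)
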