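"""Model/Results front end for the whole rule-discovery workflow.

``RuleDiscovery`` is configured from a two-class expression matrix;
``fit()`` runs gain-ratio ranking, biomarker projection, the decision-tree
committee, the exhaustive interval-rule search and Max-Min distance
separation, and returns a :class:`RuleDiscoveryResults` carrying the
ranked features, the committee, the pooled rules, the separation table
and a ``summary()`` report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .committee import Committee, build_committee, harvest_rules
from .matrix import ExpressionMatrix, ExpressionError, read_expression_table
from .ranking import RankedFeature, project_biomarkers, rank_features
from .search import exhaustive_search, pool_rules
from .separation import SeparationResult, rank_rules_by_separation
from .evaluation import PipelineConfig, cross_validate


class RuleDiscovery:
    """Discover 2-/3-feature 100%-frequency interval rules in a two-class matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Normalized features x samples matrix with binary labels.
    biomarkers : iterable of str, optional
        Externally confirmed feature ids; the candidate set for the tree
        committee is the ranked prefix through their worst rank.  When
        omitted, ``top_n`` (or all features) defines the candidates.
    arities : tuple
        Rule sizes to mine (subset of {2, 3}).
    bound_style : str
        ``midpoint`` or ``extreme`` placement of finite rule bounds.
    scale : str
        ``none`` or ``minmax`` feature scaling for separation distances.
    exhaustive_max_features : int, optional
        Cap the exhaustive search to the top gain-ratio features for very
        wide matrices.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        biomarkers=None,
        top_n: int | None = None,
        arities=(2, 3),
        bound_style: str = "midpoint",
        scale: str = "none",
        min_leaf: int = 2,
        gain_mean_filter: bool = True,
        exhaustive_max_features: int | None = None,
    ):
        self.matrix = matrix
        self.biomarkers = tuple(biomarkers) if biomarkers else None
        self.top_n = top_n
        self.arities = tuple(sorted(set(arities)))
        if any(a not in (2, 3) for a in self.arities):
            raise ExpressionError("arities must be a subset of {2, 3}")
        self.bound_style = bound_style
        self.scale = scale
        self.min_leaf = min_leaf
        self.gain_mean_filter = gain_mean_filter
        self.exhaustive_max_features = exhaustive_max_features

    @classmethod
    def from_files(
        cls, matrix_path, labels_path, orientation="features_in_rows", **kwargs
    ) -> "RuleDiscovery":
        m = read_expression_table(matrix_path, labels_path, orientation=orientation)
        return cls(m, **kwargs)

    def as_pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            biomarker_ids=self.biomarkers,
            top_n=self.top_n,
            arities=self.arities,
            bound_style=self.bound_style,
            min_leaf=self.min_leaf,
            gain_mean_filter=self.gain_mean_filter,
            exhaustive_max_features=self.exhaustive_max_features,
        )

    def fit(self) -> "RuleDiscoveryResults":
        m = self.matrix
        ranked = rank_features(m)
        if self.biomarkers:
            candidates = project_biomarkers(ranked, self.biomarkers)
        elif self.top_n:
            candidates = [r.feature_id for r in ranked[: self.top_n]]
        else:
            candidates = [r.feature_id for r in ranked]

        committee = Committee()
        committee_rules: list = []
        if len(candidates) >= 2:
            committee = build_committee(
                m, candidates, min_leaf=self.min_leaf,
                gain_mean_filter=self.gain_mean_filter,
            )
            committee_rules = harvest_rules(committee, m, arity_range=self.arities)

        exhaustive_rules: list = []
        for arity in self.arities:
            exhaustive_rules.extend(
                exhaustive_search(
                    m, arity, bound_style=self.bound_style,
                    max_features=self.exhaustive_max_features,
                )
            )
        rules = pool_rules(committee_rules, exhaustive_rules, m)
        separation = rank_rules_by_separation(rules, m, scale=self.scale)
        return RuleDiscoveryResults(
            model=self,
            ranked_features=ranked,
            candidate_features=candidates,
            committee=committee,
            rules=rules,
            separation=separation,
        )


@dataclass
class RuleDiscoveryResults:
    """Fitted output: ranked features, committee, rules, Max-Min table."""

    model: RuleDiscovery
    ranked_features: list
    candidate_features: list
    committee: Committee
    rules: list
    separation: list

    @property
    def selected_rules(self) -> list:
        return [s for s in self.separation if s.selected]

    @property
    def best_rule(self) -> SeparationResult | None:
        if not self.separation:
            return None
        return max(self.separation, key=lambda s: (s.min_distance, -s.rule.arity))

    def ranking_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": r.rank,
                    "feature_id": r.feature_id,
                    "gain_ratio": r.gain_ratio,
                    "pvalue": r.pvalue,
                }
                for r in self.ranked_features
            ]
        ).set_index("rank")

    def separation_frame(self) -> pd.DataFrame:
        """Table-style view: one row per rule with margin, rank and selection."""
        rows = [
            {
                "arity": s.rule.arity,
                "features": " + ".join(s.rule.feature_ids),
                "class": s.rule.target_class,
                "min_distance": s.min_distance,
                "rank": f"{s.rule.arity}D.{s.rank}",
                "selected": s.selected,
                "rule": s.rule.describe(),
            }
            for s in sorted(self.separation, key=lambda s: (s.rule.arity, s.rank))
        ]
        return pd.DataFrame(rows)

    def cross_validate_best(self, k: int = 10, seed: int = 0, classifier: str = "c45"):
        best = self.best_rule
        if best is None:
            raise ExpressionError("no rules discovered; nothing to cross-validate")
        return cross_validate(
            self.model.matrix, best.rule.feature_ids, k=k, seed=seed,
            classifier=classifier,
        )

    def summary(self) -> str:
        m = self.model.matrix
        a, b = m.classes
        lines = [
            "Rule discovery by gain-ratio tree committee + exhaustive interval search",
            "=" * 72,
            f"Samples: {m.n_samples}  ({a}: {m.class_size(a)}, {b}: {m.class_size(b)})"
            f"    Features: {m.n_features}  [{m.normalization}]",
            f"Candidate features for committee: {len(self.candidate_features)}"
            + (
                f" (projection of {len(self.model.biomarkers)} biomarkers)"
                if self.model.biomarkers
                else ""
            ),
            f"Committee trees: {len(self.committee)}"
            f"    100%-frequency rules (pooled, minimal): {len(self.rules)}",
            "",
            "Max-Min distance separation",
            "-" * 72,
        ]
        frame = self.separation_frame()
        if frame.empty:
            lines.append("(no rules discovered)")
        else:
            for _, row in frame.iterrows():
                mark = "*" if row["selected"] else " "
                lines.append(
                    f" {mark} {row['rank']:>5}  d={row['min_distance']:.4f}  {row['rule']}"
                )
            lines.append("")
            lines.append("* = selected (top ceil(k/3) of each arity stratum)")
        return "\n".join(lines)
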