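"""Synthetic two-class expression matrices with planted axis-separable signals.

The generator emulates the small-n, imbalanced regime of tissue miRNA
profiling studies (default 10 control vs 61 disease samples) on a
post-log2 intensity scale: null features are i.i.d. Gaussian around a
common baseline, and each planted 2- or 3-feature group places the two
classes in disjoint axis-aligned regions whose one-sided boundaries are
``margin`` apart, so the true minimum inter-class Euclidean distance in
the planted subspace is bounded below by the margin.

Within a planted group the non-target class cycles which axis it
violates, so no single planted feature separates the classes on its own —
the joint 2D/3D rule is required, as in real multi-miRNA signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ExpressionError


@dataclass(frozen=True)
class PlantedGroup:
    """One planted 2- or 3-feature axis-separable signal.

    ``orientations[j]`` is the side of the boundary on which the *target*
    class sits for feature j: ``"le"`` (below) or ``"ge"`` (above).
    """

    features: tuple
    orientations: tuple
    margin: float
    target_class: str

    def __post_init__(self):
        if len(self.features) not in (2, 3):
            raise ExpressionError("planted group needs 2 or 3 features")
        if len(self.orientations) != len(self.features):
            raise ExpressionError("one orientation per planted feature required")
        if any(o not in ("le", "ge") for o in self.orientations):
            raise ExpressionError("orientations must be 'le' or 'ge'")
        if not self.margin > 0:
            raise ExpressionError("planted margin must be > 0")


@dataclass
class SyntheticSpec:
    """Study-condition parameters of the generator (defaults mirror the
    10-normal vs 61-cancer tissue regime on a log2 intensity scale)."""

    n_class1: int = 10
    n_class2: int = 61
    class_names: tuple = ("normal", "cancer")
    n_null_features: int = 20
    planted: list = field(default_factory=list)
    noise_sd: float = 0.5
    base_mean: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_class1 < 2 or self.n_class2 < 2:
            raise ExpressionError("each class needs at least 2 samples")
        if self.noise_sd <= 0:
            raise ExpressionError("noise_sd must be > 0")
        ids = [f for g in self.planted for f in g.features]
        if len(ids) != len(set(ids)):
            raise ExpressionError("planted feature ids must be unique across groups")
        for g in self.planted:
            if g.target_class not in self.class_names:
                raise ExpressionError(
                    f"planted target {g.target_class!r} not in {self.class_names}"
                )
            n_other = (
                self.n_class2 if g.target_class == self.class_names[0] else self.n_class1
            )
            if n_other < len(g.features):
                raise ExpressionError(
                    "non-target class too small to violate every planted axis"
                )


def default_planted_pair(
    target_class: str = "normal",
    margin: float = 2.5,
    features: tuple = ("planted_p1", "planted_p2"),
    orientations: tuple = ("le", "le"),
) -> PlantedGroup:
    return PlantedGroup(features, orientations, margin, target_class)


def default_planted_triple(
    target_class: str = "cancer",
    margin: float = 2.5,
    features: tuple = ("planted_t1", "planted_t2", "planted_t3"),
    orientations: tuple = ("ge", "le", "ge"),
) -> PlantedGroup:
    return PlantedGroup(features, orientations, margin, target_class)


def generate_dataset(spec: SyntheticSpec):
    """Generate a matrix plus ground truth for the given spec.

    Returns ``(matrix, truth)`` where truth lists each planted group's
    features, orientations, boundary positions, margin and target class.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_class1, spec.n_class2
    n = n1 + n2
    c1, c2 = spec.class_names
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    labels = pd.Series([c1] * n1 + [c2] * n2, index=sample_ids)

    rows, feature_ids = [], []
    truth = {"planted": [], "n_null_features": spec.n_null_features}

    for group in spec.planted:
        arity = len(group.features)
        target_idx = np.arange(n1) if group.target_class == c1 else np.arange(n1, n)
        other_idx = np.setdiff1d(np.arange(n), target_idx)
        # each non-target sample violates exactly one planted axis (cycling)
        violated_axis = np.arange(len(other_idx)) % arity
        boundaries = []
        for j, (fid, orient) in enumerate(zip(group.features, group.orientations)):
            t = spec.base_mean
            boundaries.append(t)
            row = np.empty(n)
            sign = -1.0 if orient == "le" else 1.0
            # target class sits on its side of the boundary
            row[target_idx] = t + sign * np.abs(rng.normal(0, spec.noise_sd, n1 if group.target_class == c1 else n2))
            inside = t + sign * np.abs(rng.normal(0, spec.noise_sd, len(other_idx)))
            outside = t - sign * (
                group.margin + np.abs(rng.normal(0, spec.noise_sd, len(other_idx)))
            )
            row[other_idx] = np.where(violated_axis == j, outside, inside)
            rows.append(row)
            feature_ids.append(fid)
        truth["planted"].append(
            {
                "features": list(group.features),
                "orientations": list(group.orientations),
                "boundaries": boundaries,
                "margin": group.margin,
                "target_class": group.target_class,
            }
        )

    for k in range(spec.n_null_features):
        rows.append(rng.normal(spec.base_mean, spec.noise_sd, n))
        feature_ids.append(f"null_{k + 1:03d}")

    if not rows:
        raise ExpressionError("spec generates no features")
    values = pd.DataFrame(np.vstack(rows), index=feature_ids, columns=sample_ids)
    matrix = ExpressionMatrix(values, labels, normalization="quantile_log2")
    return matrix, truth


def generate_null_dataset(
    n1: int,
    n2: int,
    n_features: int,
    seed: int,
    class_names: tuple = ("normal", "cancer"),
    base_mean: float = 8.0,
    noise_sd: float = 0.5,
) -> ExpressionMatrix:
    """All-noise matrix: every feature i.i.d. Gaussian, labels carry no signal."""
    if n1 < 2 or n2 < 2 or n_features < 1:
        raise ExpressionError("need >=2 samples per class and >=1 feature")
    rng = np.random.default_rng(seed)
    n = n1 + n2
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    labels = pd.Series([class_names[0]] * n1 + [class_names[1]] * n2, index=sample_ids)
    values = pd.DataFrame(
        rng.normal(base_mean, noise_sd, size=(n_features, n)),
        index=[f"f{k + 1:03d}" for k in range(n_features)],
        columns=sample_ids,
    )
    return ExpressionMatrix(values, labels, normalization="quantile_log2")


def generate_informative_dataset(
    n1: int,
    n2: int,
    n_features: int,
    seed: int,
    shift: float = 2.0,
    class_names: tuple = ("normal", "cancer"),
    base_mean: float = 8.0,
    noise_sd: float = 0.4,
) -> ExpressionMatrix:
    """Matrix in which every feature carries a between-class mean shift.

    Useful for exercising the committee: each feature has positive
    information gain, so every induced tree has a root split and iterative
    root removal runs the full n_features - 1 rounds.
    """
    if n1 < 2 or n2 < 2 or n_features < 2:
        raise ExpressionError("need >=2 samples per class and >=2 features")
    rng = np.random.default_rng(seed)
    n = n1 + n2
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    labels = pd.Series([class_names[0]] * n1 + [class_names[1]] * n2, index=sample_ids)
    rows = []
    for k in range(n_features):
        direction = 1.0 if k % 2 == 0 else -1.0
        mu1 = base_mean - direction * shift / 2
        mu2 = base_mean + direction * shift / 2
        row = np.concatenate(
            [rng.normal(mu1, noise_sd, n1), rng.normal(mu2, noise_sd, n2)]
        )
        rows.append(row)
    values = pd.DataFrame(
        np.vstack(rows),
        index=[f"f{k + 1:03d}" for k in range(n_features)],
        columns=sample_ids,
    )
    return ExpressionMatrix(values, labels, normalization="quantile_log2")
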