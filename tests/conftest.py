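import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mirule as mr

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, labels, feature_ids=None, sample_ids=None, normalization="quantile_log2"):
    """Build a small ExpressionMatrix from plain lists (features x samples)."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"f{i + 1}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samp)]
    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    lab = pd.Series(list(labels), index=sample_ids)
    return mr.ExpressionMatrix(df, lab, normalization)


@pytest.fixture
def planted_pair_matrix():
    """10 vs 30 samples, one planted normal-targeting pair among 10 nulls."""
    spec = mr.SyntheticSpec(
        n_class1=10,
        n_class2=30,
        n_null_features=10,
        planted=[mr.default_planted_pair()],
        noise_sd=0.5,
        seed=11,
    )
    matrix, truth = mr.generate_dataset(spec)
    return matrix, truth


def make_corner_dataset(n1=10, n2=30, n_nulls=6, seed=0):
    """Two-class matrix whose target class sits in a bounded corner box with a
    wide clear gap (3 units) to every violating coordinate, so interval rules
    learned on any training subset generalize perfectly to held-out samples.

    Returns (matrix, planted_feature_ids).  'normal' samples have both planted
    coordinates in [7.0, 7.5]; each 'cancer' sample violates exactly one axis
    (coordinate in [10.5, 11.0]) and sits below the normal range ([5.0, 5.5])
    on the other, so neither feature separates alone and no other-class value
    interleaves with the normal range on any axis.
    """
    rng = np.random.default_rng(seed)
    n = n1 + n2
    def normal_range(size):
        return 7.25 + rng.uniform(-0.25, 0.25, size)
    def inside(size):  # non-violating cancer coords: below the normals
        return 5.25 + rng.uniform(-0.25, 0.25, size)
    def outside(size):
        return 10.75 + rng.uniform(-0.25, 0.25, size)
    p1 = np.empty(n)
    p2 = np.empty(n)
    p1[:n1] = normal_range(n1)
    p2[:n1] = normal_range(n1)
    violate_first = np.arange(n2) % 2 == 0
    p1[n1:] = np.where(violate_first, outside(n2), inside(n2))
    p2[n1:] = np.where(violate_first, inside(n2), outside(n2))
    rows = [p1, p2] + [rng.normal(8.0, 0.5, n) for _ in range(n_nulls)]
    feature_ids = ["planted_p1", "planted_p2"] + [
        f"null_{k + 1:03d}" for k in range(n_nulls)
    ]
    m = make_matrix(rows, ["normal"] * n1 + ["cancer"] * n2, feature_ids=feature_ids)
    return m, ["planted_p1", "planted_p2"]


@pytest.fixture
def planted_pair_and_triple_matrix():
    spec = mr.SyntheticSpec(
        n_class1=10,
        n_class2=30,
        n_null_features=15,
        planted=[mr.default_planted_pair(), mr.default_planted_triple()],
        noise_sd=0.5,
        seed=7,
    )
    matrix, truth = mr.generate_dataset(spec)
    return matrix, truth
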