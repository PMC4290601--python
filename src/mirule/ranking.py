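"""Gain-ratio feature ranking and biomarker projection.

The gain ratio of a continuous feature is the best, over all candidate
binary thresholds, of information gain divided by the entropy of the
left/right partition sizes.  Ranking the features by this score and then
truncating the list at the worst rank attained by a set of externally
confirmed biomarkers ("projection") yields the candidate set used for
rule discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._splits import GAIN_TOL, split_scan
from .matrix import ExpressionMatrix, ExpressionError


@dataclass(frozen=True)
class RankedFeature:
    feature_id: str
    gain_ratio: float
    rank: int
    pvalue: float | None = None


def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ExpressionError(
            f"gain ratio needs exactly 2 classes, found {len(classes)}"
        )
    return (labels == classes[1]).astype(np.int64)


def gain_ratio(values, labels, threshold_style: str = "midpoint") -> float:
    """Maximum gain ratio of a single continuous feature over a binary split.

    Returns 0 when the feature is constant or no threshold has positive
    information gain.  The result is always in [0, 1].
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ExpressionError("gain ratio needs at least 2 samples")
    y = _encode_labels(labels)
    _, gains, split_infos, _ = split_scan(values, y, threshold_style)
    ok = gains > GAIN_TOL
    if not ok.any():
        return 0.0
    ratios = gains[ok] / split_infos[ok]
    return float(ratios.max())


def rank_features(
    m: ExpressionMatrix,
    threshold_style: str = "midpoint",
    with_pvalues: bool = False,
    pvalue_test: str = "welch_t",
) -> list[RankedFeature]:
    """Rank all features by gain ratio, descending; ties broken by feature id."""
    y = _encode_labels(m.label_array())
    arr = m.values.to_numpy(dtype=float)
    scores = []
    for i, fid in enumerate(m.feature_ids):
        _, gains, split_infos, _ = split_scan(arr[i], y, threshold_style)
        ok = gains > GAIN_TOL
        gr = float((gains[ok] / split_infos[ok]).max()) if ok.any() else 0.0
        scores.append((fid, gr))
    scores.sort(key=lambda t: (-t[1], t[0]))
    out = []
    for rank, (fid, gr) in enumerate(scores, start=1):
        pv = (
            diff_expression_pvalue(m.feature_values(fid), m.label_array(), pvalue_test)
            if with_pvalues
            else None
        )
        out.append(RankedFeature(feature_id=fid, gain_ratio=gr, rank=rank, pvalue=pv))
    return out


def project_biomarkers(ranked: list[RankedFeature], biomarker_ids) -> list[str]:
    """Prefix of the ranked list through the worst rank of any given biomarker."""
    biomarker_ids = set(biomarker_ids)
    by_id = {r.feature_id: r.rank for r in ranked}
    missing = sorted(b for b in biomarker_ids if b not in by_id)
    if missing:
        raise ExpressionError(f"biomarker(s) absent from matrix: {missing}")
    worst = max(by_id[b] for b in biomarker_ids)
    ordered = sorted(ranked, key=lambda r: r.rank)
    return [r.feature_id for r in ordered[:worst]]


def diff_expression_pvalue(values, labels, test: str = "welch_t") -> float:
    """Two-sided differential-expression p-value for one feature.

    ``welch_t`` (default) or ``wilcoxon`` (rank-sum).  A feature constant
    across both classes returns p = 1 (no evidence of difference).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ExpressionError("p-value needs exactly 2 classes")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ExpressionError("p-value needs at least 2 samples per class")
    if np.ptp(values) == 0:
        return 1.0
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p
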