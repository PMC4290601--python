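"""Shared binary-split scan for continuous attributes (gain / gain ratio).

All entropies are in bits.  Candidate thresholds are either the midpoints
of consecutive distinct sorted values (the Weka/J48 dialect) or the lower
of the two values (the classic data-value dialect).
"""

from __future__ import annotations

import numpy as np

GAIN_TOL = 1e-12


def binary_entropy(k: np.ndarray | float, n: np.ndarray | float) -> np.ndarray:
    """Entropy in bits of a two-way partition with ``k`` of ``n`` in one part."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, k / np.maximum(n, 1), 0.0)
        h = -np.where((p > 0) & (p < 1), p * np.log2(np.clip(p, 1e-300, 1)), 0.0)
        q = 1.0 - p
        h -= np.where((q > 0) & (q < 1), q * np.log2(np.clip(q, 1e-300, 1)), 0.0)
    return h


def split_scan(values: np.ndarray, y: np.ndarray, threshold_style: str = "midpoint"):
    """Score every candidate binary threshold of one continuous attribute.

    Parameters
    ----------
    values : 1-d float array
    y : 1-d 0/1 int array (class indicator)
    threshold_style : ``midpoint`` or ``data_value``

    Returns
    -------
    thresholds, gains, split_infos, left_sizes : aligned 1-d arrays
        One entry per boundary between consecutive distinct sorted values.
        Empty arrays if the attribute is constant.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y)
    n = len(values)
    order = np.argsort(values, kind="stable")
    v = values[order]
    ys = y[order]
    distinct = np.nonzero(v[1:] > v[:-1])[0] + 1  # left partition sizes
    if distinct.size == 0:
        empty = np.empty(0)
        return empty, empty, empty, empty.astype(int)
    if threshold_style == "midpoint":
        thresholds = (v[distinct - 1] + v[distinct]) / 2.0
    elif threshold_style == "data_value":
        thresholds = v[distinct - 1]
    else:
        raise ValueError(f"unknown threshold_style {threshold_style!r}")
    cum1 = np.cumsum(ys)
    n1 = cum1[-1]
    left_n = distinct
    left_1 = cum1[distinct - 1]
    right_n = n - left_n
    right_1 = n1 - left_1
    h_parent = binary_entropy(n1, n)
    h_children = (
        left_n * binary_entropy(left_1, left_n)
        + right_n * binary_entropy(right_1, right_n)
    ) / n
    gains = h_parent - h_children
    split_infos = binary_entropy(left_n, n)
    return thresholds, gains, split_infos, left_n
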