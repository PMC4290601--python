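"""Scatter plots of rule subspaces with interval boundaries (presentation aid)."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .matrix import ExpressionMatrix, ExpressionError
from .rules import ConjunctiveRule


def plot_rule(m: ExpressionMatrix, rule: ConjunctiveRule, ax=None, path=None):
    """2D (or 3D) scatter of both classes in the rule's feature subspace,
    with the finite rule bounds drawn as dashed lines/planes."""
    feats = rule.feature_ids
    arr = m.values.loc[list(feats)].to_numpy(dtype=float)
    a, b = m.classes
    mask = m.class_mask(a)
    if rule.arity == 2:
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(arr[0, mask], arr[1, mask], c="tab:blue", label=a, s=25)
        ax.scatter(arr[0, ~mask], arr[1, ~mask], c="tab:red", label=b, s=25, marker="x")
        for i, conj in enumerate(rule.conjuncts):
            for bound in (conj.lower, conj.upper):
                if math.isfinite(bound):
                    (ax.axvline if i == 0 else ax.axhline)(
                        bound, ls="--", c="gray", lw=1
                    )
        ax.set_xlabel(feats[0])
        ax.set_ylabel(feats[1])
    else:
        fig = plt.gcf() if ax is not None else plt.figure(figsize=(5, 4))
        ax = fig.add_subplot(projection="3d")
        ax.scatter(arr[0, mask], arr[1, mask], arr[2, mask], c="tab:blue", label=a)
        ax.scatter(
            arr[0, ~mask], arr[1, ~mask], arr[2, ~mask], c="tab:red", label=b, marker="x"
        )
        ax.set_xlabel(feats[0])
        ax.set_ylabel(feats[1])
        ax.set_zlabel(feats[2])
    ax.set_title(rule.describe(), fontsize=8)
    ax.legend(fontsize=8)
    if path is not None:
        plt.savefig(path, dpi=120, bbox_inches="tight")
        plt.close()
    return ax
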