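"""Validation machinery: stratified k-fold CV, random-feature AUC null,
label-permutation resampling, and the 5-fold training-test protocol.

Three thin baseline classifiers are provided — the package's gain-ratio
tree (``c45``), 1-nearest-neighbour (``knn1``) and Gaussian naive Bayes
(``naive_bayes``) — all scored with the Mann-Whitney rank AUC (tie
corrected), so comparisons are threshold-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .committee import build_committee, harvest_rules
from .matrix import ExpressionMatrix, ExpressionError
from .ranking import project_biomarkers, rank_features
from .search import exhaustive_search, pool_rules
from .separation import rank_rules_by_separation
from .tree import build_tree

CLASSIFIERS = ("c45", "knn1", "naive_bayes")


@dataclass
class EvalReport:
    sensitivity: float
    specificity: float
    accuracy: float
    f_measure: float
    roc_area: float
    per_fold: list
    positive_class: str
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NullDistribution:
    draws: int
    statistic_values: list
    thresholds_table: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "draws": self.draws,
            "statistic_values": list(self.statistic_values),
            "thresholds_table": {str(k): v for k, v in self.thresholds_table.items()},
            "seed": self.seed,
        }


def mann_whitney_auc(scores, y_true) -> float:
    """AUC via the rank-sum formula with average-rank tie correction."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(bool)
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise ExpressionError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[y_true].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# -- baseline classifiers ----------------------------------------------


def _fit_predict_c45(Xtr, ytr, Xte, positive, classes, params):
    import pandas as pd

    feats = [f"f{i}" for i in range(Xtr.shape[1])]
    values = pd.DataFrame(Xtr.T, index=feats)
    labels = pd.Series(ytr, index=values.columns)
    m = ExpressionMatrix(values, labels, normalization="quantile_log2")
    tree = build_tree(m, feats, **params)
    labs, scores = [], []
    for row in Xte:
        lab, sc = tree.classify(dict(zip(feats, row)), positive)
        labs.append(lab)
        scores.append(sc)
    return np.array(labs), np.array(scores)


def _fit_predict_knn1(Xtr, ytr, Xte, positive, classes, params):
    from scipy.spatial.distance import cdist

    d = cdist(Xte, Xtr)
    nearest = d.argmin(axis=1)
    labs = ytr[nearest]
    pos_mask = ytr == positive
    d_pos = d[:, pos_mask].min(axis=1)
    d_neg = d[:, ~pos_mask].min(axis=1)
    denom = d_pos + d_neg
    denom[denom == 0] = 1.0
    scores = d_neg / denom  # closer to a positive -> higher score
    return labs, scores


def _fit_predict_nb(Xtr, ytr, Xte, positive, classes, params):
    eps = 1e-9 * max(1.0, float(np.var(Xtr)))
    log_post = np.zeros((len(Xte), 2))
    for k, c in enumerate(classes):
        Xc = Xtr[ytr == c]
        mu = Xc.mean(axis=0)
        var = Xc.var(axis=0) + eps
        log_lik = -0.5 * (np.log(2 * np.pi * var) + (Xte - mu) ** 2 / var).sum(axis=1)
        log_post[:, k] = log_lik + np.log(len(Xc) / len(Xtr))
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    pos_col = classes.index(positive)
    labs = np.array([classes[i] for i in post.argmax(axis=1)])
    return labs, post[:, pos_col]


_FITTERS = {"c45": _fit_predict_c45, "knn1": _fit_predict_knn1, "naive_bayes": _fit_predict_nb}


def _confusion_metrics(y_true, y_pred, positive) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == positive) & (y_pred == positive)).sum())
    fn = int(((y_true == positive) & (y_pred != positive)).sum())
    tn = int(((y_true != positive) & (y_pred != positive)).sum())
    fp = int(((y_true != positive) & (y_pred == positive)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(y_true)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": sens, "specificity": spec, "accuracy": acc, "f_measure": f1,
    }


def cross_validate(
    m: ExpressionMatrix,
    features,
    k: int,
    seed: int,
    classifier: str = "c45",
    positive_class: str | None = None,
    tree_params: dict | None = None,
) -> EvalReport:
    """Stratified k-fold CV of one feature subset with a baseline classifier.

    Pooled confusion metrics over all folds; roc_area is the mean of the
    per-fold Mann-Whitney AUCs (folds lacking a class are excluded from
    the AUC mean).
    """
    if classifier not in CLASSIFIERS:
        raise ExpressionError(f"unknown classifier {classifier!r}")
    features = list(features)
    missing = [f for f in features if f not in m.values.index]
    if missing:
        raise ExpressionError(f"unknown feature(s): {missing}")
    if k < 2 or k > m.n_samples:
        raise ExpressionError(f"k={k} incompatible with {m.n_samples} samples")
    classes = list(m.classes)
    positive = positive_class or classes[0]
    if positive not in classes:
        raise ExpressionError(f"unknown positive class {positive!r}")
    X = m.values.loc[features].to_numpy(dtype=float).T
    y = m.label_array()
    fitter = _FITTERS[classifier]
    params = tree_params or {}

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    pooled_true, pooled_pred = [], []
    aucs = []
    for tr, te in skf.split(X, y):
        labs, scores = fitter(X[tr], y[tr], X[te], positive, classes, params)
        fold = _confusion_metrics(y[te], labs, positive)
        y_bin = y[te] == positive
        if 0 < y_bin.sum() < len(y_bin):
            fold["roc_area"] = mann_whitney_auc(scores, y_bin)
            aucs.append(fold["roc_area"])
        else:
            fold["roc_area"] = float("nan")
        per_fold.append(fold)
        pooled_true.extend(y[te])
        pooled_pred.extend(labs)
    pooled = _confusion_metrics(pooled_true, pooled_pred, positive)
    return EvalReport(
        sensitivity=pooled["sensitivity"],
        specificity=pooled["specificity"],
        accuracy=pooled["accuracy"],
        f_measure=pooled["f_measure"],
        roc_area=float(np.mean(aucs)) if aucs else float("nan"),
        per_fold=per_fold,
        positive_class=positive,
        seed=seed,
    )


def randomization_test(
    m: ExpressionMatrix,
    arity: int,
    n_draws: int,
    k: int,
    thresholds,
    seed: int,
    positive_class: str | None = None,
) -> NullDistribution:
    """Null distribution of CV mean AUC over random feature subsets.

    Each draw picks a uniform random distinct subset of ``arity`` features,
    runs c45 cross-validation, and records the mean AUC; the table reports
    empirical exceedance probabilities P(AUC >= threshold).
    """
    if n_draws < 1:
        raise ExpressionError("n_draws must be >= 1")
    if m.n_features < arity:
        raise ExpressionError("fewer features than requested arity")
    rng = np.random.default_rng(seed)
    fids = np.array(m.feature_ids)
    cv_seed = int(rng.integers(0, 2**31 - 1))  # one fold layout for all draws
    stats = []
    for i in range(n_draws):
        subset = rng.choice(len(fids), size=arity, replace=False)
        rep = cross_validate(
            m, fids[subset], k=k, seed=cv_seed,
            classifier="c45", positive_class=positive_class,
        )
        stats.append(rep.roc_area)
    stats_arr = np.asarray(stats)
    table = {
        float(t): float(np.mean(stats_arr >= t)) for t in thresholds
    }
    return NullDistribution(
        draws=n_draws, statistic_values=stats, thresholds_table=table, seed=seed
    )


# -- full discovery pipeline (shared by permutation test / protocol) ----


@dataclass
class PipelineConfig:
    """How candidate features are chosen and rules discovered in one run."""

    biomarker_ids: tuple | None = None
    top_n: int | None = None
    arities: tuple = (2, 3)
    bound_style: str = "midpoint"
    min_leaf: int = 2
    gain_mean_filter: bool = True
    exhaustive_max_features: int | None = None


def discover_rules(m: ExpressionMatrix, config: PipelineConfig) -> list:
    """Rank -> project/truncate -> committee harvest + exhaustive search -> pool."""
    ranked = rank_features(m)
    if config.biomarker_ids:
        candidates = project_biomarkers(ranked, config.biomarker_ids)
    elif config.top_n:
        candidates = [r.feature_id for r in ranked[: config.top_n]]
    else:
        candidates = [r.feature_id for r in ranked]
    committee_rules: list = []
    if len(candidates) >= 2:
        committee = build_committee(
            m, candidates, min_leaf=config.min_leaf,
            gain_mean_filter=config.gain_mean_filter,
        )
        committee_rules = harvest_rules(committee, m, arity_range=config.arities)
    exhaustive_rules: list = []
    for arity in config.arities:
        exhaustive_rules.extend(
            exhaustive_search(
                m, arity, bound_style=config.bound_style,
                max_features=config.exhaustive_max_features,
            )
        )
    return pool_rules(committee_rules, exhaustive_rules, m)


def label_permutation_test(
    m: ExpressionMatrix,
    config: PipelineConfig,
    n_permutations: int,
    seed: int,
) -> list:
    """Rerun the whole discovery pipeline on label-shuffled data.

    Returns the number of valid 100%-frequency rules found under each of
    ``n_permutations`` uniform label permutations.  On genuinely
    structured data the true labels yield rules while permuted labels
    should yield none.
    """
    rng = np.random.default_rng(seed)
    counts = []
    labels = m.labels.to_numpy()
    import warnings as _warnings

    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        shuffled = m.labels.copy()
        shuffled[:] = labels[perm]
        perm_m = m.with_labels(shuffled)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            rules = discover_rules(perm_m, config)
        counts.append(len(rules))
    return counts


def train_test_protocol(
    m: ExpressionMatrix,
    biomarker_ids,
    n_folds: int = 5,
    seed: int = 0,
    config: PipelineConfig | None = None,
    min_normal_per_fold: int = 2,
):
    """k-fold training-test protocol with per-fold feature re-selection.

    The smaller class is spread over the folds (at least
    ``min_normal_per_fold`` per test part); per fold, ranking + biomarker
    projection and rule discovery run on the training part only, the
    Max-Min best rule is applied to the held-out part as a classifier.
    """
    classes = m.classes
    sizes = {c: m.class_size(c) for c in classes}
    small = min(classes, key=lambda c: sizes[c])
    if sizes[small] < n_folds * min_normal_per_fold:
        raise ExpressionError(
            f"class {small!r} has {sizes[small]} samples; cannot give every of "
            f"{n_folds} test folds at least {min_normal_per_fold}"
        )
    rng = np.random.default_rng(seed)
    folds: list = [[] for _ in range(n_folds)]
    for c in classes:
        ids = [s for s in m.sample_ids if m.labels[s] == c]
        rng.shuffle(ids)
        for i, s in enumerate(ids):
            folds[i % n_folds].append(s)

    base = config or PipelineConfig()
    results = []
    for i, test_ids in enumerate(folds):
        train_ids = [s for s in m.sample_ids if s not in set(test_ids)]
        m_train = m.subset_samples(train_ids)
        m_test = m.subset_samples(test_ids)
        cfg = PipelineConfig(**{**base.__dict__, "biomarker_ids": tuple(biomarker_ids)})
        ranked = rank_features(m_train)
        candidates = project_biomarkers(ranked, biomarker_ids)
        rules = discover_rules(m_train, cfg)
        fold = {
            "fold": i + 1,
            "selected_features": candidates,
            "best_rule": None,
            "test_accuracy": float("nan"),
        }
        if rules:
            ranked_rules = rank_rules_by_separation(rules, m_train)
            best = max(ranked_rules, key=lambda s: (s.min_distance, -s.rule.arity))
            pred = best.rule.predict(m_test)
            fold["best_rule"] = best.rule
            fold["test_accuracy"] = float(np.mean(pred == m_test.label_array()))
        results.append(fold)
    return results
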