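import math

import numpy as np
import pytest

import mirule as mr
from mirule.matrix import ExpressionError

from conftest import make_matrix


class TestAUC:
    def test_perfect_scorer(self):
        assert mr.mann_whitney_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scorer_is_half(self):
        assert mr.mann_whitney_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_tie_correction_average_rank(self):
        # one tie across classes contributes 1/2
        assert mr.mann_whitney_auc([0.3, 0.5, 0.5], [0, 0, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ExpressionError):
            mr.mann_whitney_auc([0.1, 0.2], [1, 1])


def _separable_matrix():
    # wide deterministic gap: any midpoint threshold generalizes perfectly
    a = np.linspace(0.0, 1.0, 8)
    b = np.linspace(6.0, 7.0, 16)
    f1 = np.concatenate([a, b])
    f2 = np.concatenate([a[::-1], b[::-1] + 1])
    return make_matrix([f1, f2], ["normal"] * 8 + ["cancer"] * 16)


class TestCrossValidate:
    @pytest.mark.parametrize("classifier", ["c45", "knn1", "naive_bayes"])
    def test_separable_case_perfect(self, classifier):
        m = _separable_matrix()
        rep = mr.cross_validate(m, m.feature_ids, k=4, seed=3, classifier=classifier)
        assert rep.accuracy == 1.0
        assert rep.roc_area == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_confusion_identities(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        rep = mr.cross_validate(m, ["planted_p1", "null_001"], k=5, seed=1)
        tp = sum(f["tp"] for f in rep.per_fold)
        fn = sum(f["fn"] for f in rep.per_fold)
        tn = sum(f["tn"] for f in rep.per_fold)
        fp = sum(f["fp"] for f in rep.per_fold)
        assert tp + fn + tn + fp == m.n_samples
        assert rep.sensitivity == pytest.approx(tp / (tp + fn))
        assert rep.specificity == pytest.approx(tn / (tn + fp))
        assert rep.accuracy == pytest.approx((tp + tn) / m.n_samples)
        prec = tp / (tp + fp)
        assert rep.f_measure == pytest.approx(
            2 * prec * rep.sensitivity / (prec + rep.sensitivity)
        )

    def test_null_data_auc_half_and_no_majority_beating(self):
        """Label-independent features: mean CV AUC ~ 0.5 and mean accuracy
        does not exceed the majority-class rate beyond sampling noise."""
        aucs, accs = [], []
        for seed in range(60):
            m = mr.generate_null_dataset(12, 28, 3, seed=seed)
            rep = mr.cross_validate(m, m.feature_ids, k=4, seed=seed)
            aucs.append(rep.roc_area)
            accs.append(rep.accuracy)
        se_auc = np.std(aucs, ddof=1) / math.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) <= 3 * se_auc + 0.01
        se_acc = np.std(accs, ddof=1) / math.sqrt(len(accs))
        assert np.mean(accs) <= 28 / 40 + 3 * se_acc

    def test_unknown_feature_and_bad_k(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        with pytest.raises(ExpressionError):
            mr.cross_validate(m, ["ghost"], k=5, seed=0)
        with pytest.raises(ExpressionError):
            mr.cross_validate(m, ["planted_p1"], k=m.n_samples + 1, seed=0)

    def test_deterministic_given_seed(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        r1 = mr.cross_validate(m, ["planted_p1", "planted_p2"], k=5, seed=9)
        r2 = mr.cross_validate(m, ["planted_p1", "planted_p2"], k=5, seed=9)
        assert r1.to_dict() == r2.to_dict()


class TestRandomizationTest:
    def test_threshold_zero_probability_one(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        null = mr.randomization_test(m, 2, n_draws=20, k=5, thresholds=[0.0], seed=1)
        assert null.thresholds_table[0.0] == 1.0

    def test_exceedance_monotone_non_increasing(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        thresholds = [0.0, 0.5, 0.8, 0.9, 0.95, 1.0]
        null = mr.randomization_test(m, 2, n_draws=40, k=5, thresholds=thresholds, seed=2)
        probs = [null.thresholds_table[t] for t in thresholds]
        assert probs == sorted(probs, reverse=True)

    def test_matches_subset_enumeration(self):
        """Empirical exceedance agrees with exact enumeration over all pairs
        (same CV fold layout), within binomial sampling error."""
        spec = mr.SyntheticSpec(
            n_class1=8, n_class2=16, n_null_features=8,
            planted=[mr.default_planted_pair()], seed=23,
        )
        m, _ = mr.generate_dataset(spec)
        seed, draws, thr = 5, 200, 0.95
        null = mr.randomization_test(m, 2, n_draws=draws, k=4, thresholds=[thr], seed=seed)
        cv_seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
        import itertools

        stats = [
            mr.cross_validate(m, pair, k=4, seed=cv_seed).roc_area
            for pair in itertools.combinations(m.feature_ids, 2)
        ]
        q = float(np.mean(np.asarray(stats) >= thr))
        tol = 3 * math.sqrt(max(q * (1 - q), 1e-4) / draws) + 0.02
        assert abs(null.thresholds_table[thr] - q) <= tol

    def test_deterministic(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        a = mr.randomization_test(m, 2, 15, 5, [0.9], seed=3)
        b = mr.randomization_test(m, 2, 15, 5, [0.9], seed=3)
        assert a.statistic_values == b.statistic_values


class TestLabelPermutation:
    def test_true_labels_yield_rules(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        rules = mr.discover_rules(m, mr.PipelineConfig(top_n=6, arities=(2,)))
        assert len(rules) > 0

    def test_permuted_labels_yield_none(self, planted_pair_matrix):
        m, _ = planted_pair_matrix
        counts = mr.label_permutation_test(
            m, mr.PipelineConfig(top_n=6, arities=(2,)), n_permutations=20, seed=4
        )
        assert sum(c == 0 for c in counts) >= 19

    def test_constant_matrix_never_yields_rules(self):
        m = make_matrix(np.full((4, 12), 8.0), ["A"] * 4 + ["B"] * 8)
        counts = mr.label_permutation_test(
            m, mr.PipelineConfig(arities=(2,)), n_permutations=5, seed=0
        )
        assert counts == [0] * 5


class TestTrainTestProtocol:
    def test_dominant_planted_pair_selected_every_fold(self):
        from conftest import make_corner_dataset

        m, planted = make_corner_dataset(seed=2)
        folds = mr.train_test_protocol(m, planted, n_folds=5, seed=2)
        assert len(folds) == 5
        for fold in folds:
            assert fold["best_rule"] is not None
            assert set(fold["best_rule"].feature_ids) == set(planted)
            assert fold["test_accuracy"] == 1.0

    def test_small_class_fold_constraint(self, planted_pair_matrix):
        m, truth = planted_pair_matrix  # 10 normals: 6 folds x 2 impossible
        with pytest.raises(ExpressionError):
            mr.train_test_protocol(
                m, truth["planted"][0]["features"], n_folds=6, seed=0
            )

    def test_fold_assignment_deterministic(self, planted_pair_matrix):
        m, truth = planted_pair_matrix
        planted = truth["planted"][0]["features"]
        f1 = mr.train_test_protocol(m, planted, n_folds=5, seed=7)
        f2 = mr.train_test_protocol(m, planted, n_folds=5, seed=7)
        assert [f["test_accuracy"] for f in f1] == [f["test_accuracy"] for f in f2]
        assert [f["selected_features"] for f in f1] == [
            f["selected_features"] for f in f2
        ]
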