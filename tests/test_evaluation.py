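"""Metrics, ROC/AUC + DeLong, partitioning, cohort statistics."""

import numpy as np
import pytest

from lesionroi import (
    AlignmentError,
    ConfigurationError,
    ConfusionMatrix,
    DegenerateInputError,
    classification_metrics,
    delong_test,
    mann_whitney_u,
    partition_patients,
    patient_soft_vote,
    pearson_chi_square,
    roc_auc,
)


def auc_by_pair_counting(labels, scores):
    """Brute-force oracle: fraction of positive-negative pairs ranked
    correctly, ties counting one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestPartition:
    def test_stratified_fold_sizes(self):
        pids = [f"p{i}" for i in range(128)]
        labels = [1] * 64 + [0] * 64
        part = partition_patients(pids, labels, k=5, seed=0)
        sizes = [len(part.fold_patients(f)) for f in range(5)]
        assert sorted(sizes)[0] >= 25 and sorted(sizes)[-1] <= 26
        assert sum(sizes) == 128
        # stratification: each fold close to balanced
        for f in range(5):
            members = part.fold_patients(f)
            n_pos = sum(int(p[1:]) < 64 for p in members)
            assert abs(n_pos - len(members) / 2) <= 1

    def test_singleton_folds(self):
        part = partition_patients(list("abcde"), [0, 0, 1, 1, 1], k=5, seed=1)
        assert sorted(len(part.fold_patients(f)) for f in range(5)) == [1] * 5

    def test_deterministic_and_disjoint(self):
        pids = [f"p{i}" for i in range(20)]
        labels = [i % 2 for i in range(20)]
        a = partition_patients(pids, labels, k=4, seed=3)
        b = partition_patients(pids, labels, k=4, seed=3)
        assert a.assignment == b.assignment
        assert set(a.assignment) == set(pids)  # union covers, no duplicates

    def test_k_exceeding_patients_rejected(self):
        with pytest.raises(ConfigurationError):
            partition_patients(["a", "b"], [0, 1], k=3)


class TestMetrics:
    def test_formula_evaluation(self):
        rep = classification_metrics(ConfusionMatrix(tp=3, fp=1, fn=2, tn=4))
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)
        assert rep.f1 == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.specificity == pytest.approx(0.8)

    def test_perfect_prediction(self):
        rep = classification_metrics(ConfusionMatrix(tp=5, tn=5, fp=0, fn=0))
        assert all(v == 1.0 for v in rep.as_dict().values())

    def test_all_positive_boundary(self):
        rep = classification_metrics(ConfusionMatrix(tp=5, fp=5, tn=0, fn=0))
        assert rep.recall == 1.0 and rep.precision == 0.5 and rep.specificity == 0.0

    def test_undefined_ratio_warns_not_zero(self):
        with pytest.warns(RuntimeWarning):
            rep = classification_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(rep.precision)

    def test_empty_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            classification_metrics(ConfusionMatrix(0, 0, 0, 0))


class TestSoftVote:
    @pytest.mark.parametrize(
        "probs,expected_prob,expected_class",
        [([0.9, 0.8, 0.7], 0.8, 1), ([0.3], 0.3, 0), ([0.4, 0.6], 0.5, 1)],
    )
    def test_mean_and_threshold(self, probs, expected_prob, expected_class):
        prob, cls = patient_soft_vote(probs)
        assert prob == pytest.approx(expected_prob)
        assert cls == expected_class

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            patient_soft_vote([])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]).auc == 1.0

    def test_pair_counting_example(self):
        res = roc_auc([1, 1, 0, 0], [0.9, 0.2, 0.3, 0.8])
        assert res.auc == pytest.approx(0.5)
        assert (res.n_pos, res.n_neg) == (2, 2)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.integers(0, 2, size=12)
            if labels.min() == labels.max():
                continue
            scores = rng.random(12)
            assert roc_auc(labels, scores).auc + roc_auc(labels, -scores).auc == pytest.approx(1.0)

    def test_ties_count_half(self):
        res = roc_auc([1, 0], [0.5, 0.5])
        assert res.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        labels = [1, 1, 0, 0, 1, 0]
        scores = [0.9, 0.6, 0.4, 0.2, 0.7, 0.5]
        auc_a, auc_b, z, p = delong_test(labels, scores, scores)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_known_auc_pair(self):
        labels = [1, 1, 0, 0]
        a = [0.9, 0.8, 0.3, 0.2]
        b = [0.9, 0.2, 0.3, 0.8]
        auc_a, auc_b, z, p = delong_test(labels, a, b)
        assert auc_a == 1.0 and auc_b == 0.5
        assert 0 < p <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            delong_test([1, 0], [0.1, 0.9], [0.5])

    def test_null_pvalues_approximately_uniform(self):
        """Under the null (two equally noisy score sets on the same cases)
        the DeLong p-value should be uniform on [0, 1]."""
        rng = np.random.default_rng(7)
        labels = np.repeat([0, 1], 20)
        ps = []
        for _ in range(500):
            base = rng.random(40) + 0.4 * labels
            a = base + rng.normal(0, 0.3, 40)
            b = base + rng.normal(0, 0.3, 40)
            ps.append(delong_test(labels, a, b)[3])
        ps = np.asarray(ps)
        for q in (0.1, 0.25, 0.5):
            assert abs((ps < q).mean() - q) < 0.05, q

    def test_variance_positive_on_noisy_scores(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 20)
        scores = rng.random(40) + labels * 0.3
        res = roc_auc(labels, scores)
        assert res.delong_variance > 0


class TestCohortStatistics:
    # category counts per group (columns: AME, OKC) for a two-class cohort
    @pytest.mark.parametrize(
        "table,p_expected",
        [
            ([[32, 30], [32, 34]], 0.724),  # sex
            ([[4, 9], [60, 55]], 0.143),  # location
            ([[15, 46], [49, 18]], 0.000),  # locularity
            ([[46, 31], [18, 33]], 0.007),  # cortical integrity
            ([[17, 30], [47, 34]], 0.017),  # impacted tooth
            ([[50, 49], [8, 6], [6, 9]], 0.639),  # scanner (2x3)
        ],
    )
    def test_chi_square_matches_printed_cohort_pvalues(self, table, p_expected):
        _, df, p = pearson_chi_square(table)
        assert df == (len(table) - 1)
        assert round(p, 3) == p_expected

    def test_uniform_table_statistic_zero(self):
        stat, df, p = pearson_chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_mann_whitney_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_mann_whitney_symmetry(self):
        x, y = [1.0, 5.0, 3.0], [2.0, 8.0, 9.0]
        assert mann_whitney_u(x, y)[1] == pytest.approx(mann_whitney_u(y, x)[1])

    def test_mann_whitney_identical_samples(self):
        x = list(np.arange(25, dtype=float))
        _, p = mann_whitney_u(x, x)
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            mann_whitney_u([], [1.0])
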