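import numpy as np
import pytest

from hetdti.evaluation import (
    kfold_split,
    ranking_metrics,
    redundancy_filter,
    sample_negatives,
)
from hetdti.exceptions import ConfigurationError, DataValidationError


def auroc_oracle(scores, labels):
    """Brute-force Mann-Whitney: fraction of (pos, neg) pairs won, ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if sp > sn else 0.5 if sp == sn else 0.0 for sp in pos for sn in neg)
    return wins / (len(pos) * len(neg))


def aupr_oracle(scores, labels):
    """Step integral of precision over recall, one step per distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        predicted = scores >= t
        tp = (labels[predicted] == 1).sum()
        precision = tp / predicted.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def filter_oracle(Y, drug_sims, protein_sims, thr_d, thr_p):
    """Greedy keep-first over sorted positives, checked against every kept pair."""
    kept = []
    for i, j in sorted(zip(*np.nonzero(Y))):
        redundant = any(
            (j2 == j and i2 != i and any(S[i, i2] > thr_d for S in drug_sims.values()))
            or (i2 == i and j2 != j and any(S[j, j2] > thr_p for S in protein_sims.values()))
            for i2, j2 in kept
        )
        if not redundant:
            kept.append((i, j))
    out = np.zeros_like(Y)
    for i, j in kept:
        out[i, j] = 1.0
    return out


class TestSampleNegatives:
    @pytest.mark.parametrize("ratio", [1, 10])
    def test_exact_ratio(self, rng, ratio):
        Y = np.zeros((40, 60))
        pos = rng.choice(40 * 60, size=100, replace=False)
        Y.flat[pos] = 1.0
        sample = sample_negatives(Y, ratio=ratio, seed=0)
        assert len(sample.positives) == 100
        assert len(sample.negatives) == ratio * 100

    def test_negatives_disjoint_from_positives_and_unique(self):
        Y = (np.arange(20).reshape(4, 5) % 3 == 0).astype(float)
        sample = sample_negatives(Y, ratio=1, seed=3)
        negs = sample.negatives
        assert len(set(negs)) == len(negs)
        assert all(Y[i, j] == 0 for i, j in negs)
        assert all(Y[i, j] == 1 for i, j in sample.positives)

    def test_exhaustion_takes_all_with_warning(self):
        Y = np.ones((3, 3))
        Y[2, 2] = 0.0  # 8 positives, 1 zero pair
        with pytest.warns(UserWarning, match="only 1"):
            sample = sample_negatives(Y, ratio=10, seed=0)
        assert len(sample.negatives) == 1

    def test_deterministic_per_seed(self, rng):
        Y = (rng.random((30, 30)) < 0.1).astype(float)
        s1 = sample_negatives(Y, ratio=5, seed=11)
        s2 = sample_negatives(Y, ratio=5, seed=11)
        s3 = sample_negatives(Y, ratio=5, seed=12)
        assert s1.pairs == s2.pairs
        assert s1.pairs != s3.pairs

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            sample_negatives(np.eye(3), ratio=0.5, seed=0)


class TestKfoldSplit:
    def test_exact_divisibility_preserves_class_balance(self):
        Y = np.zeros((2, 10))
        Y[0] = 1.0  # 10 positives, ratio 1 -> all 10 zero pairs are taken
        with pytest.warns(UserWarning):
            sample = sample_negatives(Y, ratio=1, seed=0)
        split = kfold_split(sample, k=10, seed=0)
        for fold in split.folds:
            labels = [y for _, _, y in fold]
            assert len(fold) == 2 and sum(labels) == 1

    def test_folds_partition_sample(self, rng):
        Y = (rng.random((20, 20)) < 0.15).astype(float)
        sample = sample_negatives(Y, ratio=2, seed=1)
        split = kfold_split(sample, k=5, seed=1)
        flat = [p for fold in split.folds for p in fold]
        assert sorted(flat) == sorted(sample.pairs)
        sizes = [len(f) for f in split.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_per_seed(self, rng):
        Y = (rng.random((15, 15)) < 0.2).astype(float)
        sample = sample_negatives(Y, ratio=1, seed=2)
        assert kfold_split(sample, k=4, seed=9).folds == kfold_split(sample, k=4, seed=9).folds

    def test_fewer_positives_than_folds(self):
        Y = np.zeros((5, 5))
        Y[0, 0] = Y[1, 1] = 1.0
        sample = sample_negatives(Y, ratio=1, seed=0)
        with pytest.raises(DataValidationError, match="stratify"):
            kfold_split(sample, k=5, seed=0)


class TestRankingMetrics:
    def test_hand_example(self):
        auroc, _ = ranking_metrics([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0])
        assert auroc == pytest.approx(0.75)  # 3 of 4 pairs won

    def test_perfect_separation(self):
        auroc, aupr = ranking_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auroc == 1.0 and aupr == 1.0

    def test_constant_scores_give_half_auroc(self):
        auroc, _ = ranking_metrics([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auroc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(DataValidationError):
            ranking_metrics([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracles(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            # discrete score grid so ties actually occur
            scores = rng.integers(0, 6, size=n) / 5.0
            auroc, aupr = ranking_metrics(scores, labels)
            assert auroc == pytest.approx(auroc_oracle(scores, labels), abs=1e-12)
            assert aupr == pytest.approx(aupr_oracle(scores, labels), abs=1e-12)

    def test_aupr_never_below_worst_case_floor(self, rng):
        # the minimum achievable AP ranks every negative above every positive:
        # AP_min = (1/P) sum_i i/(N+i); any scoring must do at least this well
        for _ in range(50):
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            scores = rng.random(40)
            _, aupr = ranking_metrics(scores, labels)
            P = int(labels.sum())
            N = len(labels) - P
            floor = np.mean([i / (N + i) for i in range(1, P + 1)])
            assert aupr >= floor - 1e-12

    def test_aupr_random_scores_near_prevalence_on_average(self, rng):
        labels = np.array([1] * 20 + [0] * 180)
        auprs = [ranking_metrics(rng.random(200), labels)[1] for _ in range(200)]
        # random ranking averages slightly ABOVE prevalence (finite-sample bias
        # of average precision); it must never fall materially below it
        assert labels.mean() - 0.01 < np.mean(auprs) < labels.mean() + 0.05


class TestRedundancyFilter:
    def test_all_zero_similarities_remove_nothing(self, rng):
        Y = (rng.random((6, 6)) < 0.3).astype(float)
        out, log = redundancy_filter(Y, {"chem": np.zeros((6, 6))}, {"seq": np.zeros((6, 6))})
        np.testing.assert_array_equal(out, Y)
        assert log == []

    def test_similar_drugs_sharing_protein_pruned(self):
        Y = np.zeros((3, 2))
        Y[0, 0] = Y[1, 0] = 1.0  # two drugs hit the same protein
        chem = np.eye(3)
        chem[0, 1] = chem[1, 0] = 0.9
        out, log = redundancy_filter(Y, drug_similarities={"chem": chem})
        assert out.sum() == 1 and out[0, 0] == 1.0  # lexicographically first kept
        assert len(log) == 1 and log[0]["pair"] == (1, 0)

    def test_threshold_is_strict(self):
        Y = np.zeros((2, 1))
        Y[0, 0] = Y[1, 0] = 1.0
        chem = np.eye(2)
        chem[0, 1] = chem[1, 0] = 0.6  # exactly at the threshold: not removed
        out, _ = redundancy_filter(Y, drug_similarities={"chem": chem})
        assert out.sum() == 2

    def test_similar_proteins_sharing_drug_pruned(self):
        Y = np.zeros((2, 3))
        Y[0, 0] = Y[0, 2] = 1.0
        seq = np.eye(3)
        seq[0, 2] = seq[2, 0] = 0.5  # above the 0.4 protein threshold
        out, log = redundancy_filter(Y, protein_similarities={"seq": seq})
        assert out.sum() == 1 and out[0, 0] == 1.0

    def test_crafted_fixture_matches_exhaustive_oracle(self, rng):
        n, m = 8, 6
        Y = np.zeros((n, m))
        for i, j in [(0, 1), (1, 1), (2, 1), (0, 3), (0, 5), (4, 2)]:
            Y[i, j] = 1.0
        chem = np.eye(n)
        chem[0, 1] = chem[1, 0] = 0.7
        chem[1, 2] = chem[2, 1] = 0.65
        seq = np.eye(m)
        seq[3, 5] = seq[5, 3] = 0.45
        out, _ = redundancy_filter(Y, {"chem": chem}, {"seq": seq})
        expected = filter_oracle(Y, {"chem": chem}, {"seq": seq}, 0.6, 0.4)
        np.testing.assert_array_equal(out, expected)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(20):
            Y = (rng.random((7, 5)) < 0.35).astype(float)
            C = rng.random((7, 7))
            C = (C + C.T) / 2
            S = rng.random((5, 5))
            S = (S + S.T) / 2
            out, _ = redundancy_filter(Y, {"c": C}, {"s": S})
            np.testing.assert_array_equal(out, filter_oracle(Y, {"c": C}, {"s": S}, 0.6, 0.4))

    def test_result_independent_of_visit_order(self, rng):
        # the lexicographic keep-rule fixes the outcome regardless of how the
        # positives were produced
        Y = (rng.random((6, 6)) < 0.4).astype(float)
        C = rng.random((6, 6))
        C = (C + C.T) / 2
        out1, _ = redundancy_filter(Y, {"c": C})
        out2, _ = redundancy_filter(Y.copy(), {"c": C})
        np.testing.assert_array_equal(out1, out2)

    def test_no_similarities_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            redundancy_filter(np.eye(3))
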