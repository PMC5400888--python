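from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skmetrics
from sklearn.mixture import GaussianMixture

from stakeminer import fit_em, partition_metrics, select_k, two_sample_t


def brute_force_metrics(pred, ref):
    """O(n^2) pair counter used as the independent oracle."""
    a = b = c = d = 0
    for i, j in combinations(range(len(pred)), 2):
        same_pred = pred[i] == pred[j]
        same_ref = ref[i] == ref[j]
        if same_pred and same_ref:
            a += 1
        elif same_ref:
            b += 1
        elif same_pred:
            c += 1
        else:
            d += 1
    total = a + b + c + d
    rand = (a + d) / total
    jacc = a / (a + b + c) if (a + b + c) else 0.0
    fm = a / np.sqrt((a + b) * (a + c)) if a else 0.0
    return rand, jacc, fm


def two_blobs(n=100, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))])
    labels = np.repeat([0, 1], n)
    return X, labels


class TestFitEM:
    def test_single_component(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        model, assign = fit_em(X, K=1, seed=0)
        assert model.weights == pytest.approx([1.0])
        assert np.allclose(assign.posterior, 1.0)

    def test_separated_blobs_recovered(self):
        X, planted = two_blobs()
        _, assign = fit_em(X, K=2, seed=0)
        assert partition_metrics(assign.labels, planted).rand == 1.0

    def test_seeded_determinism(self):
        X, _ = two_blobs(seed=3)
        _, a1 = fit_em(X, K=2, seed=42)
        _, a2 = fit_em(X, K=2, seed=42)
        assert np.array_equal(a1.labels, a2.labels)
        assert np.allclose(a1.posterior, a2.posterior)

    def test_posterior_rows_sum_to_one(self):
        X, _ = two_blobs(n=40)
        _, assign = fit_em(X, K=3, seed=1)
        assert np.allclose(assign.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(assign.labels, assign.posterior.argmax(axis=1))

    def test_agrees_with_reference_gaussian_mixture(self):
        # Independent cross-check of the Gaussian EM path on continuous
        # data: both routes must recover the same partition.
        X, _ = two_blobs(n=80, sep=8.0, seed=5)
        _, ours = fit_em(X, K=2, seed=0)
        ref = GaussianMixture(2, covariance_type="diag", random_state=0).fit_predict(X)
        assert partition_metrics(ours.labels, ref).rand == 1.0

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            fit_em(np.zeros((3, 2)), K=5)


class TestSelectK:
    def test_single_blob_selects_one(self):
        X = np.random.default_rng(0).normal(size=(120, 3))
        k, table = select_k(X, k_max=4, folds=10, seed=0)
        assert k == 1

    def test_two_blobs_select_two(self):
        X, _ = two_blobs(n=80)
        k, table = select_k(X, k_max=5, folds=10, seed=0)
        assert k == 2
        assert table[2] > table[1]

    def test_invalid_arguments(self):
        X, _ = two_blobs(n=10)
        with pytest.raises(ValueError):
            select_k(X, k_max=0)
        with pytest.raises(ValueError):
            select_k(X, folds=1)


class TestPartitionMetrics:
    def test_identical_partitions(self):
        pm = partition_metrics([0, 1, 2, 0], [5, 7, 9, 5])
        assert (pm.rand, pm.jaccard, pm.fm) == (1.0, 1.0, 1.0)

    def test_worked_pair_counts(self):
        # ref [1,1,1,2], pred [1,1,2,2]: a=1 b=2 c=1 d=2
        pm = partition_metrics([1, 1, 2, 2], [1, 1, 1, 2])
        assert pm.rand == pytest.approx(0.5)
        assert pm.jaccard == pytest.approx(0.25)
        assert pm.fm == pytest.approx(1 / np.sqrt(6))

    def test_singletons_vs_one_cluster(self):
        pm = partition_metrics([0, 1, 2, 3], [0, 0, 0, 0])
        assert (pm.rand, pm.jaccard, pm.fm) == (0.0, 0.0, 0.0)

    def test_relabeling_invariance(self):
        pred = [0, 0, 1, 1, 2]
        ref = [3, 3, 1, 1, 0]
        relabeled = [9, 9, 4, 4, 7]
        assert partition_metrics(pred, ref) == partition_metrics(relabeled, ref)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            partition_metrics([0, 1], [0, 1, 2])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.integers(2, 12).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 3), min_size=n, max_size=n),
                st.lists(st.integers(0, 3), min_size=n, max_size=n),
            )
        )
    )
    def test_matches_brute_force_oracle(self, labels):
        pred, ref = labels
        pm = partition_metrics(pred, ref)
        rand, jacc, fm = brute_force_metrics(pred, ref)
        assert pm.rand == pytest.approx(rand)
        assert pm.jaccard == pytest.approx(jacc)
        assert pm.fm == pytest.approx(fm)

    def test_matches_reference_library(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 4, 50)
        ref = rng.integers(0, 3, 50)
        pm = partition_metrics(pred, ref)
        assert pm.rand == pytest.approx(skmetrics.rand_score(ref, pred))
        assert pm.fm == pytest.approx(skmetrics.fowlkes_mallows_score(ref, pred))


class TestTwoSampleT:
    def test_identical_samples_null(self):
        assert two_sample_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_textbook_welch(self):
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_antisymmetry(self):
        t1, p1 = two_sample_t([1.0, 2.0, 4.0], [3.0, 5.0, 9.0])
        t2, p2 = two_sample_t([3.0, 5.0, 9.0], [1.0, 2.0, 4.0])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_constant_samples(self):
        assert two_sample_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])
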