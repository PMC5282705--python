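import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpcabiome import (
    AbundanceMatrix,
    ConfusionCounts,
    LabelVector,
    average_consistency,
    classification_metrics,
    constant_selector,
    generate_subsamples,
    ki_histogram,
    kuncheva_index,
    ncc_fit,
    ncc_predict,
    random_selector,
    run_protocol,
)


class TestGenerateSubsamples:
    @pytest.mark.parametrize("N,r,n_train", [(168, 0.8, 135), (30, 0.8, 24)])
    def test_split_sizes_ceil_rN(self, N, r, n_train):
        splits = generate_subsamples(N, r, K=5, seed=0)
        for s in splits:
            assert len(s.train_idx) == n_train
            assert len(s.test_idx) == N - n_train
            assert set(s.train_idx) | set(s.test_idx) == set(range(N))

    def test_seed_reproducibility(self):
        a = generate_subsamples(30, 0.8, K=10, seed=5)
        b = generate_subsamples(30, 0.8, K=10, seed=5)
        assert a == b
        c = generate_subsamples(30, 0.8, K=10, seed=6)
        assert any(x.train_idx != y.train_idx for x, y in zip(a, c))

    def test_replicates_differ_within_run(self):
        splits = generate_subsamples(30, 0.8, K=10, seed=5)
        assert len({s.train_idx for s in splits}) > 1

    def test_stratified_keeps_both_classes(self):
        labels = LabelVector(("U",) * 20 + ("C",) * 10, positive_class="U")
        splits = generate_subsamples(30, 0.8, K=20, seed=3, stratify_labels=labels)
        lab = np.asarray(labels.labels)
        for s in splits:
            train_lab = lab[list(s.train_idx)]
            assert len(s.train_idx) == 24
            assert (train_lab == "U").sum() >= 2 and (train_lab == "C").sum() >= 2

    @pytest.mark.parametrize("r", [0.0, 1.0, -0.2, 1.5])
    def test_bad_ratio_rejected(self, r):
        with pytest.raises(ValueError):
            generate_subsamples(30, r, K=5, seed=0)

    def test_no_test_samples_rejected(self):
        with pytest.raises(ValueError):
            generate_subsamples(10, 0.95, K=5, seed=0)  # ceil = 10


class TestKunchevaIndex:
    def test_identical_sets_hit_upper_bound(self):
        F = set(range(10))
        assert kuncheva_index(F, F, 100) == 1.0

    def test_disjoint_half_sets_hit_lower_bound(self):
        assert kuncheva_index(set(range(50)), set(range(50, 100)), 100) == -1.0

    def test_hand_computed_overlap(self):
        # |F_i ∩ F_j| = 5, T = 10, p = 100: (5 - 1) / (10 - 1) = 4/9
        F_i, F_j = set(range(1, 11)), set(range(6, 16))
        assert kuncheva_index(F_i, F_j, 100) == pytest.approx(4 / 9)

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal size"):
            kuncheva_index({1, 2}, {1, 2, 3}, 10)

    @pytest.mark.parametrize("T,p", [(0, 10), (10, 10), (12, 10)])
    def test_degenerate_sizes_rejected(self, T, p):
        with pytest.raises(ValueError):
            kuncheva_index(set(range(T)), set(range(T)), p)

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_bounds_and_symmetry(self, data):
        p = data.draw(st.integers(3, 60))
        T = data.draw(st.integers(1, p - 1))
        universe = list(range(p))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        F_i = set(rng.choice(universe, T, replace=False).tolist())
        F_j = set(rng.choice(universe, T, replace=False).tolist())
        ki = kuncheva_index(F_i, F_j, p)
        assert -1 - 1e-12 <= ki <= 1 + 1e-12
        assert ki == kuncheva_index(F_j, F_i, p)

    def test_random_selection_null_centers_at_zero(self):
        # chance-corrected index has exactly zero mean for independent
        # uniform draws; Monte-Carlo over independent pairs
        rng = np.random.default_rng(12345)
        p, T, n_pairs = 100, 10, 10_000
        kis = np.empty(n_pairs)
        for i in range(n_pairs):
            F_i = set(rng.choice(p, T, replace=False).tolist())
            F_j = set(rng.choice(p, T, replace=False).tolist())
            kis[i] = kuncheva_index(F_i, F_j, p)
        se = kis.std(ddof=1) / math.sqrt(n_pairs)
        assert abs(kis.mean()) < 3 * se


class TestAverageConsistency:
    def test_identical_sets_give_one(self):
        sets = [set(range(50))] * 500
        c_avg, ki_values = average_consistency(sets, 100)
        assert c_avg == 1.0
        assert len(ki_values) == 500 * 499 // 2 == 124_750

    def test_mean_of_hand_computed_pairwise_values(self):
        p = 100
        sets = [set(range(10)), set(range(5, 15)), set(range(50, 60))]
        expected = np.mean(
            [
                kuncheva_index(sets[0], sets[1], p),
                kuncheva_index(sets[0], sets[2], p),
                kuncheva_index(sets[1], sets[2], p),
            ]
        )
        c_avg, ki_values = average_consistency(sets, p)
        assert c_avg == pytest.approx(expected, abs=1e-12)
        assert len(ki_values) == 3

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same size"):
            average_consistency([{1, 2}, {1, 2, 3}], 10)


class TestNearestCentroid:
    def test_centroid_is_class_mean(self):
        train = AbundanceMatrix(
            np.array([[1.0, 3.0, 7.0], [1.0, 3.0, 9.0]]),
            ("a", "b"),
            ("s1", "s2", "s3"),
        )
        centroids = ncc_fit(train, ["x", "x", "y"])
        np.testing.assert_array_equal(centroids["x"], [2.0, 2.0])
        np.testing.assert_array_equal(centroids["y"], [7.0, 9.0])

    def test_single_sample_class_centroid_is_that_sample(self):
        train = AbundanceMatrix(np.array([[4.0, 1.0]]), ("a",), ("s1", "s2"))
        centroids = ncc_fit(train, ["p", "q"])
        np.testing.assert_array_equal(centroids["p"], [4.0])

    def test_matches_sklearn_nearest_centroid(self):
        # independent cross-check of fit + l2 prediction
        from sklearn.neighbors import NearestCentroid

        rng = np.random.default_rng(8)
        X = rng.random((6, 12))  # 6 taxa x 12 samples
        y = np.array(["a"] * 6 + ["b"] * 6)
        train = AbundanceMatrix(
            X, [f"t{i}" for i in range(6)], [f"s{j}" for j in range(12)]
        )
        centroids = ncc_fit(train, y)
        clf = NearestCentroid().fit(X.T, y)
        np.testing.assert_allclose(
            np.vstack([centroids["a"], centroids["b"]]), clf.centroids_, atol=1e-12
        )
        Z = rng.random((6, 20))
        ours = [ncc_predict(Z[:, j], centroids, "l2") for j in range(20)]
        np.testing.assert_array_equal(ours, clf.predict(Z.T))

    def test_empty_class_rejected(self):
        train = AbundanceMatrix(np.ones((2, 2)), ("a", "b"), ("s1", "s2"))
        with pytest.raises(ValueError, match="labels"):
            ncc_fit(train, ["x"])

    def test_predicts_exact_centroid_and_norm_choice(self):
        centroids = {"near": np.array([0.0, 0.0]), "far": np.array([4.0, 4.0])}
        assert ncc_predict(np.array([0.0, 0.0]), centroids, "l2") == "near"
        for norm in ("l1", "l2"):
            assert ncc_predict(np.array([1.0, 1.0]), centroids, norm) == "near"
        # the two norms can disagree: z=(2,0) is l1-equidistant from (0,0)
        # and (1.5,1.5) (tie -> "a") but strictly l2-closer to (1.5,1.5)
        c2 = {"a": np.array([0.0, 0.0]), "b": np.array([1.5, 1.5])}
        z = np.array([2.0, 0.0])
        assert ncc_predict(z, c2, "l1") == "a"
        assert ncc_predict(z, c2, "l2") == "b"

    def test_equidistant_tie_goes_to_smaller_label(self):
        centroids = {"b": np.array([1.0]), "a": np.array([-1.0])}
        assert ncc_predict(np.array([0.0]), centroids, "l2") == "a"

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            ncc_predict(np.ones(3), {"a": np.ones(2), "b": np.zeros(2)}, "l2")


class TestClassificationMetrics:
    def test_worked_confusion_table(self):
        acc, sens, spec = classification_metrics(
            ConfusionCounts(TP=40, TN=45, FP=5, FN=10)
        )
        assert (acc, sens, spec) == (0.85, 0.80, 0.90)

    def test_perfect_classifier(self):
        assert classification_metrics(ConfusionCounts(10, 10, 0, 0)) == (1, 1, 1)

    def test_zero_sensitivity(self):
        acc, sens, spec = classification_metrics(ConfusionCounts(0, 5, 5, 10))
        assert sens == 0.0

    def test_undefined_metric_is_nan_not_zero(self):
        acc, sens, spec = classification_metrics(ConfusionCounts(0, 5, 5, 0))
        assert math.isnan(sens) and not math.isnan(spec)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    def test_accuracy_identity(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        acc, sens, spec = classification_metrics(c)
        if c.total and (tp + fn) and (tn + fp):
            combined = (sens * (tp + fn) + spec * (tn + fp)) / c.total
            assert acc == pytest.approx(combined, abs=1e-12)


def toy_study(seed=0, p=30, n_pos=8, n_neg=8, shift=0.5):
    """Small separable two-class study for protocol plumbing tests."""
    rng = np.random.default_rng(seed)
    N = n_pos + n_neg
    values = rng.uniform(0.5, 1.5, (p, N))
    values[:3, :n_pos] += shift
    matrix = AbundanceMatrix(
        values, [f"t{i}" for i in range(p)], [f"s{j}" for j in range(N)]
    )
    labels = LabelVector(("D",) * n_pos + ("H",) * n_neg, positive_class="D")
    return matrix, labels


class TestRunProtocol:
    def test_constant_selector_gives_perfect_consistency(self):
        matrix, labels = toy_study()
        selector = constant_selector(matrix.taxon_ids)
        reports = run_protocol(matrix, labels, selector, [5], K=8, r=0.75, seed=1)
        rep = reports[0]
        assert rep.C_avg == 1.0
        assert len(rep.ki_values) == 8 * 7 // 2
        counts, edges = ki_histogram(rep.ki_values, bins=10)
        assert counts.sum() == len(rep.ki_values)
        assert counts[-1] == len(rep.ki_values)  # all mass in the top bin

    def test_random_selector_null_consistency(self):
        matrix, labels = toy_study(p=100)
        reports = run_protocol(
            matrix, labels, random_selector(), [10], K=200, r=0.75, seed=2
        )
        ki = np.asarray(reports[0].ki_values)
        # pairwise indices are uncorrelated under the null (E[KI|F_i] = 0
        # for every F_i), so the plain SE of the mean applies
        se = ki.std(ddof=1) / math.sqrt(ki.size)
        assert abs(ki.mean()) < 3 * se

    def test_test_columns_never_reach_the_selector(self):
        # sentinel poisoning: plant an enormous value in one sample column
        # and record every training matrix the selector receives — replicates
        # holding that column out must see a sentinel-free training matrix
        # identical to the unpoisoned one
        matrix, labels = toy_study(seed=3)
        K, r, seed = 6, 0.75, 9
        sentinel = 1e9
        victim = 0

        poisoned_values = matrix.values.copy()
        poisoned_values[:, victim] = sentinel
        poisoned = AbundanceMatrix(
            poisoned_values, matrix.taxon_ids, matrix.sample_ids
        )

        seen: list = []

        def recording_selector(train, rng):
            seen.append(train)
            return matrix.taxon_ids

        run_protocol(poisoned, labels, recording_selector, [4], K=K, r=r, seed=seed)
        victim_id = matrix.sample_ids[victim]
        held_out = [t for t in seen if victim_id not in t.sample_ids]
        assert held_out, "expected at least one replicate to hold the victim out"
        for train in held_out:
            assert train.values.max() < sentinel
            cols = [matrix.sample_ids.index(s) for s in train.sample_ids]
            np.testing.assert_array_equal(train.values, matrix.values[:, cols])

    def test_poisoned_test_columns_leave_centroids_unchanged(self):
        # centroids are fitted on training columns only: fitting on the same
        # train restriction of a matrix poisoned elsewhere is identical
        matrix, labels = toy_study(seed=3)
        splits = generate_subsamples(
            matrix.n_samples, 0.75, 4, seed=2, stratify_labels=labels
        )
        lab = np.asarray(labels.labels)
        for split in splits:
            poisoned_values = matrix.values.copy()
            poisoned_values[:, list(split.test_idx)] = 1e9
            poisoned = AbundanceMatrix(
                poisoned_values, matrix.taxon_ids, matrix.sample_ids
            )
            base_c = ncc_fit(
                matrix.select_samples(split.train_idx), lab[list(split.train_idx)]
            )
            pois_c = ncc_fit(
                poisoned.select_samples(split.train_idx), lab[list(split.train_idx)]
            )
            for cls in base_c:
                np.testing.assert_array_equal(base_c[cls], pois_c[cls])

    def test_selector_returning_short_ranking_rejected(self):
        matrix, labels = toy_study()
        selector = constant_selector(matrix.taxon_ids[:3])
        with pytest.raises(ValueError, match="at least"):
            run_protocol(matrix, labels, selector, [10], K=3, r=0.75, seed=0)

    def test_selector_returning_duplicates_rejected(self):
        matrix, labels = toy_study()
        selector = constant_selector(("t0",) * 10)
        with pytest.raises(ValueError, match="duplicate"):
            run_protocol(matrix, labels, selector, [5], K=3, r=0.75, seed=0)

    def test_grid_must_leave_ki_defined(self):
        matrix, labels = toy_study(p=10)
        with pytest.raises(ValueError):
            run_protocol(
                matrix, labels, constant_selector(matrix.taxon_ids), [10],
                K=3, r=0.75, seed=0,
            )

    def test_separable_study_classified_well(self):
        matrix, labels = toy_study(shift=2.0)
        selector = constant_selector(matrix.taxon_ids)  # first 3 are shifted
        reports = run_protocol(
            matrix, labels, selector, [3], K=20, r=0.75, seed=4
        )
        for summary in reports[0].classifiers.values():
            assert summary.accuracy >= 0.9
            assert summary.n_accuracy == 20


class TestKiHistogram:
    def test_counts_sum_preserved(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(-1, 1, 500)
        counts, edges = ki_histogram(values, bins=20)
        assert counts.sum() == 500
        assert edges[0] == -1.0 and edges[-1] == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ki_histogram([0.5, 1.2], bins=10)
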