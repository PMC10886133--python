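"""Protocol, classifiers, parameter studies, and the rank-ANOVA oracle."""

import numpy as np
import pytest

from gaitfuse import (ClassifierSpec, SimulationConfig, WindowScheme,
                      build_feature_dataset, kruskal_wallis_compare,
                      make_dataset, muscle_group_subset, normalize01,
                      run_experiment, split_train_test, sweep_classifiers,
                      sweep_feature_sets, train_and_classify)
from gaitfuse.segmentation import count_windows


@pytest.fixture(scope="module")
def matrix(dataset):
    return build_feature_dataset(dataset, WindowScheme(170, 20), "R/W/A")


class TestSplit:
    def test_partition(self, matrix):
        train, test = split_train_test(matrix)
        assert train.size + test.size == matrix.n_windows
        assert np.intersect1d(train, test).size == 0

    def test_final_cycle_held_out(self, matrix):
        train, test = split_train_test(matrix)
        for t in np.unique(matrix.trial_ids):
            rows = np.flatnonzero(matrix.trial_ids == t)
            last = matrix.cycle_ids[rows].max()
            test_rows = np.intersect1d(rows, test)
            assert np.all(matrix.cycle_ids[test_rows] == last)

    def test_split_sizes_follow_window_arithmetic(self, dataset, matrix):
        train, test = split_train_test(matrix)
        # per trial: test windows = ceil(count_windows(L,170,20)/2) of the
        # final cycle (decimation keeps every second row trial-wide)
        for t, rec in enumerate(dataset):
            rows = np.flatnonzero(matrix.trial_ids == t)
            L = 2 * (rec.cycle_starts_truth[1] - rec.cycle_starts_truth[0])
            per_cycle = count_windows(int(L), 170, 20)
            n_cycles = rec.cycle_starts_truth.size
            total = per_cycle * n_cycles
            assert rows.size == pytest.approx((total + 1) // 2, abs=2)

    def test_too_few_cycles_rejected(self, dataset):
        cfg = SimulationConfig(n_cycles=3)
        recs = make_dataset(cfg, seed=2)
        m = build_feature_dataset(recs, WindowScheme(170, 20), "R/W/A")
        with pytest.raises(ValueError, match="cycles"):
            split_train_test(m)


class TestTrainAndClassify:
    def test_resubstitution_knn_memorizes(self, matrix):
        m, _, _ = normalize01(matrix)
        train, _ = split_train_test(m)
        sub = m.select_rows(train)
        cm, _ = train_and_classify(
            sub, sub, ClassifierSpec("KNN", {"k": 1}), seed=0)
        assert cm.accuracy == 100.0

    def test_missing_class_rejected(self, matrix):
        m, _, _ = normalize01(matrix)
        train_rows, test_rows = split_train_test(m)
        train = m.select_rows(train_rows[m.labels[train_rows] != 0])
        test = m.select_rows(test_rows)
        with pytest.raises(ValueError, match="absent"):
            train_and_classify(train, test)

    def test_confusion_conservation(self, dataset):
        cm = run_experiment(dataset, seed=1)
        assert cm.counts.sum() == cm.total
        assert np.all(cm.counts >= 0)
        assert cm.accuracy == pytest.approx(
            100.0 * np.trace(cm.counts) / cm.total)
        rows = cm.counts.sum(axis=1)
        diag = np.diag(cm.counts)
        assert np.allclose(cm.per_class_accuracy, 100.0 * diag / rows)

    def test_all_four_algorithms_high_accuracy(self, dataset):
        """The margin-based and instance-based classifiers resolve the
        six classes almost perfectly; the generative/axis-aligned ones
        are weaker on phase-multimodal window clusters but stay far
        above chance."""
        res = sweep_classifiers(dataset, seed=1)
        for algo in ("SVM", "KNN"):
            assert res.accuracies[algo] >= 95.0, res.accuracies
        for algo in ("QDA", "DT"):
            assert res.accuracies[algo] >= 85.0, res.accuracies

    def test_determinism(self, dataset):
        a = run_experiment(dataset, seed=3)
        b = run_experiment(dataset, seed=3)
        assert np.array_equal(a.counts, b.counts)


class TestMuscleGroups:
    @pytest.mark.parametrize("group,n_cols", [
        ("Anterior Thigh", 15), ("Gluteus", 5), ("Thigh", 20),
        ("Calf", 15), ("Posterior Calf", 10)])
    def test_column_counts_rwa(self, matrix, group, n_cols):
        sub = muscle_group_subset(matrix, group)
        assert sub.values.shape[1] == n_cols

    def test_all_is_identity(self, matrix):
        sub = muscle_group_subset(matrix, "All")
        assert sub.values.shape == matrix.values.shape

    def test_unknown_group_rejected(self, matrix):
        with pytest.raises(KeyError):
            muscle_group_subset(matrix, "Forearm")

    def test_subset_columns_match_channels(self, matrix):
        sub = muscle_group_subset(matrix, "Posterior Calf")
        assert sub.channels == ("GAS", "SOL")
        assert all(("GAS" in c) or ("SOL" in c) for c in sub.column_names)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_hand_rank_oracle(self):
        """[1,2,3] vs [7,8,9]: ranks 1-3 and 4-6, so
        H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2) = 27/7."""
        h, p = kruskal_wallis_compare([1, 2, 3], [7, 8, 9])
        assert h == pytest.approx(27.0 / 7.0, rel=1e-12)
        assert 0 < p <= 1

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_compare([1.0], [2.0, 3.0])

    def test_type_one_error_rate(self, rng):
        """Under the null (three groups from one distribution), p < 0.05
        should occur at roughly the nominal rate."""
        hits = 0
        reps = 400
        for _ in range(reps):
            g = rng.standard_normal((3, 8))
            _, p = kruskal_wallis_compare(*g)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.08


class TestSweeps:
    def test_feature_set_sweep_structure(self, dataset):
        res = sweep_feature_sets(dataset, seed=1)
        assert len(res.accuracies) == 15
        assert all(0.0 <= a <= 100.0 for a in res.accuracies.values())

    def test_acc_beats_ssc(self, dataset):
        """Speed information lives in the ACC amplitude; SSC is
        amplitude-invariant, so the ACC set must dominate it."""
        res = sweep_feature_sets(dataset, seed=1)
        assert res.accuracies["ACC"] > res.accuracies["SSC"]

    def test_longer_windows_trend(self):
        """Short windows inflate feature variance: averaged over seeds,
        W=30 must not beat W=170 (non-strict trend)."""
        acc30, acc170 = [], []
        cfg = SimulationConfig()
        for seed in range(1, 11):
            recs = make_dataset(cfg, seed)
            acc30.append(run_experiment(
                recs, WindowScheme(30, 20), seed=seed).accuracy)
            acc170.append(run_experiment(
                recs, WindowScheme(170, 20), seed=seed).accuracy)
        assert np.mean(acc30) <= np.mean(acc170)
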