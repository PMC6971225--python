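"""Tests for the rate-coding decoder against brute-force oracles."""

import numpy as np
import pytest

from neurotouch.decoding import (DecoderConfig, evaluate, knn_classify,
                                 nearest_class_mean, reduce_pca, spike_counts)
from neurotouch.stimulus import TrialSet


def make_trialset(counts, labels, conditions, n_sa=None, duration=1000.0):
    """Build a TrialSet whose per-unit spike counts equal ``counts``."""
    counts = np.asarray(counts)
    n_trials, n_units = counts.shape
    if n_sa is None:
        n_sa = n_units // 2
    types = np.array(["SA"] * n_sa + ["FA"] * (n_units - n_sa))
    spike_times = []
    for i in range(n_trials):
        trial = []
        for u in range(n_units):
            k = int(counts[i, u])
            trial.append(np.linspace(1.0, duration - 1.0, k) if k else
                         np.zeros(0))
        spike_times.append(trial)
    return TrialSet(labels=np.asarray(labels), conditions=np.asarray(conditions),
                    unit_ids=[f"u{i}" for i in range(n_units)],
                    unit_types=types,
                    unit_sensors=np.zeros(n_units, dtype=np.int64),
                    spike_times=spike_times, duration=duration)


def separable_trialset(per_class=10, seed=0):
    """Three well-separated classes over 4 SA + 4 FA units."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for label, base in (("A", 10), ("B", 60), ("C", 140)):
        for _ in range(per_class):
            rows.append(base + rng.integers(0, 4, size=8))
            labels.append(label)
    conditions = np.full(len(labels), 3)
    return make_trialset(np.array(rows), labels, conditions, n_sa=4)


class TestSpikeCounts:

    def test_firing_rate_definition(self):
        ts = make_trialset([[10, 0]], ["A"], [3], n_sa=1, duration=100.0)
        fm = spike_counts(ts, window=(0.0, 100.0))
        assert fm.X[0, 0] == 10
        assert fm.rates()[0, 0] == pytest.approx(100.0)  # 10 spikes / 0.1 s

    def test_empty_raster_gives_zero_row(self):
        ts = make_trialset([[0, 0, 0]], ["A"], [3], n_sa=2)
        assert np.all(spike_counts(ts).X == 0)

    def test_type_filter_selects_columns(self):
        ts = make_trialset([[1, 2, 3, 4]], ["A"], [3], n_sa=3)
        assert spike_counts(ts, type_filter="SA").X.shape == (1, 3)
        assert spike_counts(ts, type_filter="FA").X.shape == (1, 1)
        with pytest.raises(ValueError):
            spike_counts(ts, type_filter="nope")

    def test_window_validation(self):
        ts = make_trialset([[1]], ["A"], [3], n_sa=1, duration=100.0)
        with pytest.raises(ValueError):
            spike_counts(ts, window=(0.0, 200.0))


class TestPca:

    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        direction = np.array([1.0, 2.0, -1.0, 0.5])
        X = np.outer(rng.normal(size=12), direction) + 5.0
        red = reduce_pca(X, n_components=3, normalize=False)
        assert red.explained_variance_ratio[0] == pytest.approx(1.0)
        assert np.allclose(red.scores[:, 1:], 0.0, atol=1e-8)

    def test_rank_three_backprojection_lossless(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3)) @ rng.normal(size=(3, 6))
        red = reduce_pca(X, n_components=3, normalize=False)
        Z = (X - X.mean(axis=0))
        back = red.scores @ red.components
        assert np.allclose(back, Z, atol=1e-8)

    def test_matches_covariance_eigensolve_oracle(self):
        """Scores agree with an independent eigendecomposition."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6)) * rng.uniform(1, 5, size=6)
        red = reduce_pca(X, n_components=3, normalize=True)
        # oracle: z-score, eigensolve the sample covariance, project
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        C = Z.T @ Z / (Z.shape[0] - 1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1][:3]
        V = V[:, order]
        for i in range(3):  # same sign convention
            j = np.argmax(np.abs(V[:, i]))
            if V[j, i] < 0:
                V[:, i] = -V[:, i]
        assert np.allclose(red.scores, Z @ V, atol=1e-8)

    def test_zero_variance_feature_dropped_with_warning(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            red = reduce_pca(X, n_components=1)
        assert red.kept.tolist() == [0]

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            reduce_pca(np.ones((3, 5)))


class TestKnn:

    def test_unanimous_vote(self):
        train = np.zeros((6, 3))
        train[5] = 100.0
        labels = np.array(["A"] * 5 + ["B"])
        pred = knn_classify(train, labels, np.zeros((1, 3)), k=5)
        assert pred.tolist() == ["A"]

    def test_k1_training_point_returns_own_label(self):
        rng = np.random.default_rng(3)
        train = rng.normal(size=(8, 3))
        labels = np.array(list("ABABABAB"))
        pred = knn_classify(train, labels, train, k=1)
        assert pred.tolist() == labels.tolist()

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError):
            knn_classify(np.zeros((3, 2)), np.array(["A"] * 3),
                         np.zeros((1, 2)), k=4)

    def test_matches_bruteforce_oracle(self):
        """Predictions equal an exhaustive distance-scan implementation."""
        rng = np.random.default_rng(4)
        train = rng.normal(size=(30, 3))
        labels = rng.choice(list("ABC"), size=30)
        test = rng.normal(size=(12, 3))
        k = 5

        def oracle(x):
            d = [float(np.sqrt(((x - t) ** 2).sum())) for t in train]
            nn = sorted(range(30), key=lambda i: d[i])[:k]
            votes = {}
            for i in nn:
                votes.setdefault(labels[i], []).append(d[i])
            best = max(len(v) for v in votes.values())
            tied = {c: np.mean(v) for c, v in votes.items() if len(v) == best}
            return min(tied, key=lambda c: (tied[c], c))

        expected = [oracle(x) for x in test]
        assert knn_classify(train, labels, test, k=k).tolist() == expected

    def test_nearest_class_mean(self):
        train = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array(["A", "A", "B", "B"])
        pred = nearest_class_mean(train, labels, np.array([[2.0], [9.0]]))
        assert pred.tolist() == ["A", "B"]


class TestEvaluate:

    def test_perfectly_separable_is_perfect(self):
        trials = separable_trialset()
        report = evaluate(trials, DecoderConfig(seed=0))
        for tf in ("SA", "FA", "both"):
            assert report.accuracy(tf, 3) == 1.0
            assert report.fold_accuracies[(tf, 3)].std() == 0.0

    def test_report_table_shape(self):
        trials = separable_trialset()
        report = evaluate(trials, DecoderConfig(seed=0))
        table = report.to_dataframe()
        assert list(table.index) == ["SA-I", "FA-I", "Both (SA-I and FA-I)"]
        assert list(table.columns) == ["3-finger"]
        assert "%" in table.iloc[0, 0]

    def test_invariant_to_column_order(self):
        trials = separable_trialset()
        perm = np.random.default_rng(5).permutation(trials.n_units)
        shuffled = TrialSet(
            labels=trials.labels, conditions=trials.conditions,
            unit_ids=[trials.unit_ids[i] for i in perm],
            unit_types=trials.unit_types[perm],
            unit_sensors=trials.unit_sensors[perm],
            spike_times=[[tr[i] for i in perm] for tr in trials.spike_times],
            duration=trials.duration)
        a = evaluate(trials, DecoderConfig(seed=0))
        b = evaluate(shuffled, DecoderConfig(seed=0))
        assert a.mean.equals(b.mean)

    def test_invariant_to_common_rescaling(self):
        """Z-score normalization absorbs any common positive count scaling."""
        rng = np.random.default_rng(8)
        counts, labels = [], []
        for label, base in (("A", 5), ("B", 50), ("C", 120)):
            for _ in range(5):
                counts.append(base + rng.integers(0, 6, size=4))
                labels.append(label)
        counts = np.array(counts)
        conds = [3] * len(labels)
        a = evaluate(make_trialset(counts, labels, conds, n_sa=2),
                     DecoderConfig(seed=1))
        b = evaluate(make_trialset(counts * 7, labels, conds, n_sa=2),
                     DecoderConfig(seed=1))
        assert a.mean.equals(b.mean)

    def test_permuted_labels_near_chance(self):
        """Shuffled labels decode at ~1/3 for three balanced classes."""
        trials = separable_trialset(per_class=10)
        rng = np.random.default_rng(6)
        accs = []
        for _ in range(20):
            shuffled = TrialSet(
                labels=rng.permutation(trials.labels),
                conditions=trials.conditions, unit_ids=trials.unit_ids,
                unit_types=trials.unit_types, unit_sensors=trials.unit_sensors,
                spike_times=trials.spike_times, duration=trials.duration)
            report = evaluate(shuffled, DecoderConfig(seed=0))
            accs.append(report.accuracy("both", 3))
        assert 0.20 <= np.mean(accs) <= 0.47

    def test_single_class_rejected(self):
        trials = make_trialset(np.ones((6, 2)), ["A"] * 6, [3] * 6, n_sa=1)
        with pytest.raises(ValueError):
            evaluate(trials)
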