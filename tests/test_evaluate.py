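"""Ground-truth scoring, sorter agreement and autocorrelograms."""
import itertools

import numpy as np
import pytest

from gemsort import (
    GroundTruth,
    PipelineConfig,
    RecordingBlock,
    SortResult,
    agreement_matrix,
    autocorrelogram,
    match_to_ground_truth,
    run_gemsort,
)
from gemsort.evaluate import optimal_assignment


def _truth(times, neurons, homes=None):
    times = np.asarray(times)
    neurons = np.asarray(neurons)
    homes = np.asarray(homes) if homes is not None else np.zeros_like(neurons)
    order = np.argsort(times, kind="stable")
    return GroundTruth(neurons[order], times[order], homes[order])


def _result(times, clusters, channels=None):
    times = np.asarray(times)
    channels = np.asarray(channels) if channels is not None else np.zeros_like(times)
    return SortResult(times, np.asarray(clusters), channels)


class TestMatchToGroundTruth:
    def test_perfect_sorter_scores_one(self, rng):
        times = np.sort(rng.choice(100_000, size=400, replace=False))
        neurons = rng.integers(0, 8, size=400)
        truth = _truth(times, neurons)
        result = _result(times, neurons + 100)  # arbitrary cluster ids
        m = match_to_ground_truth(result, truth)
        assert m.accuracy == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in m.per_neuron.values())

    def test_random_labels_score_one_over_k(self, rng):
        n = 8000
        times = np.arange(n) * 100
        neurons = rng.integers(0, 8, size=n)
        truth = _truth(times, neurons)
        result = _result(times, rng.integers(0, 8, size=n))
        m = match_to_ground_truth(result, truth)
        assert m.accuracy == pytest.approx(1 / 8, abs=0.02)

    def test_accuracy_invariant_under_cluster_relabelling(self, rng):
        times = np.arange(500) * 60
        neurons = rng.integers(0, 4, size=500)
        clusters = rng.integers(0, 5, size=500)
        truth = _truth(times, neurons)
        perm = rng.permutation(5)
        a = match_to_ground_truth(_result(times, clusters), truth).accuracy
        b = match_to_ground_truth(_result(times, perm[clusters]), truth).accuracy
        assert a == pytest.approx(b)

    def test_missed_spikes_count_as_errors(self):
        truth = _truth(np.arange(10) * 1000, np.zeros(10, int))
        result = _result(np.arange(5) * 1000, np.zeros(5, int))
        m = match_to_ground_truth(result, truth)
        assert m.accuracy == pytest.approx(0.5)
        assert m.accuracy_detected == pytest.approx(1.0)

    def test_coincident_events_paired_by_channel(self):
        # two neurons firing at the same instant: the representative on the
        # home channel must claim its own event
        truth = _truth([5000, 5000], [0, 1], homes=[1, 4])
        result = _result([5000, 5001], [10, 20], channels=[1, 4])
        m = match_to_ground_truth(result, truth)
        assert m.accuracy == pytest.approx(1.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            match_to_ground_truth(
                _result([1], [0]), GroundTruth(np.empty(0, int), np.empty(0, int), np.empty(0, int))
            )


class TestOptimalAssignment:
    def test_matches_exhaustive_search(self, rng):
        for _ in range(50):
            conf = rng.integers(0, 30, size=(4, 4))
            _, best = optimal_assignment(conf)
            brute = max(
                sum(conf[i, p[i]] for i in range(4))
                for p in itertools.permutations(range(4))
            )
            assert best == brute

    def test_rectangular_matrix(self):
        conf = np.array([[9, 1], [0, 7], [3, 3]])
        pairs, best = optimal_assignment(conf)
        assert best == 16 and len(pairs) == 2


class TestAgreement:
    def test_self_agreement_is_total(self, rng):
        times = np.sort(rng.choice(50_000, size=300, replace=False))
        res = _result(times, rng.integers(0, 5, size=300))
        agr = agreement_matrix(res, res)
        assert agr.agreement_pct == pytest.approx(100.0)
        off_diag = agr.matrix.to_numpy() - np.diag(np.diag(agr.matrix.to_numpy()))
        assert off_diag.sum() == 0

    def test_shift_beyond_tolerance_unmatches_everything(self, rng):
        times = np.arange(100) * 1000
        res = _result(times, np.zeros(100, int))
        shifted = _result(times + 100, np.zeros(100, int))
        agr = agreement_matrix(res, shifted, time_tol_samples=15)
        assert agr.matrix.to_numpy().sum() == 0
        assert sum(agr.unmatched_a.values()) == 100

    def test_hand_counted_two_by_two(self):
        # A: cluster 0 at t=0,100; cluster 1 at t=200,300
        # B: cluster 5 at t=2,298; cluster 6 at t=101,202
        a = _result([0, 100, 200, 300], [0, 0, 1, 1])
        b = _result([2, 101, 202, 298], [5, 6, 6, 5])
        agr = agreement_matrix(a, b, time_tol_samples=15)
        mat = agr.matrix
        assert mat.loc[0, 5] == 1 and mat.loc[0, 6] == 1
        assert mat.loc[1, 5] == 1 and mat.loc[1, 6] == 1
        assert agr.agreement_pct == pytest.approx(50.0)

    def test_counts_conserved(self, rng):
        ta = np.sort(rng.choice(100_000, 200, replace=False))
        tb = np.sort(rng.choice(100_000, 150, replace=False))
        a = _result(ta, rng.integers(0, 4, 200))
        b = _result(tb, rng.integers(0, 3, 150))
        agr = agreement_matrix(a, b)
        assert agr.matrix.to_numpy().sum() + sum(agr.unmatched_a.values()) == 200
        assert agr.matrix.to_numpy().sum() + sum(agr.unmatched_b.values()) == 150


class TestAutocorrelogram:
    def test_single_spike_all_zero(self):
        _, counts = autocorrelogram(np.array([1000]), bin_ms=1.0, window_ms=20.0)
        assert counts.sum() == 0

    def test_regular_train_peaks_at_multiples_of_period(self):
        times = np.arange(100) * 300  # 10 ms period at 30 kHz
        centers, counts = autocorrelogram(times, bin_ms=1.0, window_ms=25.0)
        nonzero = np.abs(centers[counts > 0])
        dist_to_multiple = np.abs((nonzero + 5.0) % 10.0 - 5.0)
        assert np.all(dist_to_multiple <= 0.51)
        assert counts[np.abs(centers) < 5.0].sum() == 0

    def test_refractory_train_has_empty_centre(self):
        from gemsort import poisson_spike_train

        times = poisson_spike_train(80.0, 60.0, refractory_s=0.002, seed=4)
        centers, counts = autocorrelogram(times, bin_ms=0.5, window_ms=10.0)
        # sample quantisation can shave one sample off the 2 ms dead time
        assert counts[np.abs(centers) < 1.9].sum() == 0
        assert counts.sum() > 0

    def test_symmetric(self):
        times = np.array([0, 70, 400, 1000, 1040])
        _, counts = autocorrelogram(times, bin_ms=1.0, window_ms=40.0)
        assert np.array_equal(counts, counts[::-1])


class TestRunGemsort:
    def test_zero_length_recording(self):
        block = RecordingBlock(np.zeros((16, 0)), 30_000.0)
        result = run_gemsort(block, PipelineConfig())
        assert result.n_spikes == 0

    def test_end_to_end_clusters_cover_all_neurons(self):
        from gemsort import SynthConfig, render_recording

        block, truth = render_recording(SynthConfig(duration_s=30.0, seed=6))
        result = run_gemsort(block, PipelineConfig())
        counts = np.bincount(result.cluster_ids)
        assert (counts >= 50).sum() >= 8
        # ablation configuration also runs end to end
        ablation = run_gemsort(block, PipelineConfig(use_channel_feature=False))
        assert ablation.n_spikes > 0
        assert ablation.params["channel_weight"] == 0.0

    def test_deterministic(self):
        from gemsort import SynthConfig, render_recording

        block, _ = render_recording(SynthConfig(duration_s=10.0, seed=6))
        a = run_gemsort(block, PipelineConfig())
        b = run_gemsort(block, PipelineConfig())
        assert np.array_equal(a.cluster_ids, b.cluster_ids)
        assert np.array_equal(a.peak_samples, b.peak_samples)
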