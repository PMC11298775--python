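"""Scoring sorted spikes against ground truth and against another sorter.

Ground-truth scoring pairs every sorted spike with the nearest unconsumed
true event within a time tolerance, maps clusters to neurons by an optimal
one-to-one assignment on the resulting confusion matrix, and reports the
fraction of ground-truth spikes matched with the correct label (missed
detections therefore count as errors).  Two sorters are compared the same
way, spike coincidence first, then one-to-one cluster agreement.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import GroundTruth, SortResult
from .pipeline import PipelineConfig, run_gemsort  # noqa: F401  (pipeline entry point)


def _pair_by_time(
    times_a: np.ndarray,
    times_b: np.ndarray,
    tol: int,
    chan_a: np.ndarray | None = None,
    chan_b: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Greedy in time order: each A spike consumes the nearest unconsumed B
    spike within ``tol`` samples.  Returns (index_a, index_b) pairs.

    When channel arrays are given, exact time ties (e.g. two neurons firing
    at the same instant) break to the candidate on the nearest channel.
    """
    consumed = np.zeros(times_b.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    lo = 0
    big = 1 << 30
    for ia, t in enumerate(times_a):
        while lo < times_b.size and times_b[lo] < t - tol:
            lo += 1
        best, best_key = -1, (tol + 1, big)
        j = lo
        while j < times_b.size and times_b[j] <= t + tol:
            if not consumed[j]:
                d = abs(int(times_b[j]) - int(t))
                dc = (
                    abs(int(chan_b[j]) - int(chan_a[ia]))
                    if chan_a is not None and chan_b is not None
                    else 0
                )
                if (d, dc) < best_key:
                    best, best_key = j, (d, dc)
            j += 1
        if best >= 0:
            consumed[best] = True
            pairs.append((ia, best))
    return pairs


def optimal_assignment(confusion: np.ndarray) -> tuple[list[tuple[int, int]], int]:
    """Maximum-total one-to-one row/column assignment of a count matrix."""
    confusion = np.asarray(confusion)
    rows, cols = linear_sum_assignment(-confusion)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols)]
    return pairs, int(confusion[rows, cols].sum())


@dataclass
class MatchResult:
    """Outcome of scoring a sort against ground truth."""

    confusion: pd.DataFrame  # clusters x neurons paired-spike counts
    assignment: dict[int, int]  # cluster id -> neuron id
    accuracy: float  # correct / total ground-truth spikes
    accuracy_detected: float  # correct / matched spikes only
    per_neuron: dict[int, float]
    n_matched: int
    n_truth: int


def match_to_ground_truth(
    result: SortResult, truth: GroundTruth, time_tol_samples: int = 15
) -> MatchResult:
    """Score a sort: time pairing, optimal cluster-to-neuron map, accuracy."""
    if truth.n_events == 0:
        raise ValueError("ground truth is empty")
    order = np.argsort(result.peak_samples, kind="stable")
    times = result.peak_samples[order]
    labels = result.cluster_ids[order]
    pairs = _pair_by_time(
        times,
        truth.spike_samples,
        time_tol_samples,
        chan_a=result.channels[order],
        chan_b=truth.home_channels,
    )

    clusters = np.unique(labels) if labels.size else np.empty(0, int)
    neurons = np.arange(truth.n_neurons)
    c_index = {c: i for i, c in enumerate(clusters)}
    conf = np.zeros((clusters.size, neurons.size), dtype=int)
    for ia, ib in pairs:
        conf[c_index[labels[ia]], truth.neuron_ids[ib]] += 1

    if conf.size:
        assign_pairs, correct = optimal_assignment(conf)
        assignment = {int(clusters[r]): int(neurons[c]) for r, c in assign_pairs}
    else:
        assignment, correct = {}, 0
    neuron_counts = np.bincount(truth.neuron_ids, minlength=truth.n_neurons)
    per_neuron = {int(n): 0.0 for n in neurons}
    for cl, n in assignment.items():
        if neuron_counts[n]:
            per_neuron[n] = conf[c_index[cl], n] / neuron_counts[n]
    return MatchResult(
        confusion=pd.DataFrame(conf, index=clusters, columns=neurons),
        assignment=assignment,
        accuracy=correct / truth.n_events,
        accuracy_detected=correct / len(pairs) if pairs else 0.0,
        per_neuron=per_neuron,
        n_matched=len(pairs),
        n_truth=truth.n_events,
    )


@dataclass
class AgreementMatrix:
    """Spike-coincidence counts between the clusters of two sorters."""

    matrix: pd.DataFrame  # clusters of A x clusters of B
    unmatched_a: dict[int, int]
    unmatched_b: dict[int, int]
    agreement_pct: float

    def __post_init__(self) -> None:
        total_a = int(self.matrix.to_numpy().sum() + sum(self.unmatched_a.values()))
        total_b = int(self.matrix.to_numpy().sum() + sum(self.unmatched_b.values()))
        self.total_a, self.total_b = total_a, total_b


def agreement_matrix(
    result_a: SortResult,
    result_b: SortResult,
    time_tol_samples: int = 15,
    min_spikes: int = 0,
) -> AgreementMatrix:
    """Confusion matrix and agreement percentage between two sorters.

    Agreement is the best one-to-one matched diagonal divided by the
    reference (A) spike count, optionally restricted to A clusters holding
    at least ``min_spikes`` spikes.
    """
    oa = np.argsort(result_a.peak_samples, kind="stable")
    ob = np.argsort(result_b.peak_samples, kind="stable")
    ta, la = result_a.peak_samples[oa], result_a.cluster_ids[oa]
    tb, lb = result_b.peak_samples[ob], result_b.cluster_ids[ob]
    pairs = _pair_by_time(ta, tb, time_tol_samples)

    ca = np.unique(la) if la.size else np.empty(0, int)
    cb = np.unique(lb) if lb.size else np.empty(0, int)
    ia = {c: i for i, c in enumerate(ca)}
    ib = {c: i for i, c in enumerate(cb)}
    mat = np.zeros((ca.size, cb.size), dtype=int)
    matched_a = np.zeros(la.size, dtype=bool)
    matched_b = np.zeros(lb.size, dtype=bool)
    for i, j in pairs:
        mat[ia[la[i]], ib[lb[j]]] += 1
        matched_a[i] = True
        matched_b[j] = True
    unmatched_a = {
        int(c): int(np.sum(~matched_a & (la == c))) for c in ca
    }
    unmatched_b = {
        int(c): int(np.sum(~matched_b & (lb == c))) for c in cb
    }

    counts_a = {int(c): int(np.sum(la == c)) for c in ca}
    keep = [i for i, c in enumerate(ca) if counts_a[int(c)] >= min_spikes]
    total_ref = sum(counts_a[int(ca[i])] for i in keep)
    if keep and cb.size:
        _, best = optimal_assignment(mat[keep, :])
        agreement = 100.0 * best / total_ref if total_ref else 0.0
    else:
        agreement = 0.0
    return AgreementMatrix(
        matrix=pd.DataFrame(mat, index=ca, columns=cb),
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        agreement_pct=agreement,
    )


def autocorrelogram(
    spike_times: np.ndarray,
    bin_ms: float = 0.5,
    window_ms: float = 25.0,
    sample_rate_hz: float = 30_000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pairwise spike-time differences within +-window.

    Zero-lag self-pairs are excluded; the histogram is symmetric.  Returns
    (bin centres in ms, counts).
    """
    t = np.sort(np.asarray(spike_times, dtype=float)) / sample_rate_hz * 1000.0
    n_bins = int(np.ceil(window_ms / bin_ms))
    # bin unordered pairs by |lag| and mirror, so the histogram is exactly
    # symmetric even for lags landing on bin edges
    pos = np.zeros(n_bins, dtype=int)
    for i in range(t.size):
        j = i + 1
        while j < t.size and t[j] - t[i] <= window_ms:
            k = int(np.floor((t[j] - t[i]) / bin_ms))
            if k < n_bins:
                pos[k] += 1
            j += 1
    counts = np.concatenate([pos[::-1], pos])
    edges = np.arange(-n_bins, n_bins + 1) * bin_ms
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts
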