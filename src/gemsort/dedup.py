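"""Duplicate-spike elimination across adjacent channels.

On a densely spaced probe one action potential is registered by several
neighbouring channels at the same instant (extracellular potentials
propagate effectively instantaneously).  Events with coincident peak
times, on channels within a small adjacency radius, whose waveforms
correlate above a threshold are collapsed into one group; the member with
the highest peak amplitude represents the group and the rest are
discarded.  Coincident but physically remote events are kept separate --
they are different neurons that happen to share a temporal shape.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import SpikeEvent


@dataclass
class DedupConfig:
    r_th: float = 0.6
    coincidence_tol_samples: int = 10  # ~0.33 ms at 30 kHz; covers lobe hopping
    adjacency_radius: int = 8  # ~160 um at 20 um pitch
    support_half_samples: int | None = 15  # correlate over seed peak ±0.5 ms

    def __post_init__(self) -> None:
        if not 0.0 < self.r_th < 1.0:
            raise ValueError("r_th must lie in (0, 1)")
        if self.coincidence_tol_samples < 0 or self.adjacency_radius < 0:
            raise ValueError("tolerances must be >= 0")


def pearson_r(waveform_a: np.ndarray, waveform_b: np.ndarray) -> float:
    """Sample Pearson correlation; a constant waveform gives r = 0 with a warning."""
    a = np.asarray(waveform_a, dtype=float)
    b = np.asarray(waveform_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("waveforms must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant waveform in correlation; returning r = 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def time_locked_r(a: SpikeEvent, b: SpikeEvent, support_half: int | None = None) -> float:
    """Pearson r between two windows compared at their true relative lag.

    Duplicates of one action potential are time-locked across channels, so
    the two windows are overlapped at the offset of their absolute peak
    times rather than re-aligned on their own extrema (whose position can
    hop between lobes of a multiphasic waveform under noise).

    ``support_half`` restricts the comparison to ±that many samples around
    the first event's peak; the signal-free window tails otherwise dilute
    the correlation of a weak duplicate toward zero.
    """
    lag = b.peak_sample - a.peak_sample
    n = a.waveform.size
    if b.waveform.size != n:
        raise ValueError("waveforms must have equal length")
    if abs(lag) >= n:
        return 0.0
    lo, hi = max(0, lag), n + min(0, lag)
    if support_half is not None:
        lo, hi = max(lo, n // 2 - support_half), min(hi, n // 2 + support_half)
    if hi - lo < 4:
        return 0.0
    return pearson_r(a.waveform[lo:hi], b.waveform[lo - lag : hi - lag])


@dataclass
class DuplicateGroup:
    """A set of coincident, adjacent, correlated events and its representative."""

    members: list[SpikeEvent] = field(default_factory=list)

    @property
    def representative(self) -> SpikeEvent:
        return select_representative(self.members)

    def __len__(self) -> int:
        return len(self.members)


def select_representative(members: list[SpikeEvent]) -> SpikeEvent:
    """The member with the highest peak amplitude; ties break to the lowest channel."""
    if not members:
        raise ValueError("empty duplicate group")
    return min(members, key=lambda e: (-e.peak_amplitude, e.channel))


def group_duplicates(
    events: list[SpikeEvent], cfg: DedupConfig | None = None
) -> list[DuplicateGroup]:
    """Greedy grouping of time-sorted events, strongest seeds first.

    Ungrouped events are visited in order of descending peak amplitude;
    each seeds a group and absorbs every still-ungrouped event within the
    coincidence tolerance on either side, within the channel adjacency
    radius of the seed, and correlating with the seed above ``r_th``
    (compared time-locked at the true peak-time lag).  Seeding on the
    strongest copy centres the adjacency radius on the channel nearest the
    firing neuron, so one spike's duplicates collapse into one group no
    matter which channel happened to cross threshold first.  Every event
    lands in exactly one group.
    """
    cfg = cfg or DedupConfig()
    n = len(events)
    grouped = np.zeros(n, dtype=bool)
    groups: list[DuplicateGroup] = []
    peaks = np.array([e.peak_sample for e in events])
    if np.any(np.diff(peaks) < 0):
        raise ValueError("events must be time-sorted")
    by_amplitude = sorted(
        range(n), key=lambda i: (-events[i].peak_amplitude, events[i].channel, i)
    )
    for i in by_amplitude:
        if grouped[i]:
            continue
        seed = events[i]
        grouped[i] = True
        members = [seed]
        lo = int(np.searchsorted(peaks, seed.peak_sample - cfg.coincidence_tol_samples))
        hi = int(
            np.searchsorted(peaks, seed.peak_sample + cfg.coincidence_tol_samples, "right")
        )
        for j in range(lo, hi):
            if (
                not grouped[j]
                and abs(events[j].channel - seed.channel) <= cfg.adjacency_radius
                and time_locked_r(seed, events[j], cfg.support_half_samples) > cfg.r_th
            ):
                grouped[j] = True
                members.append(events[j])
        groups.append(DuplicateGroup(members))
    groups.sort(key=lambda g: (g.representative.peak_sample, g.representative.channel))
    return _rescue_singletons(groups, cfg)


def _rescue_singletons(
    groups: list[DuplicateGroup], cfg: DedupConfig
) -> list[DuplicateGroup]:
    """Second pass: fold leftover single-event groups into a coincident,
    adjacent group whose representative they correlate with.

    A weak duplicate can miss its group when its home-channel partner was
    already claimed by an earlier seed; comparing against the group's
    (high-amplitude) representative gives a cleaner correlation.
    """
    reps = [g.representative for g in groups]
    order = sorted(range(len(groups)), key=lambda k: reps[k].peak_sample)
    rep_times = np.array([reps[k].peak_sample for k in order])
    absorbed: set[int] = set()
    for k, group in enumerate(groups):
        if len(group) != 1:
            continue
        lone = group.members[0]
        lo = np.searchsorted(rep_times, lone.peak_sample - cfg.coincidence_tol_samples)
        hi = np.searchsorted(rep_times, lone.peak_sample + cfg.coincidence_tol_samples, "right")
        best, best_amp = None, -np.inf
        for idx in order[lo:hi]:
            if idx == k or idx in absorbed or len(groups[idx]) == 0:
                continue
            rep = reps[idx]
            if (
                rep.peak_amplitude > max(best_amp, lone.peak_amplitude)
                and abs(rep.channel - lone.channel) <= cfg.adjacency_radius
                and time_locked_r(rep, lone, cfg.support_half_samples) > cfg.r_th
            ):
                best, best_amp = idx, rep.peak_amplitude
        if best is not None:
            groups[best].members.append(lone)
            absorbed.add(k)
            group.members.clear()
    return [g for g in groups if len(g)]


def deduplicate(
    events: list[SpikeEvent], cfg: DedupConfig | None = None
) -> tuple[list[SpikeEvent], list[DuplicateGroup]]:
    """Collapse duplicates; returns (time-sorted representatives, groups)."""
    groups = group_duplicates(events, cfg)
    reps = [g.representative for g in groups]
    reps.sort(key=lambda e: (e.peak_sample, e.channel))
    return reps, groups
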