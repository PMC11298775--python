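"""Core data containers shared across the sorting pipeline.

These are deliberately thin: numpy arrays plus the minimal metadata each
stage needs.  Heavier provenance (configs, seeds) rides on ``SortResult``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class RecordingBlock:
    """A multichannel extracellular voltage block.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage traces, one row per channel, in signal units.
    sample_rate_hz : float
        Sampling rate, > 0.  30 kHz is the usual probe rate.
    channel_ids : ndarray of int, optional
        Channel labels in physical order along the shank.  Adjacency in
        index equals adjacency on the probe.  Defaults to ``arange``.
    """

    samples: np.ndarray
    sample_rate_hz: float
    channel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) matrix")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.samples.shape[0])
        else:
            self.channel_ids = np.asarray(self.channel_ids, dtype=int)
            if self.channel_ids.shape[0] != self.samples.shape[0]:
                raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def copy_with(self, samples: np.ndarray) -> "RecordingBlock":
        return RecordingBlock(samples, self.sample_rate_hz, self.channel_ids.copy())


@dataclass
class SpikeEvent:
    """One isolated waveform window on one channel.

    ``peak_sample`` is the absolute sample index of the extremum of
    ``|waveform|`` and ``peak_amplitude = max(|waveform|)``.
    """

    channel: int
    peak_sample: int
    waveform: np.ndarray
    peak_amplitude: float

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)


@dataclass
class GroundTruth:
    """Exact event list of a synthetic recording.

    events are stored as parallel arrays sorted by spike time; templates
    are the unit-peak waveforms, one per neuron.
    """

    neuron_ids: np.ndarray
    spike_samples: np.ndarray
    home_channels: np.ndarray
    templates: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)
        self.spike_samples = np.asarray(self.spike_samples, dtype=int)
        self.home_channels = np.asarray(self.home_channels, dtype=int)
        if not (
            self.neuron_ids.shape == self.spike_samples.shape == self.home_channels.shape
        ):
            raise ValueError("ground-truth event arrays must have equal length")
        if np.any(np.diff(self.spike_samples) < 0):
            raise ValueError("ground-truth events must be sorted by time")

    @property
    def n_events(self) -> int:
        return self.neuron_ids.size

    @property
    def n_neurons(self) -> int:
        return int(self.neuron_ids.max()) + 1 if self.n_events else 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "spike_sample": self.spike_samples,
                "home_channel": self.home_channels,
            }
        )


@dataclass
class SortResult:
    """Stream of (spike time, cluster id, channel) sorting records."""

    peak_samples: np.ndarray
    cluster_ids: np.ndarray
    channels: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.peak_samples = np.asarray(self.peak_samples, dtype=int)
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)
        self.channels = np.asarray(self.channels, dtype=int)
        if not (
            self.peak_samples.shape == self.cluster_ids.shape == self.channels.shape
        ):
            raise ValueError("sort-result arrays must have equal length")

    @property
    def n_spikes(self) -> int:
        return self.peak_samples.size

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.cluster_ids[self.cluster_ids >= 0]).size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_sample": self.peak_samples,
                "cluster_id": self.cluster_ids,
                "channel": self.channels,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs: Any) -> "SortResult":
        return cls(
            df["peak_sample"].to_numpy(),
            df["cluster_id"].to_numpy(),
            df["channel"].to_numpy(),
            **kwargs,
        )
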