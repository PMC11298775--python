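"""Per-channel threshold detection of spikes on filtered voltages.

The channel noise level sigma_c is estimated robustly as
median(|v|)/0.6745 (the classic median-based noise estimator, immune to
the spikes themselves), and any excursion of |v| beyond k*sigma_c (k = 5
by default) yields one waveform window centred on the local extremum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import RecordingBlock, SpikeEvent

MAD_SCALE = 0.6745  # median(|N(0,1)|)


@dataclass
class ThresholdConfig:
    k_sigma: float = 5.0
    window_samples: int = 60
    dead_time_samples: int = 45  # 1.5 ms: covers the trailing lobes of the widest templates

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.window_samples % 2 or self.window_samples <= 0:
            raise ValueError("window_samples must be a positive even number")
        if self.dead_time_samples < 0:
            raise ValueError("dead_time_samples must be >= 0")


def estimate_sigma(channel_trace: np.ndarray) -> float:
    """Robust noise SD of one trace: median(|v|) / 0.6745."""
    trace = np.asarray(channel_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace must be non-empty")
    return float(np.median(np.abs(trace)) / MAD_SCALE)


def _extract_window(trace: np.ndarray, peak: int, width: int) -> np.ndarray:
    """Window of ``width`` samples centred on ``peak``, zero-padded at edges."""
    half = width // 2
    lo, hi = peak - half, peak - half + width
    out = np.zeros(width)
    s_lo, s_hi = max(lo, 0), min(hi, trace.size)
    out[s_lo - lo : s_hi - lo] = trace[s_lo:s_hi]
    return out


def detect_spikes(block: RecordingBlock, cfg: ThresholdConfig | None = None) -> list[SpikeEvent]:
    """Threshold crossings of |v| > k*sigma_c on every channel.

    Each crossing is refined to the local extremum of |v| within one dead
    time, a fixed-width window is cut centred there, and further crossings
    within the dead time on the same channel are suppressed.  Events are
    returned time-sorted across channels.
    """
    cfg = cfg or ThresholdConfig()
    if cfg.window_samples > block.n_samples:
        raise ValueError("window_samples exceeds the trace length")
    events: list[SpikeEvent] = []
    for ci in range(block.n_channels):
        trace = block.samples[ci]
        sigma = estimate_sigma(trace)
        if sigma == 0.0:
            warnings.warn(
                f"channel {ci}: zero noise estimate, channel disabled", stacklevel=2
            )
            continue
        thr = cfg.k_sigma * sigma
        above = np.flatnonzero(np.abs(trace) > thr)
        next_allowed = 0
        for idx in above:
            if idx < next_allowed:
                continue
            # localise the extremum, then re-centre once on the window max
            seg_hi = min(idx + cfg.dead_time_samples + 1, trace.size)
            peak = idx + int(np.argmax(np.abs(trace[idx:seg_hi])))
            win = _extract_window(trace, peak, cfg.window_samples)
            shift = int(np.argmax(np.abs(win))) - cfg.window_samples // 2
            if shift:
                peak += shift
                win = _extract_window(trace, peak, cfg.window_samples)
            events.append(
                SpikeEvent(
                    channel=int(block.channel_ids[ci]),
                    peak_sample=int(peak),
                    waveform=win,
                    peak_amplitude=float(np.abs(trace[peak])),
                )
            )
            next_allowed = peak + cfg.dead_time_samples + 1
    events.sort(key=lambda e: (e.peak_sample, e.channel))
    return events
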