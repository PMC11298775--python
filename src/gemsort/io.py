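"""Plain-text / flat-binary persistence for recordings and results.

Recordings travel as flat binary interleaved int16 (sample-major: frame of
all channels per time point) next to a JSON sidecar holding the channel
count, sampling rate and the int16 scale factor.  Ground truth and sort
results are CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GroundTruth, RecordingBlock, SortResult

SIDECAR_SUFFIX = ".json"
BINARY_SUFFIX = ".bin"


def write_recording(prefix: str | Path, block: RecordingBlock) -> tuple[Path, Path]:
    """Write ``<prefix>.bin`` (int16, channel-interleaved) and ``<prefix>.json``."""
    prefix = Path(prefix)
    peak = float(np.max(np.abs(block.samples))) if block.n_samples else 1.0
    scale = 32000.0 / peak if peak > 0 else 1.0
    data = np.round(block.samples.T * scale).astype(np.int16)  # (time, channel)
    bin_path = prefix.with_suffix(BINARY_SUFFIX)
    sidecar_path = prefix.with_suffix(SIDECAR_SUFFIX)
    data.tofile(bin_path)
    sidecar_path.write_text(
        json.dumps(
            {
                "n_channels": block.n_channels,
                "sample_rate_hz": block.sample_rate_hz,
                "scale": scale,
                "dtype": "int16",
                "order": "time_major_channel_interleaved",
            },
            indent=2,
        )
    )
    return bin_path, sidecar_path


def read_recording(prefix: str | Path) -> RecordingBlock:
    """Read a recording written by :func:`write_recording`."""
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(SIDECAR_SUFFIX).read_text())
    raw = np.fromfile(prefix.with_suffix(BINARY_SUFFIX), dtype=np.int16)
    n_ch = int(sidecar["n_channels"])
    samples = raw.reshape(-1, n_ch).T.astype(float) / float(sidecar["scale"])
    return RecordingBlock(samples, float(sidecar["sample_rate_hz"]))


def write_ground_truth(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    truth.to_dataframe().to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    return GroundTruth(
        df["neuron_id"].to_numpy(),
        df["spike_sample"].to_numpy(),
        df["home_channel"].to_numpy(),
    )


def write_sort_result(path: str | Path, result: SortResult) -> Path:
    path = Path(path)
    result.to_dataframe().to_csv(path, index=False)
    return path


def read_sort_result(path: str | Path) -> SortResult:
    return SortResult.from_dataframe(pd.read_csv(path))
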