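"""End-to-end sorting pipeline: filter -> detect -> deduplicate -> feature
extraction -> graph clustering.

``run_gemsort`` wires the stages together with one configuration object
and logs per-stage counts; everything downstream of the raw voltages is
deterministic, so a given recording and configuration always produce the
same :class:`~gemsort.core.SortResult`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import RecordingBlock, SortResult
from .dedup import DedupConfig, deduplicate
from .detect import ThresholdConfig, detect_spikes
from .features import build_feature, fit_pca, project
from .gng import GngParams, Graph, sort_stream
from .preprocess import LcarConfig, highpass, lcar

logger = logging.getLogger("gemsort")


@dataclass
class PipelineConfig:
    """Configuration of the full sorting pipeline."""

    highpass_cutoff_hz: float = 300.0
    highpass_order: int = 2
    lcar: LcarConfig = field(default_factory=LcarConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    dedup: DedupConfig = field(default_factory=DedupConfig)
    n_components: int = 2
    channel_weight: float = 1.0
    use_channel_feature: bool = True
    pca_training_spikes: int = 600
    pca_training_max_s: float = 15.0
    gng: GngParams | None = None  # None: node budget of 12 per channel
    gng_warm_passes: int = 2
    seed: int = 0

    def gng_params(self, n_channels: int) -> GngParams:
        if self.gng is not None:
            return self.gng
        return GngParams(max_nodes=12 * n_channels)


def run_gemsort(block: RecordingBlock, config: PipelineConfig | None = None) -> SortResult:
    """Sort a raw multichannel recording; returns the spike/cluster stream.

    Stages: zero-phase Butterworth high-pass, local common average
    referencing, 5-sigma threshold detection, duplicate-spike elimination,
    PCA (trained on the initial batch of representatives) plus the channel
    positional feature, and growing-neural-gas stream clustering.
    """
    config = config or PipelineConfig()
    empty = SortResult(
        np.empty(0, int), np.empty(0, int), np.empty(0, int),
        params={"config": repr(config)}, seed=config.seed,
    )
    if block.n_samples == 0:
        return empty
    try:
        filtered = highpass(block, config.highpass_cutoff_hz, config.highpass_order)
        filtered = lcar(filtered, config.lcar)
    except ValueError as err:
        raise ValueError(f"preprocess stage failed: {err}") from err

    try:
        events = detect_spikes(filtered, config.threshold)
    except ValueError as err:
        raise ValueError(f"detect stage failed: {err}") from err
    logger.info("detected %d threshold events", len(events))
    if not events:
        return empty

    reps, groups = deduplicate(events, config.dedup)
    logger.info(
        "collapsed %d events into %d representatives (%d duplicates discarded)",
        len(events), len(reps), len(events) - len(reps),
    )

    max_train_sample = int(config.pca_training_max_s * block.sample_rate_hz)
    training = [r for r in reps if r.peak_sample < max_train_sample]
    training = training[: config.pca_training_spikes] or reps[: config.pca_training_spikes]
    try:
        basis = fit_pca(training, config.n_components)
    except ValueError as err:
        raise ValueError(f"features stage failed: {err}") from err

    weight = config.channel_weight if config.use_channel_feature else 0.0
    feats = [
        build_feature(
            r,
            project(r, basis),
            channel_weight=weight,
            coeff_scale=basis.coeff_scale,
            allow_zero_weight=not config.use_channel_feature,
        )
        for r in reps
    ]

    params = config.gng_params(block.n_channels)
    graph = Graph(params)
    # warm-start the graph on the same initial batch that trained the PCA
    # basis (those spikes are retained for training anyway), then classify
    # the full stream, training batch included, against the warmed graph
    for _ in range(config.gng_warm_passes):
        sort_stream(feats[: len(training)], params, graph)
    result = sort_stream(feats, params, graph)
    logger.info("sorted %d representatives into %d clusters", result.n_spikes, result.n_clusters)
    result.params = {
        "channel_weight": weight,
        "use_channel_feature": config.use_channel_feature,
        "gng": params.__dict__.copy(),
        "n_events_detected": len(events),
        "n_representatives": len(reps),
    }
    result.seed = config.seed
    return result
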