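# gemsort

Streaming spike sorting for densely spaced multichannel extracellular
probes, with a synthetic benchmark generator and evaluation tooling.

## The problem

A dense linear probe (20 µm pitch, Neuropixels-style) records every action
potential on several neighbouring channels at once, and neurons with
similar waveforms at different depths produce near-identical spike shapes.
Post-hoc sorters resolve this with global optimisation over the whole
recording; that rules out low-latency use. `gemsort` targets the streaming
regime: each spike is processed once, classified immediately, and then
discarded, with memory bounded by a fixed node budget.

Two ideas carry the design:

* **Duplicate-spike elimination.** Extracellular potentials propagate
  effectively instantaneously, so the copies of one spike are time-locked
  across channels. Events that coincide (±0.33 ms), sit within 8 channels
  of each other, and correlate above `r_TH = 0.6` are collapsed to the
  single highest-amplitude copy. This both removes over-counting and cuts
  the downstream workload several-fold.
* **A positional feature.** The channel index of the surviving
  representative is appended to its two PCA waveform coefficients,
  `x_i = {c_i, a_0, a_1}`, so identical waveforms recorded at different
  probe locations become separable.

Feature vectors stream into a growing-neural-gas graph: nodes move toward
incoming spikes (`W1 ← W1 + e_s1 (x − W1)`, neighbours by `e_nbr`), edges
connect co-winning nodes and age out when unused, and the connected
components of the graph are the clusters. Each spike is emitted as
`(peak time, cluster id, channel)`.

The package also ships the synthetic 16-channel, 8-neuron recording
generator used for benchmarking (Poisson trains, four wavelet-shaped
templates, 1/(4πσr) distance attenuation, Gaussian noise) with exact
ground truth, plus ground-truth scoring and two-sorter agreement matrices.
See `docs/methods.md` for the full model description and design notes.

## Worked example

```python
from gemsort import (PipelineConfig, SynthConfig, match_to_ground_truth,
                     render_recording, run_gemsort)

block, truth = render_recording(SynthConfig(duration_s=60.0, seed=1))
result = run_gemsort(block, PipelineConfig())
match = match_to_ground_truth(result, truth)
print(f"spikes sorted: {result.n_spikes}, ground truth: {truth.n_events}")
print(f"overall accuracy: {match.accuracy:.4f}")

ablation = run_gemsort(block, PipelineConfig(use_channel_feature=False))
print(f"without channel feature: {match_to_ground_truth(ablation, truth).accuracy:.4f}")
```

prints

```
spikes sorted: 2478, ground truth: 2477
overall accuracy: 0.9806
without channel feature: 0.8066
```

The 60 s recording holds ~2500 true spikes; after duplicate elimination
the sorter emits about one representative per true spike. With the channel
feature the one-to-one cluster/neuron matching recovers ~98% of spikes on
this seed; removing the positional feature collapses the two same-family
neuron pairs into shared clusters and costs ~17 percentage points — the
ablation the channel feature exists to prevent.

The same pipeline is available from the shell:

```bash
gemsort synth --scenario general --duration 60 --seed 1 --out rec
gemsort sort rec --out sorted.csv
gemsort eval sorted.csv rec.truth.csv
gemsort agree sorted.csv other_sorter.csv
```

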