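# Methods

`gemsort` implements a streaming spike sorter for densely spaced
multichannel extracellular probes, together with a synthetic recording
generator that provides exact ground truth and the evaluation tooling to
score sorting output. This note documents the model, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## The sorting pipeline

Raw voltages `v_c(t)` (channels × samples, 30 kHz by default) pass through
five stages, each exposed as its own module and composed by
`gemsort.run_gemsort`:

1. **High-pass filtering** (`preprocess.highpass`). A 2nd-order Butterworth
   high-pass with a 300 Hz cut-off removes LFP and drift. It is applied
   forward–backward (zero phase): peak times must not shift, because
   duplicate elimination later relies on spikes being time-locked across
   channels. Zero-phase application squares the magnitude response, so the
   realised attenuation at 300 Hz is 6 dB; the designed single-pass 3 dB
   point is at 300 Hz and is what `butter_highpass_response` reports.

2. **Local common average referencing** (`preprocess.lcar`). For channel
   `c` the mean of the channels at offsets `N_near/2 … N_far/2` on each
   side is subtracted, cancelling noise that is spatially correlated across
   the shank. Defaults are `N_near = 8`, `N_far = 16` (offsets 4–8):
   with 20 µm pitch and 1/r attenuation a spike is still clearly audible
   two or three channels away, so a nearer band would subtract the spike
   itself and deflate amplitudes by ~15%. At the array edges the missing
   half-band is treated as contributing zero — the sum is still divided by
   the full two-sided band size. Renormalising by the surviving channel
   count instead would double the weight of the surviving half-band and
   fold any neuron inside it into the reference at high gain, producing
   large inverted "ghost" spikes on edge channels.

3. **Threshold detection** (`detect`). The per-channel noise level is the
   robust estimate `sigma_c = median(|v|)/0.6745`, immune to the spikes
   themselves; the threshold is `5 sigma_c`. Detection operates on `|v|`
   (both polarities). Each crossing is refined to the local extremum
   within one dead time (1.5 ms — long enough to cover the trailing lobes
   of the widest templates), a 60-sample window is cut centred on the
   extremum, and further crossings inside the dead time are suppressed.

4. **Duplicate elimination** (`dedup`). One action potential registers on
   several neighbouring channels at effectively the same instant, because
   extracellular potentials propagate electromagnetically. Events are
   therefore grouped when they (i) coincide within 10 samples (~0.33 ms),
   (ii) lie within 8 channels of the group seed, and (iii) correlate with
   the seed above `r_TH = 0.6`. Three details matter:

   * Seeds are visited in order of *descending amplitude*, so the
     adjacency radius is centred on the channel nearest the neuron; a
     first-in-time seed on the edge of the footprint splits groups.
   * Waveforms are compared *time-locked*: the two windows are overlapped
     at the lag of their absolute peak times, never re-aligned on their
     own extrema. The extremum of a multiphasic waveform hops between
     lobes under noise; re-alignment then anti-correlates true duplicates.
   * The correlation is evaluated over the seed's central ±0.5 ms only.
     The signal-free window tails otherwise dilute a weak duplicate's
     correlation to just under the 0.6 threshold.

   The group member with the highest peak amplitude represents the group
   (ties to the lower channel index); all other members are discarded. A
   second pass folds leftover single-event groups into a coincident
   adjacent group whose representative they correlate with.

5. **Features and clustering** (`features`, `gng`). A PCA basis is trained
   once on the first 600 representatives (or the first 15 s, whichever is
   smaller) and frozen; every representative is projected onto the first
   two components. Windows are first aligned to sub-sample precision
   (parabolic interpolation of the extremum): the ±1-sample discrete
   jitter otherwise dominates the within-cluster spread for narrow or
   oscillatory spikes. Coefficients are standardised by their training
   SDs, and the recording-channel index, scaled by `channel_weight`
   (default 1.0), is prepended — the positional feature that separates
   similar-shaped spikes from different probe locations. Setting
   `use_channel_feature=False` reproduces the shape-only ablation.

## The graph clusterer

Feature vectors stream through a growing-neural-gas graph. Each spike:
finds its two nearest nodes `W1, W2`; adds `d1²` to `W1`'s error; moves
`W1` by `e_s1 = 0.8` and `W1`'s edge neighbours by `e_nbr = 0.001` toward
the spike; refreshes the `W1–W2` edge; ages `W1`'s other edges and prunes
those older than `a_th = 8` (nodes left edgeless are deleted); and every
`λ = 10` spikes a node is inserted halfway between the highest-error node
and its highest-error *same-cluster* neighbour, splitting the parent's
error by `α = 0.5` and decaying all errors by `β = 0.01`. The node budget
is 12 per channel. Connected components of the graph are the clusters; no
spike is retained after classification, so memory is bounded by the node
budget regardless of recording length.

Large moving rates make the raw component structure churn: nodes pile onto
cluster centres, win spikes essentially at random within a pile, and an
edge's age only advances when its own endpoint wins — so a spurious edge
between two busy clusters can survive for hundreds of spikes. Four
stabilising mechanisms keep cluster *identity* well defined through this
churn; they are this implementation's design (the upstream variant's exact
step order is not published) and are the main place it may differ from
other growing-neural-gas codes:

* **Persistent labels.** Every node carries a cluster label. Labels are
  inherited at insertion, minted only when a cluster genuinely fissions,
  re-homogenised per side whenever a component splits (each side takes its
  own majority; if both majorities coincide, the smaller side is minted a
  fresh name), and never rewritten on a merge. A spike is named by the
  majority label among the component nodes near it. Consequently a brief
  bridge between two clusters renames neither, and node turnover does not
  change a cluster's name.
* **Stale-node deletion.** Nodes that have not won a spike for 400 steps
  are removed: spikes stopped arriving in their region, either because the
  cluster drifted away or because the node was parked between clusters.
* **Outlier gating.** A running, outlier-clipped average of the
  nearest-node distance defines the typical spike–node distance. A spike
  farther than 3× that scale (an overlapping-spike distortion or noise
  event) is classified but adapts nothing; a `W1–W2` edge is only created
  when `W2` is within the same bound. Without the gate, single outliers
  falling between clusters wire them together.
* **Warm start.** The graph is pre-trained with 2 passes over the same
  initial batch that trains the PCA basis (those spikes are already
  retained for PCA), then the full stream — training batch included — is
  classified against the warmed graph. This removes most of the cold-start
  mislabelling without breaking the streaming contract.

A distance-based reject class (`reject_distance`) is exposed but off by
default: every spike is assigned to the cluster of its nearest node.

## Scoring

`evaluate.match_to_ground_truth` pairs each sorted spike greedily (in time
order) with the nearest unconsumed ground-truth event within ±0.5 ms;
exact time ties — two neurons firing at the same instant — break to the
event whose home channel is nearest the spike's channel. Clusters are then
mapped one-to-one onto neurons by maximising the total matched spikes
(Hungarian assignment on the confusion matrix). The headline accuracy
divides correctly labelled matches by the *total* ground-truth count, so
missed detections count as errors; `accuracy_detected` conditions on
matched spikes only and is reported alongside. Accuracy is invariant to
cluster renaming. `evaluate.agreement_matrix` applies the same pairing
between two sorters and reports the best one-to-one matched fraction of
the reference sorter's spikes. `evaluate.autocorrelogram` histograms
pairwise lags (zero-lag self-pairs excluded) — an empty centre within the
refractory period is the standard single-unit sanity check.

## The synthetic benchmark

`synth.render_recording` emulates a 16-channel, 20-µm-pitch linear probe
with 8 neurons placed 10 µm lateral to channels 0, 3, 5, 7, 9, 11, 13, 15.
Each neuron fires a Poisson train (2 ms absolute refractory period) with
per-neuron rates of 2.5–8 Hz, chosen so a 60 s recording holds ~2400
events, the scale of the published benchmark. Spike shapes come from four
wavelet families — gaussian, ricker, biorthogonal (bior2.6) and Daubechies
(db4), the latter two resampled from their mother wavelets — each family
used by exactly two neurons with slightly different widths. Every spike is
added to all channels with the point-source gain `V(r) = 1/(4πσr)`
(σ = 0.35, r in µm), normalised so the home-channel peak equals the
configured amplitude, and i.i.d. Gaussian noise of variance 0.02 is added
last. Rendering is a pure superposition with a full determinism contract
(same seed, same bits).

Peak amplitudes span 6.5–14 noise SDs. Two deliberate structures are built
in: the two same-family pairs (gaussian, ricker) have nearly equal
amplitudes, so their clusters genuinely overlap when only shape features
are used — this is what the channel-feature ablation measures — while the
other two pairs are amplitude-separated. One neuron sits close to the
detection threshold, giving a realistically weak unit. The lower end of
the amplitude range stops at 6.5 SDs because a 5-SD unit would sit at the
detection threshold itself and its ground truth would be undetectable by
construction. Shape constants were fixed once so that all four families
remain mutually distinguishable (pairwise r < 0.6 after filtering).

Three scenarios probe specific failure modes: `simultaneous` forces two
neurons (home channels 1 and 4, distinct families) to share identical
spike times; `similar_shapes` gives two neurons the same family with
near-identical width (template correlation > 0.95) on well-separated
channels; `unrestricted` shuffles a balanced family assignment (each
family twice) with uniformly jittered widths as a control.

### What the benchmark does not show

The generator produces stereotyped, stationary templates, additive white
noise, a strictly linear 1-D probe geometry, and no electrode drift, no
bursting amplitude adaptation, and no biophysical waveform variability.
Passing the benchmark demonstrates the pipeline's bookkeeping — duplicate
collapse, positional separation, streaming cluster identity — under the
stated conditions; it does not certify accuracy on real recordings, where
overlap resolution (explicitly out of scope here) and drift dominate.
Spatiotemporally overlapping spikes are treated as outliers or
misclassified, never resolved into their constituents.

The duplicate-conservation check runs on high-pass-only data. On an
essentially noise-free recording the L-CAR reference subtracts scaled
copies of the spikes themselves, creating anti-correlated ghost events
that the `r > 0.6` rule correctly refuses to merge; the quantity under
test is the deduplication bookkeeping, not the spatial noise filter.

## Problem sizes and reproducibility

All headline numbers use 60 s of 16-channel, 30 kHz data (~2400–2800
ground-truth spikes) averaged over five seeded recordings; a full
five-seed evaluation of all six quantities runs in a few minutes on one
CPU. Everything downstream of the rendered voltages is deterministic, and
the generator is seeded, so every reported number is exactly reproducible
from a seed.
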