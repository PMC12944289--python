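# Methods

## Task and data model

Emotion estimation is treated as four-class classification of 3-s EEG
windows into valence×arousal quadrants (HVHA, LVHA, LVLA, HVLA), with
both rating axes thresholded at 5 and 5 itself mapping to High. Models
are strictly subject-dependent: one model per subject, trained on that
subject's own windows under a seeded window-level 6:2:2
train/validation/test split (train gets ⌊0.6n⌋ windows, the remainder is
balanced between validation and test).

A trial is a channels×samples matrix in microvolts with a pre-stimulus
baseline segment and continuous ratings in [1, 9]. The default montage is
the 32-channel cap in DEAP channel order with standard 10-20 positions
projected to the unit sphere; any montage with supplied 3-D coordinates
is accepted (`name x y z` text files).

## Feature extraction

* Windows: non-overlapping, `window_s` = 3 s by default; a trailing
  partial window is dropped rather than padded so all windows share one
  shape. The baseline segment never enters any split.
* Time branch input: the baseline **median** per channel is subtracted
  from each window. Optionally the waveform is block-averaged by an
  integer factor (`time_downsample`); this only changes the recurrent
  branch's time resolution, never the spectral features. The benchmark
  protocol uses factor 8 (48 steps per 3-s window at 128 Hz), which
  preserves the slow transients the time branch must detect while keeping
  recurrent training tractable.
* Frequency branch input: differential entropy ½ln(2πeσ̂²) of the
  band-passed window per channel and band (δ/θ/α/β/γ). The estimator is a
  4th-order zero-phase (forward–backward) Butterworth filter followed by
  the Gaussian DE of the filtered samples; a `skip_filter` flag exposes
  the raw-variance path, for which the closed forms DE = ½ln(2πe) at unit
  variance and DE(aX) − DE(X) = ln a hold exactly. The variance is
  floored at 1e−12 before the log so constant windows stay finite (a
  warning is emitted). The per-trial baseline is segmented at the same
  window length (a 3-s baseline is a single window; shorter baselines are
  used whole) and its mean DE is subtracted per channel-band.
* Standardization: per channel (time domain, pooled over windows and
  samples) and per channel-band (DE). Statistics are computed on the
  training partition only and applied unchanged elsewhere; standard
  deviations are floored at 1e−8.

## Electrode graph

Gaussian kernel of Euclidean distance, β_ij = exp(−d²_ij/τ²), symmetric
with unit diagonal. τ defaults to the median pairwise electrode distance,
which puts the kernel's useful dynamic range across the montage at any
scale; the edge set is therefore invariant under joint rescaling of
coordinates and τ. Edges are undirected; the top
round(edge_fraction·n(n−1)/2) pairs by β are kept (round-half-to-even,
minimum one edge; exact ties go to the lexicographically smaller pair so
selection is deterministic). Aggregation always adds self-loops so no
node has an empty neighborhood. For the 32-channel montage at the default
fraction 0.2 this keeps 99 of 496 pairs.

## Model

The two branches are conceptually parallel but computed sequentially per
sample, because the channel-attention gate applied to the time branch's
input reads the frequency branch's second-layer node embeddings.

* Graph attention: per head, scaled dot-product logits plus the distance
  bias, softmax over the kept-edge neighborhood (plus self-loop), then
  attention-weighted sums of value projections; heads are concatenated
  and linearly projected; ELU activation. Depth is fixed at two layers.
  The readout is mean pooling over nodes followed by a dense layer (the
  readout choice was open; mean pooling keeps the node dimension
  permutation-consistent with channel masking).
* Channel attention: softmax of a learned linear score per node, rescaled
  by n so the mean weight is exactly 1; the gate interpolates between
  identity and full attention weighting through a scalar mixing
  coefficient stored as a raw parameter squashed by a sigmoid into (0,1)
  (initialized at 0.5). The scalar (rather than per-channel) coefficient
  and the use of the *rescaled* weights in the gate follow the mean-1
  rescaling's purpose of keeping signal amplitude unchanged on average.
* Time branch: two stacked LSTM layers (forget-gate bias 1), additive
  tanh temporal attention (the temporal-attention form was open;
  additive scoring is the standard choice for recurrent pooling), dense
  ReLU readout.
* Fusion: scalar sigmoid gate over the concatenated branch outputs,
  convex combination of the (pre-projected) frequency output and the time
  output. Single-branch variants bypass fusion and feed the classifier
  directly. Classifier: one dense layer + softmax, cross-entropy loss, no
  dropout.
* Ablation variants: 1 time-only, 2 frequency-only, 3 both + fusion,
  4 both + channel attention + fusion, with fixed widths 32/64 (layers),
  32 (dense readouts) and 2 heads.

All computation runs on the package's own reverse-mode automatic
differentiation core (`eegfuse.autodiff`), gradient-checked against
central differences in the test suite. Training uses Adam at learning
rate 0.001, batch size 32, 150 epochs by default; the returned model
carries the weights of the best-validation epoch (consistent with
validation-based architecture selection) and per-epoch train/validation
loss and accuracy are logged. Forward passes are deterministic given
fixed parameters; all randomness flows through explicit seeds.

## Architecture search

Decision points and candidate sets: LSTM layer widths
{32, 48, 64, 80, 96, 128, 160} (each layer its own decision), LSTM dense
width {64, 96, 128, 160}, graph layer widths
{32, 48, 64, 80, 96, 112, 128, 160}, attention heads {1, 2, 4, 8}
(shared by both graph layers), graph dense width {64, 96, 128, 160}.

The supernet instantiates one sub-layer per candidate and mixes outputs
with softmax(α). Heterogeneous widths are made summable by a linear
canonicalization map from each candidate's width to the decision point's
maximum; the discretized network drops these maps, preserving each
candidate's native capacity during search. Head-count candidates are
separate sub-layer instantiations; a graph layer's width and head
mixtures factorize, each (width, heads) sub-layer weighted by the product
of the two softmax weights. The projection before fusion is sized to the
LSTM dense decision's (canonical or discrete) width.

Search pools training+validation windows, splits them 50/50 with a
seeded shuffle, and alternates per epoch between updating network weights
on one half and α on the other (first-order only; both with Adam at
0.001). Default 40 search epochs. Discretization takes the argmax per
decision with exact ties resolved toward the smaller (cheaper) candidate.
The protocol repeats the search under several seeds, retrains each
discretized architecture from scratch on the standard split, and selects
by validation accuracy — test accuracy is reported only for the selected
configuration. Whether retraining happens per seed or once was ambiguous
in the protocol this follows; retraining per seed is implemented since
selection *by validation accuracy* requires a retrained candidate per
seed.

## Synthetic benchmark

The generator emulates DEAP-shaped subjects: 40 trials of 60 s at 128 Hz,
32 channels, a 3-s pre-stimulus baseline, ratings drawn per class
(means at (7,7), (3,7), (3,3), (7,3) with jitter 1.0, clipped to the
intended side of the threshold so labels match the generating class
exactly), classes balanced round-robin then shuffled.

Signals are sums of one band-limited carrier per rhythm band and channel
(base amplitudes 1.0/0.8/0.7/0.7/0.5 for δ/θ/α/β/γ) plus 1/f and white
noise at a configurable signal-to-noise ratio (default 3; snr = 0 removes
the oscillations entirely for pure-noise subjects). Carrier frequency and
phase are redrawn per 3-s block, and the 1/f noise is synthesized per
block as well: block-wise independence is deliberate, because spectra
synthesized once per trial act as a trial fingerprint that a window-level
split converts into label leakage (see Limitations).

Two independently switchable cues live on a known informative-electrode
set ({F7, T8, CP6, P4, FC5} by default):

* **Spectral cue** — class-dependent band amplitude multipliers. The
  default codes *valence by band identity* (α×2.5 for high valence,
  β×2.5 for low) with equal base amplitudes in α and β, so total signal
  power is class-independent: the cue is visible to band-wise DE but
  nearly invisible to the waveform's envelope.
* **Temporal cue** — a smooth low-frequency transient (Gaussian bump,
  width 0.15 s, amplitude 1.5·√(background power)) whose latency within
  each 3-s period codes arousal (0.6 s for high, 1.8 s for low; a
  4-latency per-class variant exists). Same shape and energy in every
  class, so band variances — and hence DE — carry no arousal
  information.

With both cues active neither branch alone can separate all four
quadrants (each is capped near 0.5), which is exactly the regime in which
fusing the branches must help; this is the package's complementarity
benchmark. The baseline segment is generated without any class effect.

What the generator does **not** emulate: volume conduction and realistic
cross-channel covariance, artifacts (blinks, EMG), non-stationary
drift, rating noise that crosses the class threshold. Passing tests on
this benchmark therefore demonstrate that the pipeline's machinery
(features, graph, attention, fusion, search, reduction) behaves as
designed — not that comparable accuracy would be reached on real
recordings.

## Scaled-down benchmark protocol

Simulation-based checks (test suite and `scripts/acceptance.py`) run at
reduced cost, fixed once as the package's benchmark protocol: model
widths 16/32 with dense width 16, 30 training epochs (15 for the
noise-floor measurement, where only memorization is at stake), time
branch downsampled ×8, and the architecture-search check at 10 search
epochs on a 20-trial subject with a 4-band spectral cue and a width-1
decoy candidate in the first graph layer. The full-width defaults
(32/64, 150 epochs, 40 search epochs) remain the package defaults for
real use.

## Numerical choices

* Variance floor 1e−12 in DE; standardization floor 1e−8; sigmoid input
  clipped at ±60; softmax computed with max-shift; masked softmax
  assigns exactly zero weight outside the admitted set.
* Channel masking (`mode="drop"`, default) removes electrodes from the
  graph (attention renormalized over the remaining neighborhood), zeroes
  their time input, and mean-pools over retained nodes only; with all
  channels kept the code path is bit-identical to the unmasked forward
  pass. `mode="zero"` keeps the graph and zeroes the excluded channels'
  inputs instead. Retraining at reduced montages rebuilds the induced
  subgraph with the same τ and refits the scaler on the reduced training
  partition.
* Electrode ranking averages the rescaled attention weights over
  validation windows; ties sort by channel name. Random-K masking uses 10
  seeded replicates.

## Known limitations

* **Window-level splits leak trial identity.** Windows of one trial
  share any per-trial constant. The per-trial baseline-DE correction
  subtracts a *noisy* constant estimated from a single 3-s baseline
  window (estimator sd roughly 0.15–0.5 nats per band), so all windows
  of a trial acquire a trial-unique offset; with train and test windows
  drawn from the same trials, a classifier can recover the trial — and
  hence its label — from that offset alone. On pure-noise subjects the
  pipeline accordingly measures ≈0.34–0.40 test accuracy against a 0.25
  chance level (the `noise_only_accuracy` quantity in the acceptance
  report). This is a property of the protocol, not a bug in the
  implementation: removing it would require trial-level splits or
  dropping baseline correction. It also means window-level accuracies on
  real data should be read as within-trial generalization.
* First-order search only; the architecture gradient is noisy at few
  epochs, and decisions whose candidates barely change the loss drift
  slowly.
* Per-subject models only; no cross-subject transfer, no artifact
  handling, no re-referencing or resampling beyond what the container
  declares.
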