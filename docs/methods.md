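# Methods

This note documents the model implemented by `glcnet`, the assumptions
behind the synthetic data, and the numerical and design choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

The decoder classifies epoched multichannel neuromagnetic (or
electrophysiological) time series: trials of C channels × T samples with
one class label each, e.g. motor/cognitive imagery conditions recorded
by 204 planar gradiometers at 500 Hz in 5 s epochs (the reference
geometry, C=204, T=2500). Task-related information is carried by
band-limited power changes (ERD/ERS) with class-specific spatial
topographies, and by inter-channel phase relationships. Raw-recording
preprocessing (Maxwell filtering/SSS, ICA, head-movement compensation,
epoching) is out of scope: the package consumes pre-cut epochs and
assumes broadband content up to at least 40 Hz survives any upstream
filtering.

## Filter bank

Nine non-overlapping 4 Hz pass bands, 4–40 Hz, realized as Chebyshev
Type II band-passes. The source architecture fixes the band layout and
filter family but not the order or attenuation; the defaults here are
design order 4 (band-pass order 8), 30 dB stop-band attenuation, and
stop-band edges placed 2 Hz outside each pass band — standard values in
the filter-bank decoder lineage (FBCSP/FBCNet) that keep transients
short relative to 2–5 s epochs. Chebyshev II has a maximally flat pass
band, so in-band amplitudes are preserved without ripple.

Filters are applied forward–backward by default (`sosfiltfilt`, with
reflect padding), so all band signals remain mutually time-aligned; this
doubles the effective attenuation (the magnitude response squares). A
single-pass causal mode is available (`zero_phase: false`), in which
case a reflected pre-extension absorbs the onset transient. The
operation is linear and preserves the epoch length; both properties are
asserted by tests against a direct evaluation of the designed transfer
function on a frequency grid.

## Sensor graph

Channels are nodes of a weighted graph. Two adjacency constructions are
provided:

* **Phase lag index (PLI).** `PLI_jk = |⟨sign(φ_j(t) − φ_k(t))⟩|`,
  averaged over samples and trials, where phases come from the analytic
  (Hilbert) signal of each band-limited channel. The sign of the
  *wrapped* difference is taken as `sign(sin Δφ)`. PLI is blind to
  zero-lag coupling (volume conduction): identical channels score 0, a
  constant non-zero lag scores 1. Choices the source leaves open,
  decided here: the PLI is computed on the **training partition only**
  (no validation/test leakage) and averaged over all nine bands into a
  single shared adjacency (per-band adjacencies are available through
  the band argument); the first and last 5% of samples are discarded
  before averaging to limit analytic-signal edge effects.
* **Distance.** `A_jk = 1 − d_jk` with `d` the min-max-normalized
  pairwise sensor distance. Straight-line (chordal) distance stands in
  for scalp-geodesic distance, which would require a head model the
  input does not carry; a precomputed matrix can be supplied in
  `custom` mode. When all pairwise distances are equal (the 2-sensor
  case), the degenerate normalization defines d = 0, i.e. A = 1.

The adjacency is kept dense and unthresholded. The propagation operator
is the standard symmetric normalization
`S = D̃^{-1/2}(A+I)D̃^{-1/2}` with `D̃_ii = Σ_j(A+I)_ij`; the +I makes
isolated nodes impossible and the spectrum of S lies in [−1, 1]
(asserted by a dense-eigendecomposition test). The source text prints
the second exponent as +1/2; that form breaks both symmetry and the
spectral bound and is treated as a typographical slip — the symmetric
form matches the graph-convolution lineage the architecture builds on.

## Architecture

Input is the band tensor `(9, C, T)`. Fixed default hyperparameters:
temporal conv kernel (1,10) with 9 output maps and "same" padding;
max-pool (1,10) stride (1,10); two graph layers with output dims
(64, 5); channel-aggregating (C,1) conv to 288 maps; grouped (C,1)
spatial conv with 9 groups × 32 filters = 288 (the grouped layout is
the unique standard one whose parameter count, 288·C + 288, matches
the published table; an ungrouped conv would be ~9× larger);
temporal averaging window T/5; LSTM hidden size 32 with a per-step
linear readout to 288; dropout p = 0.25 throughout; ReLU after
convolution and graph layers, ELU after batch-norm where the published
table lists it. Batch statistics are kept per feature map (pooled over
bands within a map).

The three branch outputs are fused by elementwise summation. F1's
second axis (graph feature dim, 5) equals F2/F3's temporal axis
(T / avg_window = 5) under the defaults; if a configuration breaks that
equality, F1 is linearly interpolated along that axis (a fixed linear
map, differentiable by construction). The fused map is flattened
(288·5 = 1440) into a linear classifier with log-softmax output.

Two published per-layer parameter counts are not reproducible under any
standard parameterization and are excluded from the count checks: the
first temporal convolution (printed 8,109; K=(1,10), F=9 over 9 input
maps gives 819) and the LSTM (printed 44,002, not divisible by the 4
gates). The first graph layer's printed count (15,424) implies a
node-feature dimension of 240 (T = 2400 after pooling by 10), so the
count checks pin that dimension explicitly; the pipeline default T=2500
gives 250 and a correspondingly larger first graph layer.

Ablations remove one branch's contribution from the fused sum:
`module1_gcn` removes the front-end and graph branch entirely;
`module3_lstm` removes the recurrent branch; `module2_spatialconv`
removes F3 *from the fusion only*, because the spatial convolution it
ablates still feeds the LSTM — its trainable parameters therefore
remain. The classifier width never changes.

### Implementation

The network is implemented directly in numpy: every layer carries an
explicit reverse-mode `backward`, checked element-by-element against
central finite differences in the test suite, and a full-network
gradient check compares backpropagated loss gradients on randomly
chosen weights. Convolutions are realized as GEMMs (the temporal
convolution as k shifted matrix products in a channels-last scratch
layout, avoiding any materialized window tensor); layers preserve the
input dtype, so training runs in float32 while verification runs in
float64. Weight initialization is fan-in-scaled uniform with a recorded
seed. The two input-facing convolutions skip their (unused) input
gradients.

## Losses and metrics

Losses operate on log-probability rows. Cross-entropy
`H(p,q) = −Σ p ln q` and the enhanced (focal-style) variant
`H(p,q) = −Σ (1−q)² p ln q`; with one-hot p both reduce to functions of
the true-class probability only, and the implementation uses that
reduced form (provably identical for one-hot p). Natural logarithms
throughout; q is clipped at 1e-12 before logs. For one-hot p,
ECE ≤ CE always, with equality only in the limits q → 0 and q = 1. The
accompanying text of the source describes the weight as a "square
root" while its formula squares (1−q); the formula is implemented as
printed. The analytic loss gradients
(d/du of −u and −(1−e^u)²u for u = ln q) are finite-difference checked.

Metrics come exclusively from the confusion matrix: accuracy =
trace/total; per-class precision/recall one-vs-rest, F1 macro-averaged
(the published single F1 for 4 classes does not state its averaging;
macro — the unweighted class mean — is the choice here, appropriate for
the balanced designs the protocol uses); Cohen's kappa
`(acc − p_e)/(1 − p_e)` with `p_e = Σ_k row_k·col_k / n²`, and kappa = 0
by convention when p_e = 1. Degenerate one-vs-rest cells yield 0.
Cross-checked against scikit-learn and a brute-force one-vs-rest
recomputation.

## Two-stage training

Adam (standard moment coefficients, no weight decay), learning rate
1e-3, batch size 32, ECE loss — the published settings, kept as library
defaults. Batches are reshuffled every epoch from a seeded generator;
the last short batch is kept.

* **Stage 1** trains on the training set and evaluates validation
  accuracy each epoch. "Improvement" means *strictly greater* accuracy
  than the best so far (ties do not reset patience — the conservative
  reading of an unstated rule). Stop after `patience` epochs without
  improvement (default 50) or at `max_epochs_stage1` (default 100);
  then the weights of the best epoch are restored. With the defaults
  the patience rule is rarely binding (50 vs 100); both are
  reproduced as published.
* **Stage 2** merges the validation set into training (its indices are
  remembered), continues optimizing, and monitors the loss restricted
  to the former validation trials; it stops as soon as that loss drops
  below the *minimum* stage-1 validation loss ("lower than the first
  stage", read as the best stage-1 value). Because this criterion need
  not ever trigger, a safety cap (`max_epochs_stage2`, default 200)
  guarantees termination, and the history records whether the
  criterion was met.

Evaluation is eval-mode forward (dropout off, batch-norm running
statistics), argmax with ties broken toward the lower class index.
Given identical seeds, whole runs are bit-reproducible on one platform.

## Synthetic data

The generator plants the signatures the decoder is built for. Each
trial is per-channel 1/f^β background noise (spectrally shaped white
noise, unit variance; β = 1 by default) plus white sensor noise
(σ = 0.5); trials of class k add a narrow-band oscillation in that
class's band on that class's channel subset, scaled by
`modulation_depth` (default 3, i.e. oscillation SD = 3× the unit
background). Oscillations are band-pass-filtered white noise by
default — realistically varying across trials — with a pure-tone mode
for analytic tests. Within a class's subset, channels after the first
carry a phase-lagged copy of the first channel's oscillation (default
lag 90°), giving PLI estimation a known ground truth. Labels are
exactly balanced and trial order is shuffled; everything is
deterministic given the seed.

Desk-scale default geometry: 32 channels, 250 Hz, 2 s (T = 500), four
classes with disjoint 8-channel subsets and bands (10–12), (20–22),
(14–16), (26–28) Hz. This preserves every shape relation of the
reference architecture (T divisible by the pool factor and by the
averaging window, T/avg_window = 5) at a size where the full pipeline —
PLI, filter bank, two-stage training — runs in minutes on one CPU core.
The fixture suite (`make_fixture_suite`) writes tiny, separable-2class,
separable-4class (4×100 trials) and null (depth 0) sets with documented
seeds.

What the generator does **not** emulate: sensor geometry and forward
fields, correlated background between channels, artifacts, inter-trial
nonstationarity, or inter-subject variability. Passing tests on this
data therefore demonstrate that the implementation recovers planted
band-power and phase-coupling structure under its own assumptions — not
any particular accuracy on recorded MEG, whose published dataset-level
results require the original recordings.

A deliberately weak baseline accompanies the decoder in the tests: a
regularized logistic regression on log band-power features. Its
cross-validated accuracy certifies fixture separability independently
of the network, and on null data it checks that nothing is decodable.
On null data, cross-validated accuracy is systematically at or slightly
*below* chance (the well-known anti-learning effect of fold-wise noise
fitting), so the chance-level check is one-sided: the estimate must not
exceed the upper 95% binomial bound around 1/K.

## Numerical choices and degenerate inputs

* q clipped at 1e-12 before logarithms; batch-norm ε = 1e-5,
  momentum 0.1; Adam ε = 1e-8.
* Argmax ties → lower class index; max-pool ties → first maximum.
* kappa with p_e = 1 → 0; empty one-vs-rest cells → 0.
* Two-sensor distance graphs: A = 1 (degenerate min-max).
* Stratified splits need ≥ 3 trials per class; rounding keeps at least
  one trial per class in every partition.
* External label sets (e.g. 1-based) are remapped to 0-based contiguous
  integers on load, with the original mapping stored alongside.
* Checkpoints store weights, batch-norm statistics, the full model
  config, the adjacency and the init seed in one HDF5 file.

## Problem sizes used in the shipped checks

The test suite and the acceptance script train the decoder at the
desk-scale geometry (C=32, T=500, 4×100 trials, split 60/20/20) with a
reduced epoch budget — stage 1 ≤ 6 epochs, patience 3, stage 2 ≤ 6 —
which this package chooses because the planted structure is learned
within the first epochs and longer schedules add nothing to the check.
The published budget (100/50/…) remains the library default for real
data. Parameter-count checks build the full 204-channel architecture
(construction is cheap; only training at that scale is not).

## Known limitations

* CPU-only, single-device; large-C training (204 channels, thousands of
  trials) is feasible but slow compared to GPU frameworks.
* Single shared adjacency per model; no time-varying or learned
  connectivity.
* Single-layer unidirectional LSTM only; no attention or augmentation.
* FIF support is read-only and limited to epoch files.
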