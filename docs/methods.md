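# Methods notes

## Coordinate conventions

Annotations have one-second resolution. Seconds are 1-based and seizure
intervals inclusive at both ends: an event spanning seconds 104–121 lasts
18 seconds, and second `i` covers sample indices `[(i−1)·fs, i·fs)`. A
seizure *event* is a maximal contiguous run of 1s in an expert's per-second
track; decoding runs to events and re-encoding events to a track are exact
inverses whenever events are separated by at least one second.

## Input data and preprocessing

Recordings are standard EDF: 19 referential 10–20 channels, 256 Hz,
microvolts. Channel order differs between files, so the pipeline first
permutes channels into a fixed canonical order (label matching is
case-insensitive with whitespace stripped, since EDF headers vary in
padding). The classifier operates on the 18-pair longitudinal bipolar
montage, each channel the difference anode − cathode.

Down-sampling (×4 by default, 256 → 64 Hz) uses a non-overlapping block
mean rather than naive decimation or a polyphase anti-alias filter: the
block mean is the simplest decimator that also smooths, and it is exactly
testable (each output sample is the arithmetic mean of `factor` consecutive
inputs). Plain decimation is available as `method="decimate"` for
comparison. Both montage and down-sampling are linear, so their order does
not matter up to floating-point round-off; a test asserts commutation at
1e-9.

## Sliding-window design

Positives are packed from each event's onset as consecutive non-overlapping
windows that must end inside the event, so a seizure of `L` seconds yields
`min(chunks, ⌊L/w⌋)` windows. Packing from the onset is deterministic and
reproduces every worked yield; no offset policy is applied. Seizures shorter
than the window contribute nothing (logged, not an error). A chunk never
spans two events, even adjacent ones: containment in a single annotated
event is the semantics of a positive sample.

Negative sampling draws a recording uniformly per draw (among seizure-free,
EXP0 subjects only), then a start second uniformly over the recording,
rejecting windows that overlap an already drawn window of the same
recording. Rejection keeps negatives mutually independent; the sampler
fails loudly, reporting the shortfall, when the requested count cannot fit.
Everything is driven by one seed.

Subjects annotated by all experts (EXP3) supply positives; the chosen
expert's own event list is used for extraction. Subjects annotated by one
or two experts are excluded as ambiguous.

## Dataset layout

The (18+1)-row sample matrix and the `(n, w·fs, 18)` tensor are two
arrangements of the same values; `to_tensor` enforces that the class row is
constant within each chunk's column block and the round trip is the
identity. HDF5 files hold `data` (float32) and `labels` (int8) plus
metadata attributes; the external name `expert_X_Ysec_Zchunk_VHz.hdf5` is
parsed strictly, and two CSV sidecars (`seizures_*`, `non_seizures_*`)
record each chunk's subject and start second.

## The classifier

Three blocks of [valid 2-D convolution → batch normalization → ReLU →
max-pooling], flatten, dropout, two dense layers with L2 penalty, one
sigmoid unit; binary cross-entropy; SGD with learning rate 0.01, momentum
0.5, Nesterov off, batch size 16. Fixed elements are the layer counts, the
L2 coefficient (0.001) and the optimizer; filter counts (16, 32, 64),
3×3 kernels, 2×2 pooling, dense widths (64, 32) and dropout 0.5 are
configuration defaults. Hidden activations are ReLU; the named sigmoid is
the output nonlinearity. Pooling degrades gracefully: once the short
electrode axis is exhausted it pools over time only, so inputs down to a
1-second window (64×18) build without error.

The implementation is pure numpy: im2col convolutions via stride tricks,
manual backpropagation (verified against central finite differences in the
test suite), inverted dropout, spatial batch normalization with running
statistics (momentum 0.9), and a momentum SGD step. Inputs are fed in
microvolts without standardization, relying on batch normalization; a
per-channel z-score switch exists but is off by default. The classification
threshold on the sigmoid output is 0.5, the natural choice for balanced
classes. Max-pooling distributes the gradient equally over tied maxima — a
measure-zero event for continuous signals and irrelevant in practice.

Numerics: the loss is computed from logits with `logaddexp` for stability;
the L2 penalty (Keras-style `l2·Σw²`, gradient `2·l2·w`) is included in the
reported training and validation losses. Training raises
`TrainingDivergedError` on a non-finite loss. Weight initialization is
Glorot-uniform from a per-model seed (fold `k` uses `seed + k`), minibatch
order from a separate shuffle seed, so a run is bit-reproducible.

Splits: 20% of samples (stratified by label) are held out as the test set;
the remaining 80% is divided into K = 5 stratified folds differing in size
by at most one. Each fold trains on K−1 folds, validates on the held fold,
and checkpoints the weights of its best validation accuracy; each fold's
best model is evaluated on the common test set and the final score is the
mean over folds. A `complete=False` switch trains fold 0 only, five times
faster at the cost of averaging over a single model.

## Synthetic cohort

The generator emulates the structure the pipeline assumes, not neonatal
physiology. Background is band-limited (0.5–30 Hz) noise with amplitude
spectrum ∝ f^(−1/2), scaled to 20 µV RMS per channel — amplitudes in the
range of quiet neonatal background. A seizure adds, on all channels, a 3 Hz
sinusoid with per-channel random phase and amplitude `gain × 20 µV`
(default gain 4), a crude stand-in for high-amplitude rhythmic ictal
activity. Consequences worth stating: mean per-second power inside events
exceeds background by ≈ 1 + gain²/2, so a linear probe on per-channel
energy separates classes almost perfectly at gain ≥ 3 — passing the
learning-sanity tests shows the pipeline and optimizer work, *not* that the
architecture detects real neonatal seizures, which have variable morphology,
evolving frequency content and artifacts this model omits.

Events per seizing subject follow a zero-truncated Poisson (mean ≈ 3 by
default) with lengths uniform on 10–60 s — the order of real annotated
durations, whose medians sit in the tens of seconds — placed uniformly at
random with at least 5 s between events. A fixed fraction of subjects
(default 0.28, matching the roughly one-quarter seizure-free share of real
neonatal cohorts) is seizure-free by construction rather than by chance:
the balancing step *requires* EXP0 material, so its existence must not
depend on the seed. Each "expert" reproduces each true event with an
integer onset/offset jitter (default ±2 s) and omits it with probability
0.1; jittered intervals are clamped to gap midpoints so events never merge.
EDF output uses a ±2000 µV physical range with 16-bit quantization
(≈ 0.06 µV resolution), leaving ample headroom for burst amplitudes.

## Problem sizes in the tests

The shared test cohort is 10 subjects × 600 s at the default gain 4; with
window 2 s and 10 chunks per seizure it yields a few hundred balanced
chunks. Learning sanity uses 2 folds × 30 epochs on that cohort (reaching
>95% mean test accuracy in minutes on one CPU), a label-permuted control
(chance level), and a 40-sample training run at gain 0.5 for the
overfitting signature (validation loss rising ≥20% above its minimum while
training loss still falls). These sizes exercise every code path at desk
scale; headline accuracies on real clinical cohorts require the full data
volume and are out of scope here.

## Known limitations

- The burst model is linearly separable by design; no claim of realism.
- No artifact simulation (movement, ECG, electrode pops) and no band-pass
  filtering or artifact rejection — the pipeline applies none by design.
- EDF support is plain EDF (16-bit, one-second records); EDF+ annotations
  embedded in the file are not parsed.
- Per-fold ROC curves are not threshold-averaged; the aggregate report
  carries mean scalar metrics and summed confusion matrices only.
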