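# Methods

This note documents the models, procedures and numerical choices behind
`gaitfatigue`, what the synthetic cohort generator does and does not
emulate, and the known limitations.

## Data model

A recording session produces, per subject and fatigue state, six sensor
sites (TAL/TAR on the tibialis anterior, GLL/GLR on the gastrocnemius
lateralis, RFL/RFR on the rectus femoris). Each site carries a 3-axis
accelerometer (m/s²) and 3-axis gyroscope (rad/s) at 148 Hz and one sEMG
channel (mV) at 1259 Hz. The two IMU modalities of a site must have equal
sample counts, and the EMG length must equal the IMU length scaled by
1259/148 within ±1 sample. Units are fixed by convention and never
converted; axis conventions are arbitrary but consistent within a cohort.
Missing samples are carried as an explicit boolean mask (empty CSV cells on
disk), never as sentinel values, so the interpolation stage sees true
missingness. A (subject, state) pair enters a cohort only when all six
sites are present.

## Signal conditioning

Each channel passes through, in order:

1. **Outlier masking** — a single pass computes mean and SD over unmasked
   samples and masks values beyond ±3 SD. The pass is deliberately
   non-iterative (one threshold, applied once, per channel over the whole
   recording); a constant channel (SD = 0) is left untouched.
2. **Gap filling** — linear interpolation between the nearest observed
   neighbours; leading/trailing gaps take the nearest observed value. The
   operation is idempotent and exact on linear signals.
3. **Band-pass filtering** — 4th-order Butterworth applied
   forward-backward (`sosfiltfilt`), i.e. zero-phase with an effective
   8th-order magnitude response. Bands: gyroscope 0.25–30 Hz, accelerometer
   1–20 Hz (both at 148 Hz), EMG 20–500 Hz *at its native 1259 Hz* — the
   EMG band would violate the Nyquist limit after resampling, so EMG is
   filtered and enveloped before the rate conversion. Zero-phase filtering
   was chosen so that no modality acquires a group delay that would skew
   jerk timing relative to the EMG envelope.
4. **Feature derivation** — IMU: linear jerk as the forward difference
   `(a(t+Δt) − a(t))/Δt` (the final frame replicates its predecessor to
   preserve length), angular jerk as `dω/dt` by the same difference;
   a `angular_jerk_order = 2` switch exposes the second-derivative
   alternative for sensitivity analyses. Jerk is computed *before* the
   100 ms moving-average smoothing: smoothing raw IMU first and then
   differencing would re-amplify exactly the noise the smoothing removed.
   EMG: full-wave rectification followed by the same 100 ms moving average
   (the envelope). The smoothing window is `round(0.1·fs)` samples, bumped
   to odd for a symmetric centre (15 samples at 148 Hz, 127 at 1259 Hz),
   with shrinking windows at the edges.
5. **Resampling** — polyphase band-limited resampling onto the common
   148 Hz grid (identity for IMU channels, 1259 → 148 for the EMG
   envelope), then truncation of all channels to the common minimum length.

The ordering of stages follows the conditioning sequence stated for this
class of pipeline: cleaning → filtering → derivation/envelope → resampling.

## Segmentation and normalization

Recordings are cut into 3 s windows (444 = round(3 × 148) frames) with 50 %
overlap (hop 222). The first nine windows of each recording are kept, so a
subject contributes 18 segments (2 states × 9). Windows are z-scored **per
segment, per channel**; zero-variance channels become zeros. Per-segment
scaling removes each subject's amplitude offsets without borrowing
statistics from other subjects or windows — a requirement for honest
leave-one-subject-out evaluation (global scaling would leak the test
subject's statistics into training). A consequence worth stating: any
fatigue effect that only rescales a channel's amplitude is invisible to the
classifier; only changes of shape, contrast or timing survive.

## Sensor combinations

The 14-row registry maps each configuration to an ordered channel list
(EMG envelope = 1 channel; a jerk block = 3 channels in x, y, z order; EMG
blocks precede jerk blocks). Feature widths: 1, 1, 2, 6, 6, 12, 6, 6, 12,
7, 4, 9, 10, 20 for rows 1–14. Channel selection happens after
normalization, so a combination's data is exactly the corresponding slice
of the full segment array.

## Classifier

Input: one segment, frames × channels. The stack is

    conv1d(64, k=5, same) + ReLU + max-pool(2)
    conv1d(128, k=3, same) + ReLU + max-pool(2) + dropout(0.3)
    LSTM(64) returning the full sequence
    scaled dot-product self-attention (single head, Q = K = V)
    global average pooling over time
    dense(64) + ReLU → dense(2) → softmax

with two-class cross-entropy loss. The attention layer computes
`A = softmax(HHᵀ/√d)` over the LSTM state sequence `H` and re-weights it as
`AH`; its rows are probability vectors over timesteps and are exported for
heatmap inspection. Max-pooling follows each convolution; the dense block
has two layers. Defaults for the hyperparameters the architecture does not
pin down: kernel sizes 5 and 3, pool size 2, dropout 0.3, Adam with
learning rate 10⁻³, batch 16, at most 100 epochs, early stopping with
patience 10 on validation loss (best weights restored), learning-rate
reduction ×0.5 with patience 5, stratified 80:20 train/validation split.
Ties in the argmax go to class 0 (non-fatigued).

The network, backpropagation (im2col convolution, BPTT through the LSTM,
the exact softmax Jacobian in the attention layer) and Adam are implemented
directly in NumPy. Every random choice — initialization (Glorot uniform;
LSTM forget-gate bias 1), batch shuffling, dropout masks, the validation
split — derives from the config seed, so a run is bit-reproducible. A
gradient test in the suite checks backpropagation against central finite
differences through the whole stack.

`ModelConfig.small()` is a reduced preset used for desk-scale cohorts and
the test suite: conv filters 8/16, pool 4, LSTM 24, dense 16, dropout 0.2,
learning rate 10⁻³, up to 40 epochs, patience 8. The wider pools shorten the
attended sequence (444 → 27), which is what makes NumPy training fast. The
preset was chosen for optimization stability: pilot runs with a 16-unit
LSTM, learning rate 3 × 10⁻³ and patience 4 occasionally collapsed on
single folds (constant-class predictions), which longer patience and the
lower rate eliminate.

## Evaluation protocols

**LOSOCV** (subject-independent): one fold per subject; the fold's test set
is all of that subject's segments, and a fresh seeded model (seed + fold id)
is trained on everyone else. **9-fold subject-dependent**: fold *j* tests
window index *j* of every subject in both states, giving exactly
label-balanced folds of 2 × n_subjects segments. Because adjacent windows
overlap by 50 %, neighbouring windows share frames across the 9-fold
train/test boundary; this leakage is inherent to the protocol and is part of
why subject-dependent accuracy exceeds subject-independent accuracy.

Metrics come from integer confusion counts with fatigued as the positive
class; the per-class table swaps the positive class. Division-by-zero cases
return 0 and are flagged. Both pooled-count metrics and macro-averaged
per-fold metrics are reported (they coincide for equal fold sizes); pooled
counts drive the confusion matrices. A helper reconstructs the integer
confusion counts implied by a pair of per-class recalls on a balanced set —
with 315 segments per class, recalls of 0.8476/0.9111 imply
TP = 267, FN = 48, TN = 287, FP = 28, hence accuracy 554/630 = 0.8794 and
precisions 0.9051/0.8567 — which the suite uses to verify the arithmetic
consistency of reported confusion tables.

## Synthetic cohorts

The generator emulates steady over-ground walking: a periodic stride
waveform (fundamental + second harmonic at a subject's latent cadence,
~N(0.9, 0.05²) strides/s) with sharp Gaussian heel-strike transients
(σ = 20 ms, peak 8 m/s²) and white noise on the accelerometer; phase-locked
sinusoids plus attenuated transients on the gyroscope; and EMG built as
band-limited carrier noise (20–450 Hz at 1259 Hz) amplitude-modulated by a
gait-phase-gated burst (clipped-cosine⁴ gate centred at a muscle-specific
phase) over a small tonic floor (0.1 mV vs. burst peak 0.8 mV). Right-side
sites run half a stride out of phase.

The fatigued recording of a subject shares every latent parameter with the
non-fatigued one and differs only through four multipliers, with defaults
chosen to be physiologically plausible in direction and deliberately
moderate in size: `jerk_gain` 1.3 on the heel-strike transients,
`emg_gain` 1.25 on the burst envelope, `asymmetry_gain` 1.2 extra on
left-side EMG, `cadence_factor` 0.92. The gains act on the
transient/burst components *relative to* the baseline because per-segment
z-scoring removes whole-signal rescaling — only contrast and timing changes
can reach the classifier. Setting all multipliers to 1 yields a null cohort
whose labels are independent of the signals. Because the EMG tonic floor is
not scaled, the realized EMG RMS ratio sits slightly below the configured
gain (≈1.20 for a 1.25 gain); the realized jerk ratio similarly dilutes as
noise grows, which `effect_report` quantifies per cohort.

What the generator does **not** emulate: real stride-to-stride variability
and turns, gravity and orientation drift in the accelerometer, motion
artifacts and electrode noise in EMG, spectral compression of the EMG with
fatigue (it changes only amplitude structure), heel-strike timing jitter,
and any within-recording fatigue progression. Passing tests therefore show
that the pipeline recovers the specific effect structure it injects — not
that the classifier would reach comparable accuracy on real gait data.

## Problem sizes used by tests and the acceptance script

Synthetic experiments run at desk scale as the package's own choice of
study conditions: 8-subject cohorts (16 s recordings, 144 segments), three
seeds, the small model preset, and combination 13 (the best-performing
hybrid). Null cohorts (all gains 1) classify at chance; strong-effect
cohorts (transient gain 2.5, EMG gain 1.5 — pronounced but within the range
reported for exhaustive exercise) are classified subject-independently at
≥0.9 pooled accuracy, and the subject-dependent 9-fold protocol scores at
least as high, reproducing the qualitative protocol gap.

## Known limitations

* The forward-difference jerk is O(Δt) accurate and correlates noise across
  exactly one lag; a central difference would halve the bias but break the
  printed definition.
* The 9-fold protocol's window leakage (above) means its accuracies should
  be read as within-subject consistency, not generalization.
* NumPy training is practical at the small-preset scale but slow at the
  full 64/128-filter, 444-frame configuration; the full preset exists and
  is exercised for construction and prediction contracts, while training
  tests use reduced sizes.
* The generator's effect magnitudes are free parameters; they were fixed
  once (directions from the exercise-physiology literature, sizes chosen to
  make the task neither trivial nor impossible) and are not fitted to any
  real dataset.
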