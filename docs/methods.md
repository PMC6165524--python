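# Methods

This note records the models, defaults and design choices behind
harspec, and what the synthetic experiments do and do not demonstrate.

## Synthetic IMU generator

The generator emulates labelled 6-axis streams (accelerometer in m/s²,
gyroscope in deg/s) whose three activities are spectrally separable:

- **walking** — every axis carries a sinusoid at the gait fundamental
  (default 1.5 Hz, accelerometer amplitude 3 m/s², gyroscope 60 deg/s)
  plus a half-amplitude second harmonic; the phase performs a slow
  random walk (σ = 0.02 rad/sample) so windows are not phase-locked, and
  each axis gets a random scale in [0.7, 1] to break exact axis symmetry;
- **standing** — quasi-static accelerometer (0.3 Hz sway of 0.05 m/s²
  plus noise) with sparse gyroscope "arm turn" bursts: Gaussian-shaped
  pulses of 45 deg/s, ~0.4 s half-width, Poisson-timed at 8 events/min.
  This makes standing energy gyroscope-dominated, the qualitative
  contrast that separates it from sitting;
- **sitting** — Gaussian noise only (accelerometer σ = 0.05 m/s²).

A constant 9.81 m/s² gravity offset rides on the accelerometer z axis
(configurable, `gravity_mps2`), so the "least spectral density" feature
blocks see a realistic DC component. Gyroscope noise is the
accelerometer σ times a per-class scale (2–4), reflecting the larger
numeric range of deg/s readings.

Default sampling is 50 Hz, the rate the STFT stage assumes; `fs` stays
a free parameter because wireless IMU deployments often transmit far
slower (e.g. 10 Hz) than the analysis rate. All randomness flows
through `numpy.random.SeedSequence`, so any (parameters, seed) pair
regenerates streams bit-for-bit.

What this generator does **not** model: biomechanically realistic gait,
sensor displacement/orientation drift, inter-subject variability, or
any overlap between class distributions. Passing tests on this data
shows the pipeline machinery is correct and that spectrally separable
activities are learned; it says nothing about accuracy on real
recordings, where the quasi-static classes genuinely overlap.

## Feature extraction

3-s windows with 50 % overlap (150 samples at 50 Hz). Since a window is
shorter than the 512-point FFT block, the STFT uses taper segments of
`min(window, 128)` samples with hop = segment/2, each zero-padded to
`fft_length = 512`; all three lengths are config keys. The taper is a
periodic Hann window. The spectrogram is the squared magnitude of the
one-sided FFT (257 bins including DC and Nyquist). Frames are computed
directly (frame × taper × `numpy.fft.rfft`) because the defining
double-sum has no normalisation; library STFTs apply window-sum scaling
that would silently rescale every feature. The implementation is tested
against a literal double-sum evaluation at 1e−8 relative tolerance.

"Pooling" concatenates every (frequency, time) cell of the three axis
spectrograms of a sensor into one multiset before the ascending sort —
so the selection is axis-order-free (verified by a permutation-invariance
test) and scales exactly as c² under amplitude scaling by c. Within each
output block the values stay in ascending order; ties keep stable-sort
order. S + L larger than the pool raises an error.

## Augmentation

Grouping for local averaging is non-overlapping consecutive blocks of G
rows *in current row order* within each class; the trailing remainder
(< G rows) yields no averaged row but remains in the set. This is what
makes the closed-form bookkeeping exact:
`|OR+LA1| = n + Σ_c ⌊n_c/G₁⌋`, `|full| = |OR+LA1| + Σ_c ⌊n'_c/G₂⌋`.
Averaging is the unweighted arithmetic mean per column, uniform across
the four feature blocks. Shuffling permutes rows only within each class
(one child RNG per class, spawned deterministically from the shuffle
seed) and is applied to the *whole* OR+LA1 set before the second
averaging, so LA2 rows mix originals with first averages. Provenance
(`OR` → `OR+LA1` → `OR+LA1+SH+LA2`) is tracked on the FeatureSet and
enforced: compositions only accept an `OR` input.

For independent rows the expected LA1/OR per-column variance ratio is
1/G; for windows extracted from the same stream, neighbouring rows are
correlated and the reduction is smaller. Tests assert ratio < 1 always
and ≈ 1/G on independent synthetic rows.

## Stacked LSTM

The cell implements the peephole-form gate equations exactly as the
package documents them: the input gate is driven by `c_{t−1}` through
`W_hi`, and the forget/output gates carry full-matrix peephole terms
`W_cf c_{t−1}` and `W_co c_t`. This differs from mainstream framework
cells (which use `h_{t−1}` in the input gate and at most diagonal
peepholes), so the network — forward pass, backpropagation through time
and Adam — is implemented in NumPy float64. A `peephole=False` switch
provides the standard cell. Correctness evidence: an element-wise
pure-Python oracle for the gate equations (1e−10), and a central
finite-difference gradient check over every parameter tensor of a
2-layer model.

Architecture: 5 stacked layers × 15 hidden units, a 15-unit ReLU dense
stage, softmax output. Static feature vectors enter as 4-step sequences
(one step per block SA/LeA/SG/LG, (S+L)/2 features per step); the
reshape is configurable. Defaults: Adam (β₁ = 0.9, β₂ = 0.999), L2
λ = 1e−4 on weight matrices (biases unpenalised; the penalty
0.5·λ·Σ‖W‖² is included in the reported loss), loss target 0.001,
max 300 epochs, mini-batch 8000 capped at the dataset size (full-batch
at desk scale). Weights initialise uniform ±1/√fan-in from the run
seed; forget biases start at 1 to keep early memory open.

Feature values span ~10 orders of magnitude (squared spectral
densities), so inputs are transformed by `log1p` and per-column
standardisation fitted on the training set and stored in the model.
Without this, gradient training at the documented learning rates does
not converge. The transform is monotone and per-column, so it preserves
the least/largest semantics of the blocks.

Determinism: pure-NumPy float64 arithmetic makes training reproducible
given the seed on a fixed platform. Prediction ties break toward the
lowest class index (argmax convention); class order is the sorted label
set.

## Evaluation

Accuracy is kept at full precision internally and rounded to 2 decimals
only in reports; accuracy deltas are computed on unrounded values and
rounded last (rounding first distorts small improvements by up to 0.01).
A class never predicted (or absent) has an undefined precision (recall);
it is reported as 0 with an explicit flag, which matches how collapsed
runs — everything assigned to one class — are scored. f1 is the
per-class harmonic mean of precision and recall, macro-averaged without
weights. Metrics are cross-checked against scikit-learn to 1e−9 in the
test suite; scikit-learn is never used as the implementation.

The sweep harness trains each (variant, learning rate, seed) cell and
evaluates all variants on one shared held-out set: augmentation is a
training-data operation only, and the reports assert the constant
test-set size.

### Bundled reference matrices

`harspec.reference_matrices` ships fixed confusion matrices from
published wrist-IMU and UCI-HAR three-activity runs at five learning
rates, as plain count data. Two of the stored matrices are transcribed
as printed with internally inconsistent row sums (`full-100` at 0.006
and `la1-200` at 0.003); they are kept verbatim, flagged in tests, and
excluded from headline-accuracy checks. The full-ensemble 200-feature
variant is omitted entirely because its published table duplicates the
100-feature one and cannot serve as an oracle.

## Problem sizes

The end-to-end experiments use 5 training and 3 test streams per class
of 18 s each at 50 Hz (165 training, 99 test windows of 100 features)
and a 300-epoch Adam budget — the scale at which the synthetic
three-class problem is comfortably learned while a full test-suite run
stays in tens of seconds. Halving the epoch budget leaves some seeds
underfitted; the published-scale sample counts (thousands of windows)
are not needed for the properties tested here.

## Known limitations

- The generator's classes are separable by construction; held-out
  accuracy near 100 % reflects that, not real-world difficulty.
- The peephole cell follows the documented equations literally; results
  will differ numerically from framework LSTM layers.
- Mini-batching beyond full batch is implemented but rarely exercised at
  desk scale.
- The UCI reader handles the text dialect and label filtering; it does
  not download or bundle the archive itself.
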