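# Methods

## Problem and pipeline

Dynamic knee instability — involuntary mediolateral oscillation of the knees
under load — is operationalized per squat as the peak knee-shakiness velocity
reaching 0.03 m/s. The pipeline turns two raw sensor streams per session into
a per-squat binary classification problem:

1. **Ingest**: CSV streams with a `t_sec` column. Camera channels
   (`x_left_knee`, `x_right_knee`, `y_torso`) are in meters; force-plate CoP
   (`cop_x` ML, `cop_y` AP) is in millimeters by plate convention and is
   converted to meters at ingest so all feature formulas share SI units.
   Rows with non-finite values are dropped (logged); non-monotone timestamps
   are an error, not silently reordered.
2. **Synchronization**: both modalities are linearly interpolated onto one
   uniform grid covering only the intersection of the two recordings.
   The grid rate defaults to 50 Hz — the lower of the two nominal device
   rates — so no information is invented. No extrapolation, no gap filling
   beyond linear interpolation, no inter-device drift correction.
3. **Filtering**: all channels are low-pass filtered at 5 Hz (4th order
   Butterworth) in zero-phase mode by default, so squat onset/end timing is
   not lagged. See *Numerical choices* for the implementation.
4. **Segmentation**: squat cycles are detected on the torso depth signal
   `d(t) = y_t1 - y_torso(t)`. The standing baseline `y_t1` is the median of
   non-squat samples, found iteratively (samples with depth below 25% of the
   depth signal's 95th percentile). A candidate cycle is validated where
   depth exceeds 20% of its own peak (spurious-detection rejection), and its
   onset/end are then extended outward to a 5 mm depth floor so reported
   boundaries sit at the true start/end of the movement. Candidates
   shallower than 0.15 m or with durations outside [1 s, 10 s] are rejected
   and logged. The hold phase is where depth ≥ 90% of peak — a kinematic
   proxy, since no joint angles exist in the data model. If two candidate
   runs would share a boundary sample, the earlier run keeps it.
5. **Features and label**: the five feature series (KS, KD, SD, SV, SA; see
   README) are computed on the **physical-unit, full-rate** window of each
   cycle. The KI/NKI label is the thresholded peak |KS| from that series.
   Only then is each feature series time-normalized to 20 samples (linear
   interpolation, endpoints preserved, `Δt` rescaled to duration/19) and
   min-max scaled. Ordering rationale: the 0.03 m/s threshold is
   dimensional, so it must see unscaled data; and a 1–4 Hz oscillation
   cannot be represented on a 20-sample grid spanning a multi-second cycle
   (effective Nyquist ≈ 2.4 Hz), so differentiating *after* time
   normalization would destroy the very signal being thresholded.
6. **Normalization scopes**: duration variability is removed by the
   20-sample time normalization; amplitude scaling is min-max per subject by
   default (preserving subject-specific biomechanics) with a `global` scope
   available that pools all subjects. The per-channel (min, max) record is
   stored and inverts exactly.
7. **Ranking**: each feature enters the correlation through a per-squat
   scalar summary — peak |KS|, mean KD, peak depth, mean SV, total SA —
   computed on physical units (per-subject rescaling is monotone within a
   subject but not across subjects, so ranking on normalized values would
   be scope-dependent). Spearman's ρ is computed summary-vs-label; φ on a
   median-split binarization (the binarizer is injectable). Ranking is not
   inference: no multiple-testing correction.
8. **Classification**: LSTM on the (20 × F) sequences; RBF-SVM on the
   flattened 20·F vectors (how a time series enters an SVM is otherwise
   unspecified, and flattening is the conventional baseline). One stratified
   80/20 holdout split per report; the split, seed and protocol are recorded
   in every report row.

## Synthetic cohort: what it emulates, and what it does not

`squatstab.synth` generates, per subject: a camera stream at 60 Hz and a
plate stream at 50 Hz whose start differs by a uniform offset of up to 3 s
(exercise begins after the slowest device has started, so no squat is
truncated); squats as raised-cosine descent / flat hold / raised-cosine
ascent with depth ~ U(0.25, 0.45) m, duration ~ U(3, 5) s, hold fraction 0.3
and 1.5 s standing rests; mediolateral knee oscillation with a sin² envelope
over the cycle, antiphase between knees by default (valgus-like; in-phase by
flag); CoP baseline sway as correlated AR(1) processes (3 mm scale, 1 s
correlation time), a mild squat-locked posterior shift, and the knee
oscillation coupled into CoPx with unitless gain 0.5; white Gaussian
measurement noise per channel. Each subject draws from an independent
substream keyed by (seed, subject id), so cohorts are bit-reproducible and
order-independent.

**Calibration.** An antiphase sinusoid of amplitude `a` and frequency `f`
produces peak knee shakiness `2·(2πfa)` before filtering. Unstable squats
draw `a` ~ U(4, 10) mm and `f` ~ U(1, 4) Hz: the worst post-filter,
post-differencing peak (f = 1 Hz, a = 4 mm) is ≈ 0.050 m/s, safely above the
0.03 m/s label threshold. Stable squats draw residual wobble of at most
0.3 mm (peak KS ≤ 0.013 m/s). The frequency band stays below the 5 Hz
cutoff by construction — instability that the pipeline's own filter removed
could never be detected. Camera jitter defaults to 0.3 mm: white marker
noise propagates through the low-pass filter and backward difference into a
velocity noise floor whose per-squat peak is ≈ 0.015 m/s at that level;
at several millimeters of jitter the noise floor alone would cross the
label threshold and the labels would be meaningless, which is inconsistent
with the ~6.5% prevalence the generator is built to reproduce.

**Not emulated**: joint angles or EMG; musculoskeletal dynamics; fatigue
drift across a session; slow mediolateral stance adjustments; non-sinusoidal
instability waveforms (the sinusoid is an explicit assumption — nothing is
known about the true waveform's spectrum); inter-device clock drift.
Consequently, passing end-to-end tests demonstrates that the pipeline
recovers what the generator injects under realistic rates, offsets and
noise — it does **not** validate the 0.03 m/s threshold or the classifiers'
accuracy on human data, where the label would not be a deterministic
function of one feature.

Because stable squats' sub-millimeter oscillation amplitudes fall below the
velocity noise floor at default jitter, the monotone-injection property
(Spearman between injected amplitude and measured peak |KS| ≥ 0.9) is
verified on a noise-free cohort; with default noise the observed value is
≈ 0.76, dominated by rank noise among stable squats.

## Numerical choices

- **Zero-phase filter**: implemented spectrally — reflective (even) padding,
  then multiplication of the rFFT by the exact two-pass Butterworth
  magnitude `1/(1+(f/fc)^(2n))`. A bilinear-designed IIR run forward and
  backward warps the response toward Nyquist (measured two-pass gain at
  10 Hz on a 50 Hz grid: 0.0016 instead of the analytic 0.00389); the
  spectral form matches the analytic Butterworth response at every
  frequency and is exactly zero-phase. The single-pass mode (`zero_phase =
  False`) is a standard bilinear IIR and exhibits the usual group delay.
- **Velocities** use backward differences with the first sample replicated;
  CoP step quantities use forward differences with the last sample
  replicated. Central differences were rejected to stay closest to the
  two-point definitions of the features.
- **Sway formulas**: the per-step forms of SV and SA are sometimes typeset
  with a multiplication by Δt; dimensional analysis and standard
  posturography give δ/Δt (velocity) and plain shoelace increments (area),
  which are the defaults. `as_printed=True` reproduces the multiplied-by-Δt
  forms; `per_second=True` turns the SA total into a rate.
- **KD** uses an absolute value (a signed left-minus-right separation would
  be negative in the natural stance under this axis convention); **SD** uses
  the positive-depth convention with a sign flag for the raw displacement
  difference. Axis names are standardized to x = mediolateral, y = vertical
  (camera) / anteroposterior (plate).
- **Label statistic**: peak |KS| by default; `mean` is exposed. The label is
  computed from the filtered series (the pipeline's canonical signal path).
  The threshold boundary is inclusive (statistic = 0.03 → KI).
- **Degenerate inputs**: constant channels min-max to all zeros with a
  warning; precision with zero predicted positives is reported as 0 with a
  warning; an empty candidate list from segmentation is a result, not an
  error.
- **LSTM**: gates as sigmoids, cell input as tanh, `C_t = F⊙C_{t-1} +
  X⊙C̃_t`, `H_t = Y⊙tanh(C_t)`, final hidden state through a fully
  connected layer to 2 logits and softmax. Initialization: uniform
  ±1/√fan-in, forget-gate bias +1 (open at start), zero initial states.
  Training: mini-batch Adam (β₁ = 0.9, β₂ = 0.999) on softmax
  cross-entropy; gradients by analytic BPTT, verified against central
  differences to 1e-5 relative. Defaults h = 32, 100 epochs, batch 32,
  learning rate 1e-3 — small-data defaults; nothing about them is tuned per
  dataset, and all are recorded in `TrainConfig`. Deterministic given the
  seed.
- **SVM**: scikit-learn's libsvm SMO backs the solver contract (KKT
  tolerance 1e-3); γ defaults to the variance-scaled `1/(d · var)` and
  C = 1. Dual coefficients are bounded by C as required.
- **Class imbalance**: no reweighting by default (the ~6.5% prevalence is
  part of the problem); a `class_weight` flag enables inverse-frequency
  weighting (LSTM) / `balanced` (SVM).
- **Metrics**: KI is the positive class everywhere. F1 is the binary
  positive-class F1 (not macro-averaged). ROC sweeps all distinct score
  thresholds with ties grouped; AUC is trapezoidal and equals the pairwise
  Mann-Whitney statistic. Report tables round to 2 decimals, accuracy in
  percent.

## Problem sizes

The default test suite uses a shared 6 × 40 cohort for cross-module checks
and a full 28 × 130 cohort (≈ 3640 squats, ~6.5% KI) for the end-to-end
recovery tests, with classifiers at 30 epochs; the acceptance script runs
the same full-cohort analysis, training both models on the full feature set.
These sizes reflect the emulated study's scale; per-module unit tests use
constructed micro-signals with closed-form expectations.

## Known limitations

- Validation is entirely synthetic; see the generator caveats above.
- The label is a deterministic function of KS on synthetic data, so
  classifier metrics on sets containing KS are near-ceiling and should be
  read as pipeline-consistency checks, not performance claims.
- The fixed 20-sample cycle representation discards within-cycle frequency
  content above ≈ 2.4 Hz; classifiers see oscillation *magnitude* carried by
  the resampled KS series, not its spectrum.
- The hold-phase definition (90% of peak depth) is a kinematic surrogate for
  a 90° knee-flexion hold; no joint angles are computed.
- Whether held-out-split, resubstitution or cross-validated evaluation is
  the "right" protocol for the emulated study is undecidable from the
  available description; the package defaults to a stratified holdout and
  stamps the protocol into every report.
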