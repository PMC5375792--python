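# Methods

This note documents the model behind `wristhr`, its assumptions, the
parameters that matter, the synthetic benchmark, and the numerical choices
made where the design was genuinely open.

## Signal model

The observed wrist PPG in each channel is modeled as

    y(l) = y0(l) + m(l)

where `y0` is the cardiac component (a quasi-periodic waveform whose
fundamental lies at HR/60 Hz, 0.5–3 Hz for healthy adults) and `m` is a
motion artifact that is strongly correlated with simultaneous accelerometer
measurements. The chain removes `m` in three complementary stages — an
adaptive time-domain filter driven by an accelerometer-derived reference, a
sparse frequency-domain representation, and subtraction of the acceleration
spectral envelope — and then tracks the surviving cardiac peak across
windows with a binary classifier.

All processing operates on 8-s windows shifted by 2 s over signals decimated
to 25 Hz and band-passed 0.4–4 Hz (zero-phase, second-order Butterworth).
Zero-phase filtering was chosen so the PPG and accelerometer channels stay
time-aligned; filtering is applied after decimation (the decimator applies
its own anti-alias low-pass).

## Stage parameters

| parameter | default | meaning |
|---|---|---|
| `window_s` / `shift_s` | 8 s / 2 s | analysis window and hop |
| `fs_target` | 25 Hz | processing rate after decimation |
| `bp_low`..`bp_high` | 0.4–4 Hz | Butterworth band, order 2 |
| `lms_order` | 25 | tap-delay length of the LMS filter |
| `mu` | 0.005 | LMS step size |
| `n_grid` (N) | 1024 | redundant DFT grid size (M = 200 rows) |
| `lam` (λ) | 1e-10 | ridge on the M-FOCUSS normal-equation kernel |
| `p` | 0.8 | sparsity (diversity) exponent, in (0, 1] |
| `tau` | 1.0 | row-sparsity weight of the mixed-norm objective; its role is absorbed by λ in the reweighted iteration and it is kept only for the record |
| `max_bin` | 199 | analysis range 0..199 bins ≈ 0–4.86 Hz (covers 230 BPM) |
| `subtract_fraction` | 0.2 | relative post-subtraction threshold (pmax/5) |
| `xi` (ξ) | 0.7 | candidate threshold κ = ξ·max(spectrum) |
| `pred_step_hz` | 0.02 Hz | fallback step per window (1.2 BPM per 2 s) |
| `smoother_window` | 10 | history length for trend extrapolation |
| `label_tol_bpm` | 2 BPM | training-label tolerance around the truth |

## Stage notes and open choices

**PCA motion reference.** Computed per window (motion axes change over a
session): standardize the three accelerometer channels, form their
correlation matrix, diagonalize with cyclic Jacobi rotations (off-diagonal
threshold 1e-12, ≤ 100 sweeps), and use the first principal component's
scores. Only PC1 is used even when the second eigenvalue is close. The
reference is sign-normalized (non-negative correlation with the first
accelerometer axis) and scaled to unit variance. Rest windows with a
zero-variance channel get a zero reference, which makes the LMS stage an
exact pass-through.

**LMS sign convention.** A scalar-reference write-up of the weight update
can carry either sign; the update implemented is the stochastic-gradient
descent direction on e(l)², `w ← w + μ·e·a⃗`, which is the convergent form
(verified by the suite's convergence test; the opposite sign diverges for
correlated e and a). The "order 25" filter is a 25-tap delay line on the
reference. Tap weights persist across the overlapping windows of a session
— each window is filtered in full, starting from the previous window's
final weights — and are reset between sessions.

**Regularized M-FOCUSS.** The MMV problem Y = ΦX + V (Y the two cleansed
PPG channels, or the three accelerometer channels, as columns) is solved by
iteratively reweighted least squares with W = diag(c_i^{1−p/2}), starting
from the matched filter X₀ = Φᴴ Y, stopping at relative Frobenius change
< 1e-4 or 100 iterations (non-convergence sets a flag on the frame rather
than raising — on noisy windows the tail of the iteration creeps while the
dominant rows are long settled). Rows below 1e-4 of the maximum row norm
are pruned **after** convergence. Pruning *during* the iteration is
deliberately restricted to numerically dead rows (≤ 1e-8 relative): harder
mid-iteration pruning forces the refit onto nearly collinear neighboring
dictionary columns, which develop huge canceling coefficients that the
reweighting then amplifies — an instability we observed and removed. Since
the measurements are real and the dictionary complex, solutions are
conjugate-symmetric (energy mirrors at N−n); downstream analysis reads only
bins 0..199, far below the mirror point.

**Spectrum subtraction.** Spectra are restricted to bins 0..199 *then*
normalized to unit energy (sum of squared coefficients = 1), so the
normalization is not distorted by mirror-half energy. Negative
post-subtraction values are clipped to zero; coefficients exactly equal to
the pmax/5 threshold are kept.

**Peak tracking.** Candidates are strict local maxima above κ; a plateau
contributes its leftmost bin. Candidates from the two PPG channels are
merged by bin (larger coefficient wins) and the coefficient ratio C uses
the merged maximum. The SVM uses a linear kernel on min-max-scaled (C, S)
with balanced class weights — a 2-D feature space rarely warrants more;
the kernel is configurable. Training labels mark at most one candidate per
window as true (closest to truth within 2 BPM, ties to the lower bin), and
during training the previous window's *truth* frequency stands in for the
previous estimate when computing S. The fallback trend predictor is an
ordinary least-squares line over the last ≤ 10 accepted frequencies
evaluated one step ahead (mean for < 3 points); the fallback step is
0.02 Hz (= 1.2 BPM per 2-s hop, a physiologic slew rate). The first window is initialized from the largest candidate between
0.5 and 3 Hz, never from ground truth. Estimates are clamped to 30–230 BPM
with a warning.

**Evaluation.** Bland–Altman uses differences est − truth and the sample
(n−1) standard deviation, the clinical convention. AAEP is reported in
percent. Cross-validation uses stratified folds with a seeded shuffle.

## Synthetic sessions

`simulate_session` emulates a treadmill recording: heart rate follows
piecewise-linear ramps (default 80 → 160 → 130 BPM over 300 s, mirroring a
rest / moderate / fast / recover / fast / cool-down protocol); each PPG
channel is a sum of three cardiac harmonics (amplitudes 1, 0.4, 0.2) driven
by the integrated instantaneous heart-rate phase, plus an artifact linearly
coupled (2×3 mixing matrix, per-channel gain α) from the noise-free
accelerometer components, plus white noise (σ = 0.1); each accelerometer
axis carries a drifting cadence sinusoid with a weak second harmonic and
noise. Per-window truth is the mean instantaneous HR over the window.

By default the cadence trajectory stays ≥ 0.3 Hz below the cardiac
frequency, separating the easy regime from the hard one; a dedicated
`cadence_mode="crossing"` sweeps the cadence through the heart-rate line.
The training-corpus builder alternates tracking and crossing sessions and
varies harmonic richness and artifact gain so both candidate classes are
well represented.

What the generator does **not** model: realistic PPG pulse morphology
(dicrotic notch asymmetry), sensor saturation, baseline wander, skin-contact
transients, or broadband/impulsive motion. Passing the synthetic benchmark
therefore demonstrates the correctness and robustness of the chain under
spectrally structured artifacts, not field performance on real wrist
recordings; real-data evaluation requires recordings in the supported
6-row matrix dialect plus per-window reference BPM.

## Problem sizes

Tests and the acceptance script use 40–120 s sessions (17–57 windows) and a
5-session, 60-s training corpus — large enough that every window exercises
the full chain and tracking statistics stabilize, while the whole suite
runs in a few minutes. The generator's default protocol remains the full
300-s session.

## Known limitations

- When the cadence sits exactly on the heart-rate line for a long stretch
  (the `crossing` stress mode), spectrum subtraction removes the cardiac
  peak together with the artifact and the tracker falls back to the ±0.02
  Hz/window predictor, which cannot follow fast ramps; this mirrors the
  known hard case for envelope-subtraction methods.
- λ = 1e-10 makes the sparse solver effectively interpolating: residual
  noise is represented as additional small spectral rows rather than
  suppressed, and is handled downstream by the ξ and pmax/5 thresholds.
- The classifier is trained on synthetic candidate statistics; for real
  recordings it should be retrained on sessions with reference BPM
  (`wristhr train`).
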