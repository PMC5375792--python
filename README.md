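# wristhr

Heart-rate estimation from wrist photoplethysmography (PPG) during intense
physical activity, when motion artifacts dominate the optical signal.

Wrist-worn devices measure two PPG channels and three accelerometer axes at
125 Hz. During running, arm swing couples rhythmic motion artifacts into the
PPG whose spectral peaks can dwarf the cardiac line, so naive peak picking
locks onto the cadence instead of the heart rate. `wristhr` implements a
full artifact-robust estimation chain over sliding 8-s windows (2-s hop, 25
Hz after decimation):

1. **Preprocessing** — decimation 125 → 25 Hz and zero-phase second-order
   Butterworth band-pass (0.4–4 Hz).
2. **Motion reference (PCA)** — the three accelerometer channels are
   standardized, their correlation matrix is diagonalized by cyclic Jacobi
   rotations, and the first principal component's scores form the reference
   artifact series a(l).
3. **Adaptive cancellation (LMS)** — an order-25 tap-delay least-mean-squares
   filter (μ = 0.005) predicts the artifact from a(l) and subtracts it:
   e(l) = y(l) − wᵀa⃗(l), w ← w + μ·e(l)·a⃗(l).
4. **Sparse spectra (Regularized M-FOCUSS)** — the two cleansed PPG channels
   are modeled jointly as Y = ΦX + V on a redundant M×N DFT dictionary
   (M = 200, N = 1024), with row-sparse X recovered by iteratively
   reweighted least squares: W = diag(c_i^{1−p/2}), X ← W·(ΦW)ᴴ(ΦW(ΦW)ᴴ +
   λI)⁻¹Y, with p = 0.8 and λ = 10⁻¹⁰. The accelerometer channels are
   solved on the same grid.
5. **Spectrum subtraction** — all power spectra are restricted to grid bins
   0–199 and normalized to unit energy; the per-bin maximum of the three
   acceleration spectra is subtracted from each PPG spectrum and everything
   below one fifth of the post-subtraction maximum is zeroed.
6. **SVM peak tracking** — spectral peaks above κ = 0.7·max become
   candidates, described by the coefficient ratio C = coe/coe_max and the
   distance S = |f − f_prev| (Hz). A linear-kernel SVM classifies true vs
   false peaks; one predicted-true peak wins outright, among several the one
   closest to the previous estimate wins, and if none survives the estimate
   is nudged ±0.02 Hz along the trend of the last ten estimates. Finally
   BPM = f_HR × 60.

Agreement with ground truth is scored by average absolute error (AAE, BPM),
average absolute error percentage (AAEP, %), Bland–Altman limits of
agreement u ± 1.96σ, Pearson correlation, and stratified 10-fold
cross-validation accuracy of the peak classifier.

A synthetic treadmill-session generator (`wristhr.simulate`) produces
structured PPG + accelerometer + truth data emulating a rest/run/fast
protocol, so the whole chain is testable without any external download.
The package also reads the common 6-row MATLAB matrix dialect
(ECG, PPG1, PPG2, ACCX, ACCY, ACCZ at 125 Hz) and a plain CSV dialect.

## Worked example

```python
from wristhr import (HeartRateModel, PipelineConfig, SimConfig,
                     simulate_session, simulate_training_corpus)
from wristhr.tracking import train_classifier

cfg = PipelineConfig()

# train the peak classifier on a small synthetic corpus
feats, labels = simulate_training_corpus(n_sessions=5, seed=7,
                                         duration_s=60, pipeline_cfg=cfg)
clf = train_classifier(feats, labels)

# estimate a session with moderate motion artifacts
record, truth = simulate_session(
    SimConfig(seed=42, duration_s=120, artifact_gain=(1.0, 1.0)), cfg)
results = HeartRateModel(record, clf, cfg).fit()
print(results.summary())
```

prints

```
HeartRateModel results
======================
windows              57
window / hop         8 s / 2 s
BPM mean (range)     104.1 (80.6-134.8)
selection flags      initialized=1, rule1=49, rule2=7
AAE                  0.448 BPM
AAEP                 0.450 %
Pearson r            0.9996
Bland-Altman LOA     [-0.67, 1.20] BPM
```

i.e. 57 overlapping windows were tracked, 49 of them resolved by a single
SVM-accepted peak, 7 by the closest-to-previous rule, and the estimates
agree with the synthetic ground truth to ~0.45 BPM on average.

The same workflow is available from the shell:

```sh
wristhr simulate --seed 42 --duration 120 --output sess
wristhr train --inputs a.mat b.mat --truths a_bpm.txt b_bpm.txt \
              --output-model clf.joblib
wristhr estimate --input sess.mat --truth sess_bpm.txt \
                 --model clf.joblib --output trace.csv
wristhr evaluate --trace trace.csv --report report.json --plots figs/
```

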