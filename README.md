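# myoscreen

**Surface-EMG-based sarcopenia screening: simulation, feature extraction,
statistics, voting classification, and Shapley interpretation.**

Sarcopenia — age-related loss of skeletal muscle mass and function — is
diagnosed by combining muscle-mass, grip-strength, and physical-performance
measurements (AWGS 2019 criteria), a protocol too cumbersome for routine
community screening. Because the disease changes motor-unit (MU) physiology
(fewer, larger, less stable MUs), its signature should be visible in surface
electromyograms (sEMG) of a simple grip task. `myoscreen` implements that
screening idea end to end for researchers in biomedical signal processing:

1. **simulate** — synthetic multichannel sEMG with MU-level group structure
   (Fuglevand-style recruitment, renewal discharge trains, channel-specific
   MUAP templates) plus AWGS-consistent subject metadata, so the whole
   pipeline is testable without clinical data;
2. **preprocess** — 50 Hz-harmonic notch + 10–500 Hz zero-phase Butterworth
   filtering, automated stationary 3-s segment selection, 200 ms / 50 ms
   sliding windows;
3. **features** — nine features per window: RMS, MAV, iEMG, waveform length
   (WL), zero crossings (ZC), slope-sign changes (SSC), and three features of
   the Morlet continuous wavelet transform
   `C(a,b) = a^{-1/2} Σ_k x[k] ψ*((k−b)/a)`, `ψ(t) = e^{iω₀t} e^{−t²/2}`:
   mean per-scale power (CWT_power), wavelet entropy
   `WE = −Σ_a h_a ln h_a` of the normalized per-scale power, and the excess
   kurtosis of the kernel-estimated density of pooled coefficient moduli
   (CWT_kurtosis). Features are MVC-normalized per subject and channel;
4. **stats** — Mann-Whitney U (groups) and Wilcoxon signed-rank (levels)
   with exact midrank-tie enumeration for small samples, plus the AWGS 2019
   screening rule;
5. **classify** — a weighted soft-voting ensemble of a linear SVM, random
   forest, and gradient boosting machine,
   `ŷ = argmax_j Σ_i w_i P_{i,j}`, with weights grid-searched for maximal
   training sensitivity, evaluated by class-balanced subject-level five-fold
   cross-validation (accuracy, sensitivity, specificity, F1, ROC-AUC, and
   the optimal operating point under a 0.65 specificity floor);
6. **interpret** — permutation-sampling Shapley values of the ensemble score
   with local-accuracy guarantees, and the drop-3-least-important feature
   selection.

See `docs/methods.md` for the model details, defaults, and limitations.

## Worked example

```python
from myoscreen import SimulationConfig, generate_dataset, cross_validate
from myoscreen.pipeline import (CLASSIFIER_CHANNELS, extract_feature_table,
                                subject_vectors)

cfg = SimulationConfig(n_healthy=15, n_sarcopenic=15, seed=7)
dataset = generate_dataset(cfg)                 # 30 subjects, 7 trials each
table = extract_feature_table(dataset, channels=CLASSIFIER_CHANNELS)
x, y, names, _ = subject_vectors(table)         # 15 features per subject
report = cross_validate(x, y, k=5, seed=1)
print({k: round(v, 3) for k, v in report.mean.items()}, round(report.auc, 3))
```

This prints (a few minutes of compute):

```
{'accuracy': 0.9, 'sensitivity': 0.867, 'specificity': 0.933, 'f1': 0.893} 0.884
```

i.e. with the default simulated sarcopenia contrast (half the motor units,
1.6× MUAP amplitude, 2× discharge jitter, 1.4× MUAP duration), the voting
classifier recovers the sarcopenic group from a 30-subject cohort with 87 %
sensitivity, 93 % specificity and an AUC of 0.88 under subject-level five-fold
cross-validation. Larger cohorts separate better: the default 93-subject
study configuration reaches sensitivity and AUC above 0.95.

A command-line interface mirrors the pipeline stages:

```bash
myoscreen simulate --out data/ --seed 1
myoscreen features --in data/ --out features.csv
myoscreen stats --features features.csv --out report.csv
myoscreen train-eval --features features.csv --seed 1
myoscreen explain --features features.csv --out impacts.csv
```

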