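# Methods

`myoscreen` implements an sEMG-based screening pipeline for sarcopenia: given
multichannel forearm surface-EMG recorded during grip contractions at known
fractions of maximal voluntary contraction (MVC), it extracts nine
window-level features, compares them between healthy and sarcopenic groups,
classifies subjects with a sensitivity-weighted soft-voting ensemble, and
attributes the classifier's decisions to features with Shapley values. A
motor-unit-level simulator generates synthetic cohorts so that every stage is
testable end to end without access to clinical recordings.

## Synthetic cohorts

Each simulated muscle is a pool of motor units (MUs). Recruitment thresholds
follow an exponential ramp over the pool (Fuglevand-style size principle,
recruitment range 40, last unit recruited at 75 % MVC), firing rates rise
linearly from 8 pulses/s at recruitment toward 35 pulses/s at full drive, and
discharges are renewal processes with Gaussian inter-spike intervals
(CV 0.15) plus per-discharge Gaussian timing jitter (SD 1 ms for healthy
muscle). MU action potentials are first derivatives of a Gaussian
(width 1.5–3 ms), attenuated and delayed across the six electrode channels
with distance from the unit's territory; amplitudes grow exponentially with
recruitment order (30-fold range). Signals are the superposition of all
recruited units' jittered trains plus white Gaussian measurement noise
(SD 0.02 in the simulator's arbitrary amplitude units, a small fraction of
the sub-maximal signal RMS), sampled at 2000 Hz.

Sarcopenia is expressed through four contrast multipliers applied to this
baseline, following the accepted denervation–reinnervation picture of the
disease: MU count × 0.5 (Poisson mean 120 → 60), MUAP amplitude × 1.6,
discharge jitter × 2, and MUAP duration × 1.4 (longer action potentials of
enlarged units, which shifts spectral content downward). Setting all four to
1.0 yields a null cohort in which both groups share one generating process —
the basis of the calibration tests. The duration multiplier is what makes
the groups separable after MVC normalization: a pure amplitude change cancels
in normalization, whereas fewer, longer, less regular MUAPs alter signal
structure at matched relative force.

The study protocol is mirrored per subject: three MVC trials (5 s of
simulated hold; features use a 3-s segment) and, by default, two 10-s
force-tracking trials at each of 20 % and 50 % MVC. The protocol description
of "four sub-maximal contractions at the two levels" is ambiguous between
four per level and four total; the default is two per level (four total),
configurable. Simulated screening measurements (grip strength, skeletal
muscle index, five-times chair-stand time) are drawn from group- and
sex-conditional Gaussians with the cohort's reported group means, truncated
at the AWGS 2019 cutoffs so the screening rule reproduces each subject's
label by construction (sarcopenic draws enforce low mass and low strength;
healthy draws enforce all three measures normal).

What the simulator does *not* emulate: volume-conductor anatomy, force
feedback and tracking error, fatigue, electrode artifacts, inter-subject
anatomical variability beyond MU-pool randomness, and any correlation
between AWGS measurements and the subject's own EMG physiology. Passing
end-to-end tests therefore show that the pipeline recovers the encoded
MU-level group structure, not that real cohorts are classifiable at the same
accuracy.

## Preprocessing

Trials are demeaned, notch-filtered at every multiple of 50 Hz inside the
passband (50–450 Hz, second-order IIR, Q = 30 — narrow enough to spare the
EMG band), and bandpassed 10–500 Hz with a 3rd-order Butterworth filter.
All filters run forward–backward (zero phase, reflective edge padding):
waveform-shape features (WL, SSC) would otherwise be biased by phase
distortion. Harmonic notches above the passband edge are not applied.

The study selected a stationary 3-s segment per contraction by visual
inspection. For reproducibility this is automated: the contiguous 3-s slice
minimizing the variance of the 250-ms moving-RMS envelope summed over
channels is selected, earliest slice on ties (the criterion is rounded at
1e-12 before the argmin so exact ties are not broken by round-off). Windows
are then 200 ms long with a 50 ms step (400 samples, step 100 at 2000 Hz;
57 windows per 3-s segment).

## Features

Per window and channel, six Hudgins time-domain features: RMS, MAV,
iEMG (= N·MAV), waveform length, zero crossings and slope-sign changes. The
ZC/SSC deadband threshold is 0.01 × the window RMS in the pipeline (0 by
default in the bare function); a threshold proportional to window RMS keeps
both counts invariant to channel gain, which the normalization tests rely
on. Three features come from the continuous wavelet transform with Morlet
mother wavelet psi(t) = exp(i·w0·t)·exp(-t²/2), w0 = 5 (the conventional
value; the analysis tradition this follows does not fix it):

* `CWT_power`: per-scale mean |C|², averaged over the 60 scales
  {3.6, 4.6, …, 62.6} (scales in samples; pseudo-frequency
  f = w0·fs/(2π·a) ≈ 25–440 Hz at 2000 Hz — the scale set is kept as given
  even though the implied range differs slightly from the 10–500 Hz band);
* `WE`: Shannon entropy, natural log, of the normalized per-scale power
  (bounded by ln 60 ≈ 4.094);
* `CWT_kurtosis`: unbiased excess kurtosis of the kernel-density estimate of
  the pooled coefficient moduli, evaluated at m = 100 equally spaced points
  spanning the pooled range.

The CWT is computed as an FFT-based correlation with the kernel truncated at
|t/a| ≤ 6 (Gaussian envelope < 1.5e-8 of peak there); it agrees with direct
evaluation of the correlation sum to ~1e-8 relative. The coefficient values
pooled for the kurtosis feature are the moduli |C| — real, non-negative and
wavelet-phase-invariant; pooling real parts instead is a defensible
alternative, and this choice is recorded here because the feature's sign and
scale depend on it. The kernel density uses a Gaussian kernel with Scott's
bandwidth (sd·n^(-1/5)) and is evaluated through linear binning of the
~24 000 pooled values into 512 bins, which changes density values by well
under 1 % relative to exact summation while making the study-scale run
tractable. Degenerate inputs (zero spread, all-zero power) raise instead of
returning a value.

Sub-maximal features are normalized channel-specifically: each raw value is
divided by the mean of the same feature over the subject's three MVC trials
on the same channel (normalization precedes any averaging). Aggregation has
two modes: `stats` averages each normalized feature over all windows, trials
and channels jointly (used for the group comparisons); `classify` averages
within each channel first and then across the chosen channel set.

## Statistics

Group differences per (feature, level) use the two-sided Mann-Whitney U
test; level differences within group use the Wilcoxon matched-pairs
signed-rank test, both at alpha = 0.05 without multiplicity correction,
matching the study's reporting (a Holm adjustment is available but off by
default). Exact permutation p-values with midrank tie handling are computed
by shift-algorithm counting for combined n ≤ 20 (Mann-Whitney) and n ≤ 25
nonzero pairs (Wilcoxon) — crossovers chosen so exact enumeration stays
desk-scale — and the tie-corrected, continuity-corrected normal
approximation is used above. Two-sided p-values double the smaller tail and
cap at 1. Levene (classic, mean-centered) and one-sample KS checks against a
fitted Gaussian are reported for audit only; the pipeline is nonparametric
regardless of their outcome. The AWGS 2019 rule is: low mass if
SMI < 7.0 (M) / 5.7 (F) kg/m²; low strength if grip < 28 (M) / 18 (F) kg;
low performance if the five-times chair-stand time ≥ 12 s; sarcopenic = low
mass AND (low strength OR low performance); healthy = none low; otherwise
intermediate.

## Classification

Subject vectors are the nine features at both levels from the mean of
channels two and three (FCR, FDS), minus the three least important features
(CWT_power@20, WE@20, SSC@50) — 15 entries. Members: linear-kernel SVM with
Platt-scaled probabilities (calibrated on inner folds), 200-tree random
forest, and a gradient boosting machine (200 rounds, depth 3).
Hyperparameters (SVM C ∈ {0.1, 1, 10}; forest depth ∈ {3, 5, none}; boosting
learning rate ∈ {0.05, 0.1}) are grid-searched on the training folds with
3-fold inner CV; the grids are small and standard since none were prescribed.
Voting weights are searched exhaustively over {0, 0.1, …, 1}³ \ {0,0,0}
against inner-out-of-fold sensitivity, ties broken by higher specificity and
then the lexicographically smallest vector; weights are returned normalized.
Vote ties (weighted score exactly 0.5) resolve to the sarcopenic class —
screening favors sensitivity.

Evaluation is subject-level five-fold cross-validation with class-balanced
folds (per-fold class counts differ by at most one); per-fold accuracy,
sensitivity, specificity and F1 are reported as mean ± SD across folds, and
the pooled held-out scores produce the ROC (thresholds at the distinct score
values), trapezoidal AUC, and the optimal operating point: maximal
sensitivity among points with specificity above 0.65. The evaluation scheme
described in the source protocol ("leave-one-out on each fold") is
ambiguous; the implementation trains on four folds and tests the fifth,
which matches the mean ± SD reporting structure. No held-out subject
influences member fitting, hyperparameter choice, or weight search.

## Interpretation

Shapley values are estimated by permutation sampling on the ensemble's
continuous positive-class score: per explained subject, feature orderings
are drawn uniformly (200 by default), one background subject per ordering
supplies the values of absent features, and marginal contributions telescope
along the ordering. The base value is the mean score over the background
sample (up to 50 training subjects), so local accuracy (base + sum of
impacts = model score) holds up to Monte-Carlo error; per-value standard
errors are returned. Feature importance is the mean |impact| across
subjects; the drop-3-lowest selection removes the three least important
(ties drop lexicographically later names). Leakage-safe practice estimates
impacts on training folds only; the all-cohort mode (model fit and explained
on all subjects) is available explicitly and is what the summary in the
reproduction script uses.

## Problem sizes and numerical choices

The end-to-end recovery check runs the full default cohort (93 subjects) on
the two classifier channels; the null-calibration check runs twenty reduced
cohorts (5 + 5 subjects, one featurized channel, one trial per level, pool
mean 40, smaller member ensembles) — calibration properties do not depend on
cohort scale, and these sizes keep the suite fast. The generator-level null
calibration uses 400 reduced datasets and a raw-RMS summary statistic.
Filtering tolerances, tie-break rules, and degenerate-input behavior are
stated above next to each operation; all randomness flows from explicit
seeds and every pipeline stage is deterministic given its inputs and seed.

## Known limitations

* The simulator's group contrast is low-dimensional by design; classifier
  performance on it says nothing quantitative about clinical cohorts.
* The CWT-kurtosis feature depends on the KDE convention (pooled moduli,
  Scott bandwidth, range-spanning grid); alternative conventions shift its
  values systematically.
* The exact-test branches assume exchangeability under the null; the
  normal-approximation branches are asymptotic and can differ from exact
  p-values by up to ~0.01 near the crossover sizes.
* `intermediate` subjects (some but not all AWGS criteria) are screened out,
  mirroring the study design; the classifier never sees them.
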