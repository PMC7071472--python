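# Methods

`pbciscreen` implements a screening analysis for passive brain–computer
interfaces (pBCIs): predict, from 60 s of two-channel resting-state EEG
(Fp1/Fp2), how much usable variability — the *dynamic range* — a user's
task-related EEG features would show during actual pBCI use, so that users
with ample dynamic range can skip a time-consuming individual calibration
session. This note documents the models, conventions and numerical choices;
the README shows the workflow.

## Features and their dynamic range

Three per-segment features are computed on 1-s windows (50% overlap):

- **FAA** — frontal alpha asymmetry, `ln(P_α(Fp1) / P_α(Fp2))` with
  α = 10–12 Hz (nats); a valence marker.
- **rFTP** — relative frontal theta power: theta (4–8 Hz) power divided by
  total 2–18 Hz power, with band and total power each averaged across the
  two channels *before* the ratio; a relaxation marker.
- **rFLBP** — the same construction for low beta (12–15 Hz); an attention
  marker.

Band powers are one-sided periodograms with a rectangular window on the
1-s segment, so the frequency resolution is 1 Hz and a band power is the
sum of PSD bins times the bin width. Band intervals are half-open
`[lo, hi)`: the five disjoint bands delta/theta/alpha(8–12)/low-beta/beta
then partition 2–18 Hz exactly and shared edges (4, 8, 12, 15 Hz) are never
double-counted. The canonical band set (delta 2–4, theta 4–8, alpha1 8–9,
alpha2 10–12, alpha3 8–12, low beta 12–15, beta 15–18, total 2–18)
deliberately leaves 9–10 Hz uncovered by alpha1/alpha2 and lets alpha3
overlap both — reproduced as conventionally printed, not "fixed".

The **dynamic range** of a feature is the interquartile range (Q3 − Q1) of
its per-segment values, sessions concatenated (task session plus flanking
resting period for rFTP/rFLBP; task session only for FAA, configurable).
Quantiles use linear interpolation between order statistics (Hyndman–Fan
type 7, numpy's default) so every IQR is reproducible bit for bit.

## Preprocessing

`resample → [LMS] → band-pass → segment → detect/reject`:

- Polyphase rational resampling to 256 Hz (2048 → 256 is exact 8:1
  decimation). Segment boundaries are always computed on the 256 Hz signal
  (256 samples per window).
- Zero-phase band-pass 0.5–30 Hz, order-4 Butterworth applied
  forward–backward; zero phase keeps segment alignment intact.
- **Blink rejection** (sessions without EOG references): a multiscale
  derivative-summation detector. The prefrontal channel mean is low-passed
  below 5 Hz (blinks are slow, large deflections; this keeps strong alpha
  bursts from triggering the detector), the net signal change over trailing
  windows of 50/100/200 ms is computed (the sum of first differences over a
  window telescopes to `x[i] − x[i−w]`), and samples where any scale's
  robust z-score (median/MAD) exceeds `k = 8` are flagged. Flags closer
  than 100 ms merge; intervals are padded by 50 ms. Every 1-s window
  intersecting a detected interval is masked out, never deleted, so
  segment indices stay aligned.
- **LMS ocular removal** (EOG-referenced sessions, by default the
  attention session only): normalized least-mean-squares adaptive
  prediction of each EEG channel from the two EOG channels, 5 taps per
  reference, normalized step 0.3 (NLMS is stable for steps below 2; 0.3
  converges within ~2 s on blink-dominated references). The EEG channel is
  replaced by the prediction residual; no windows are rejected.

## The 112 resting-state predictors

From the artifact-free resting segments: 8 bands × 7 per-segment
quantities (absolute power at Fp1, Fp2, and their mean; relative power at
Fp1, Fp2, and their mean; interhemispheric asymmetry `ln(P_Fp1/P_Fp2)` of
absolute powers) × 2 statistics (mean and IQR over segments) = 112 named
scalars, e.g. `IQR-Asym-Alpha-8-12` or `Mean-Rel-Fp12-Theta-4-8` (`Fp12`
denotes the two-channel power mean; asymmetry names carry no channel
token). The two full-band relative predictors are identically 1 (mean) and
0 (IQR); they are kept so the vocabulary stays at 112 — feature selection
simply never gains from them. Relative and asymmetry predictors are
invariant to amplifier gain; absolute predictors scale with gain².

## Prediction and evaluation

- **nRMSE** = RMSE of the predicted vs actual IQRs, divided by
  (max − min) of the actual IQRs over participants.
- **LOOCV**: one held-out participant per fold; feature selection and
  model fitting (including predictor standardization, and target
  standardization for the SVR families) see only the training fold.
- **FSFS** (forward sequential feature selection): greedy, starting from
  the empty set whose criterion is the nRMSE of predicting the training
  mean. Each round refits the model with every remaining candidate and
  adds the best one — only if it improves the training-fit nRMSE by at
  least 5% of the empty-set criterion. The materiality threshold is
  needed because flexible regressors can shave the training fit
  indefinitely by tiny amounts; with it, pure-noise targets select ~0–3
  predictors and realistic targets select small sets (1–4), in line with
  reported behaviour of this selection style. Ties break to canonical
  predictor-name order for determinism. An inner criterion based on
  training-fit nRMSE is deliberate: it is cheap, deterministic, and the
  evaluation nRMSE stays untouched by selection.
- **Model registry** (scikit-learn): MLR (ordinary least squares), TR
  (depth-4 regression tree, min leaf 2), ebTR (bagging of 30 such trees),
  SVMR (linear-kernel ε-SVR, C = 1, ε = 0.1 on the standardized target),
  kSVMR (RBF kernel, `gamma="scale"`), GPR (constant × RBF kernel,
  `normalize_y`, jitter 1e-6). Hyperparameters are documented defaults, not
  fitted values, and can be overridden per `ModelSpec`. The `Baseline`
  model is MLR on a fixed feature-matched predictor (the resting IQR of
  the same quantity whose task IQR is being predicted) with no selection;
  `Mean` predicts the training-fold mean.
- **Paired permutation test**: statistic `nRMSE(a) − nRMSE(b)` (the
  shared normalizing range cancels); under the null each participant's two
  squared errors are exchangeable, so the reference distribution swaps
  them with probability ½ (10,000 permutations by default). One-tailed,
  add-one smoothed: `p = (1 + #{T_perm ≥ T_obs}) / (n_perm + 1)`; small p
  means model b's error is credibly smaller.

## Suitability screening

Per feature, the threshold is `mean − SD` of the cohort's actual IQRs
(sample SD, n−1). A participant whose *predicted* IQR falls below it is
recommended an individual calibration session; everyone else can skip it.
The rule is a heuristic screen — it is labelled as such in the report and
has no validated operating point.

## Synthetic cohorts

No public recordings exist for this design, so the generator is
first-class: each channel is a sum of six band-limited Gaussian
oscillations (delta 2–4, theta 4–8, low alpha 8–10, high alpha 10–12, low
beta 12–15, beta 15–18 Hz; brick-wall-filtered white noise carriers), a
1/f background (spectral exponent 1.0, 3 µV RMS), and optional blink
transients. Oscillation amplitudes are piecewise-constant over 0.5-s
epochs and follow a stationary AR(1) log-amplitude process (ρ = 0.9). The
*modulation depth* — the stationary SD of the log-amplitude, drawn
uniformly per participant, channel and band — is what differentiates
participants: asymmetry features get their dynamic range from the two
channels' independent envelope paths, power features from the depths
themselves. A mean-reverting AR(1) is used rather than an unbounded random
walk so that feature IQRs are stationary properties rather than artifacts
of session length. The alpha range is split into two independent processes
so low- and high-alpha predictors are genuinely distinct quantities.

Default conditions: 35 participants, 60-s resting plus three 60-s task
sessions, 2048 Hz native rate, band RMS amplitudes 4/3/3/3/1.5/1.2 µV,
depth ranges 0.05–0.5 (delta), 0.05–0.8 (theta), 0.05–1.2 (both alpha
bands), 0.05–0.7 (low beta), 0.05–0.5 (beta) nats — wide ranges emulating
the large interindividual variability that motivates screening (some
individuals' dynamic ranges are half or double the cohort average; alpha
is the most volatile rhythm). Blinks: Poisson 8/min, biphasic
raised-cosine pulses of 200–400 ms, peak 12× the EEG background RMS, 1.5×
larger again on the periocular EOG channels (which are otherwise
independent noise, enabling the LMS stage). Ground-truth per-segment
feature values and all 112 resting predictors are computed directly from
the amplitude envelopes — oscillations only, before background, rendering
or artifact injection — so truth IQRs are exact by construction.

**Predictor→IQR links.** `generate_cohort` realizes a configurable
statistical link: each participant's true task-feature IQR is set to
`coefficient × (their truth resting predictor) + Gaussian noise` by
rescaling the task session's log-amplitude deviations until the truth IQR
hits the target (bracketed scalar root-finding; relative-power features
saturate, so unreachable targets are clamped to the best achievable scale
and logged). Default links are feature-matched — FAA ←
`IQR-Asym-Alpha-10-12`, rFTP ← `IQR-Rel-Fp12-Theta-4-8`, rFLBP ←
`IQR-Rel-Fp12-Beta-12-15` — with noise SD 10% of the noise-free target
spread. `generate_cohort_truth` exposes the same cohort at ground-truth
level (truth predictor matrix and linked targets, no waveforms), which is
how the estimation machinery is validated in isolation.

All randomness flows from the root seed through
`default_rng([seed, participant, stream])` substreams; identical
configurations reproduce cohorts bit for bit, and the pipeline summary is
byte-identical across re-runs.

### What the generator does and does not emulate

It emulates band-structured spectra with realistic prefrontal amplitudes,
participant-specific envelope variability, stereotyped blinks, EOG
crosstalk, and a controllable resting→task statistical link. It does not
emulate real task stimuli (videos, meditation, visual search), non-blink
artifacts (EMG, electrode drift, saccades beyond the EOG model),
non-Gaussian or cross-frequency-coupled oscillation structure, or any
empirically calibrated distribution of human feature variability. Passing
tests therefore show that the *pipeline machinery* is correct and that
planted relationships of realistic size are recoverable — not that real
cohorts carry such relationships.

## Validation design and problem sizes

- Numerical primitives are checked against independent oracles:
  bin-centered-sinusoid Parseval power (A²/2), a sort-based quantile
  oracle for the IQR, direct arithmetic for nRMSE, and a hand-rolled
  leave-one-out mean oracle for LOOCV.
- Artifact handling is scored against the generator's ground truth:
  ≥90% of injected blinks detected with ≤1 false interval per clean
  minute, ≥95% of blink samples removed after rejection, and LMS residual
  correlation with the EOG below 0.1 on a stationary mixing construction.
- Parameter recovery is tested on 20 cohorts of 35 participants with the
  FAA link at 10% noise, at ground-truth level: LOOCV+FSFS with SVMR must
  stay within 2× the true-predictor oracle's nRMSE and select the true
  predictor in ≥60% of folds (observed: ratio ≈ 1.0, frequency 100%, mean
  selected set 1.0). The measured end-to-end variant (rendering, blinks,
  periodogram estimation) is reported alongside: spectral-estimator noise
  — the 10–12 Hz band spans only two 1-Hz periodogram bins per segment —
  lowers predictor/target reliabilities to ~0.6–0.7 there, so exact
  predictor identification is not expected through the measurement chain,
  while prediction error stays close to the matched baseline.
- Permutation-test calibration: 500 null replicates at 2000 permutations;
  type-I error at α = 0.05 within [0.03, 0.07].
- Cohort-level checks run at 256 Hz native rate (generation and analysis
  grids coincide; the 2048→256 Hz resampling path is exercised separately
  on single recordings). These sizes keep the whole validation suite at a
  few minutes on one CPU.

## Known limitations

- The blink detector is a documented derivative-summation stand-in with
  fully specified parameters, not a re-implementation of any published
  multiwindow algorithm; its thresholds were chosen for the synthetic
  blink morphology and should be re-examined on real data.
- Regression hyperparameters are sensible defaults, not tuned values; no
  hyperparameter search is performed.
- The suitability threshold (mean − SD) is a proposal, not a validated
  decision rule.
- EDF support covers reading (via MNE) and a minimal 16-bit writer
  (integer sampling rate, whole seconds, one recording per file).
- FAA's dynamic range uses task sessions only by default; whether resting
  periods should be pooled for FAA as they are for rFTP/rFLBP is left
  configurable (`faa_include_resting`).
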