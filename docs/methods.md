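# Methods

This note documents the models, conventions and numerical choices behind
`sedeeg`, and what its synthetic-data experiments do and do not show.

## Data model and labeling

A recording is a channels × samples matrix in microvolts with a sampling
rate, canonical 10-20 channel labels, a time-sorted list of MOAA/S
assessments (score 0–5 at a time in seconds from recording start), and
cohort covariates (drug ∈ {propofol, sevoflurane, dexmedetomidine},
remifentanil flag, age 18–70 y, sex). Classification is binary: awake
(MOAA/S 5, 4) vs. sedated (1, 0); scores 3 and 2 are discarded as
transitional. All windows use half-open semantics [t0, t1): the 60-s
segment preceding an assessment at time t is [t−60, t) and excludes the
sample at the assessment instant. Assessments earlier than 60 s into the
recording are skipped with a warning.

## Preprocessing

* Bipolar montage Fp1−F7 / Fp2−F8 by sample-wise subtraction.
* Zero-phase band-pass: 2nd-order Butterworth, 0.5–25 Hz, applied
  forward–backward (`sosfiltfilt`). Forward–backward application doubles
  the effective order but has exactly zero group delay. Measured stop-band
  behavior of this prescription: a 50 Hz tone retains ≈5.5% of its RMS;
  re-applying the filter changes a white-noise PSD over 1–20 Hz by ≈12%
  RMS (pass-band roll-off near both edges at this gentle order). The tests
  assert <8% and <15% respectively.
* Resampling to 250 Hz by polyphase anti-aliased decimation — redundant
  with the 25 Hz band edge, kept as belt and braces.
* Artifact screening is cross-channel on the preprocessed signal: an
  epoch is rejected as "amplitude" if any channel exceeds 500 µV in
  absolute value, else as "flat" if any channel's peak |x| is below
  `flat_eps_uv` (default 0.5 µV) for the whole epoch. A bit-exact zero
  test would be vacuous after IIR filtering — filter ringing makes an
  originally-zeroed span numerically nonzero — so "flat" means
  *practically* zero; genuine burst-suppression troughs (≈1–3 µV with
  sensor noise) pass. Overlapping segments from closely spaced assessments
  are allowed.

## The 44 features

Computed per 4-s, 250-Hz epoch per channel, then fused by the element-wise
median across the two bipolar channels (for two channels the median equals
the mean; NaN in one channel falls back to the other). Canonical order:
items 1–12 time domain, 13–36 frequency domain, 37–44 entropy domain; the
frozen name list is `sedeeg.features.FEATURE_NAMES`.

Conventions and hyper-parameters (none dictated by the task definition;
all follow the cited literature's conventions and are configurable through
`FeatureConfig`):

* **Nonlinear energy** — mean of ψ[x](n) = x(n)² − x(n−1)x(n+1).
* **Hjorth parameters** — activity = var(x); mobility = √(var(Δx)/var(x));
  complexity = mobility(Δx)/mobility(x).
* **Moments** — RMS; kurtosis is the *non-excess* standardized fourth
  moment (Gaussian → 3); skewness the standardized third moment.
* **AM/FM** — Hilbert analytic signal; AM = envelope magnitude, FM =
  unwrapped-phase derivative × fs/2π clipped to 0.5–25 Hz; 5% of samples
  trimmed from *each* edge before the four moments, to suppress Hilbert
  end effects.
* **Burst-suppression ratio** — percentage of epoch samples inside
  contiguous spans with |x| < 5 µV lasting ≥ 0.5 s (Rampil-style
  threshold definition); computed per 4-s epoch.
* **PSD** — Welch, 2-s Hann windows, 50% overlap, 0.5 Hz resolution
  (needed to resolve the 0.5 Hz delta edge), restricted to 0.5–25 Hz.
* **Band powers** — trapezoidal integrals over delta 0.5–4, theta 4–8,
  alpha 8–12, sigma 12–16, beta 16–25 Hz, with shared edges so the five
  bands partition the 0.5–25 Hz total exactly; relative powers divide by
  the total; ratio set: θ/δ, α/δ, σ/δ, β/δ, α/θ, σ/θ, β/θ (the source
  feature list repeats three ratios verbatim; this mapping is the
  package's frozen convention, not recoverable from the original text).
* **SEF95 / peak** — 95% spectral edge with linear interpolation between
  bins; peak frequency breaks ties toward the lower frequency.
* **Entropies** — SVD entropy: delay embedding d = 10, τ = 1, entropy of
  sum-normalized singular values (bits). Spectral entropy: Shannon entropy
  of the normalized PSD scaled by 1/log N into [0, 1]; state entropy: the
  same restricted to 0.8–25 Hz and renormalized in-band (a band-restricted
  proxy for the monitor-style low-frequency de-emphasis; the exact
  construction in the literature is underspecified). Sample entropy:
  m = 2, r = 0.2·SD, Chebyshev distance, self-matches excluded, the same
  template index set for both lengths; no m+1 matches → NaN. Shannon and
  order-2 Rényi entropies of the 32-bin amplitude histogram over
  [min, max] (bits). Permutation entropy: order 3, delay 1, ties ranked by
  temporal index, normalized by log₂6 into [0, 1]. Fractal dimension:
  Higuchi with k_max = 8, least-squares slope of log L(k) vs log(1/k).
* Log base is bits throughout; after z-scoring this affects absolute
  values only, never model behavior.
* Degenerate inputs (constant or zero signals, zero band power) yield 0
  where the definition's limit is 0 and NaN otherwise; NaNs are carried,
  not fatal, and can be median-imputed at model fitting.

## Models

Four families (scikit-learn backends) behind one `fit` /
`predict_probability` surface:

| family | backend | tuned grid (min, max, step) |
|---|---|---|
| EN-LR | `LogisticRegression(saga)` | elastic-net mixing α: 0, 1, 0.1 (11 candidates; C fixed at 1) |
| SVM-G | `SVC(rbf)` + sigmoid calibration | γ, C: 0.1–100; default decade ladder {0.1, 0.25, 0.5, 1, 2.5, 5, 10, 25, 50, 100}; exhaustive 0.1-step grid via `full_grid` |
| RF | `RandomForestClassifier` | trees: 50, 1000, 10 |
| ET-B | `BaggingClassifier(DecisionTree)` | learning cycles (trees): 10, 200, 5 |

ET-B is bootstrap aggregation of full decision trees (all features at every
split); RF additionally subsamples features per split — the two are
deliberately distinct. "Number of learning cycles" is read as the number
of bagged trees. The exhaustive SVM grid (10⁶ points) is impractical on a
desktop; the decade ladder spans the same range and contains the reference
optimum (γ = 2.5, C = 50).

Tuning maximizes mean AUC over grouped 10-fold inner CV (recordings never
straddle folds, preventing within-recording leakage); candidate scores use
the SVM margin / model probability as a rank statistic. Ties go to the
least complex candidate (fewer trees; smaller C then γ; sparser mixing).
Feature z-scoring uses training-row statistics only; constant features are
dropped and zero-imputed at prediction. SVM probabilities come from
Platt-style sigmoid calibration fit by internal CV on the training data.
No class reweighting (AUC is threshold-free). Class imbalance, seeds and
chosen parameters are recorded on the trained model.

Tree-family importances are mean impurity importances normalized so the
maximum is 1; an absolute-coefficient variant exists for EN-LR for
comparison.

## Evaluation designs

* **Outer CV** — leave-one-*recording*-out by default (a subject-level
  option exists since multi-session cohorts blur the two). The headline
  statistic is the AUC of the pooled out-of-fold probabilities, because
  per-fold AUC is undefined for single-class recordings.
* **Uncertainty** — percentile bootstrap (default 1000 draws) resampling
  *recordings* with replacement, respecting within-recording correlation;
  epoch-level resampling is available. Single-class draws are discarded.
* **Operating point** — sensitivity, specificity, F1 at probability 0.5,
  sedated positive.
* **Univariate screening** — each feature used directly as the score;
  orientation-corrected AUC = max(AUC, 1−AUC).
* **Cross-group matrix** — age groups [18, 35), [35, 50), [50, 70] (or
  sex/drug/remifentanil): diagonal = within-group leave-one-recording-out;
  off-diagonal = train on all of group A, test on all epochs of group B.
* **Stability comparison** — per-family AUC with vs. without a
  remifentanil arm; the two-sided p-value bootstraps the AUC difference at
  the recording level from the pooled out-of-fold predictions (no
  refitting inside the bootstrap).

## The synthetic generator

Each recording alternates awake and sedated plateaus (default four of
70 s), with one MOAA/S event at each plateau's end so a full 60-s
pre-event window exists; awake events score 5, sedated events 0 or 1
(transition scores 2–4 optionally emitted to exercise the discard rule).
Signals are sums of band-limited Gaussian processes shaped to per-state
spectral templates plus a 1/f fraction, scaled to physiologic RMS, with
channel-shared and channel-specific components and additive sensor noise
(default SNR 30 dB):

* awake: band weights (δ, θ, α, σ, β) = (0.15, 0.15, 0.35, 0.15, 0.20),
  15 µV RMS — mixed alpha/beta-dominant;
* sedated: (0.60, 0.20, 0.10, 0.05, 0.05), 25 µV RMS — slow-wave
  dominant;
* burst suppression (probability 0.3 per sedated plateau): alternating
  spans with exponential durations (means 2 s suppression / 1 s burst),
  span boundaries shared across channels, 0.5 µV RMS suppression and
  40 µV RMS bursts — suppression is chosen well below the 5 µV BSR
  threshold so detection survives sensor noise and bipolar subtraction.

Cohort covariates are age/sex stratified round-robin (three strata ×
two sexes), mirroring stratified enrolment and guaranteeing nonempty
groups in cross-group designs. Group effects are optional multiplicative
tilts that move relative power from fast bands into delta (clamped so
weights stay positive); a remifentanil flag blends the two state templates
toward their midpoint (`remi_contrast_shrink`), shrinking separability in
kind. Generation is at 250 Hz by default (5 kHz possible, the pipeline
resamples anyway) with one RNG stream per recording derived from
(seed, subject, session), so cohorts are reproducible and parallelizable.

Artifact injection places 4-s spans on the epoch grid of qualifying
windows: movement spans add an in-band 800 µV, 2 Hz oscillation to the
prefrontal electrodes (so it survives the bipolar subtraction); flat spans
zero all electrodes with a 2-s guard margin on each side so that filter
ringing inside the logged span decays below the flat-detection threshold.

**What passing tests show — and do not.** The generator reproduces the
*statistical contracts* the pipeline relies on (two spectrally distinct
states, physiologic amplitudes, burst suppression, cohort structure,
artifact morphology), so green tests demonstrate the pipeline is correct,
leak-free and sensitive in kind. It is not a biophysical model: no PKPD
concentration dynamics, no inter-subject spectral idiosyncrasy, no ocular
or cardiac artifacts, no electrode drift. Synthetic separability is far
stronger than clinical reality — cross-validated AUCs near 1.0 here say
nothing about attainable clinical AUCs.

## Experiment sizes and design choices

Recovery experiments use desk-scale cohorts chosen as the package's
default study conditions: 6–9 recordings (≈360–540 epochs), reduced
hyper-parameter grids passed as explicit overrides, and 200–1000 bootstrap
draws. Two experiment designs deserve note:

* *Planted-feature recovery* plants a 1 SD shift on three features. A much
  larger shift makes any one of the three sufficient, and redundant strong
  predictors mask one another in impurity importance — a known property of
  the statistic, not a defect — pushing individual weights below the 0.3
  threshold.
* *Age cross-matrix* uses a moderated-contrast template pair with a strong
  age tilt and 12 dB SNR: with the default templates every cell saturates
  near AUC 1.0 and no within- vs cross-group gap can appear. The moderated
  design reproduces the qualitative pattern (within ≈ 0.97, cross ≈ 0.63).

## Known limitations

* The flat-epoch rule is threshold-based (0.5 µV), not bit-exact; signals
  engineered between 0 and 0.5 µV would be called flat.
* State entropy is a band-restricted spectral entropy, not the
  time–frequency balanced monitor construction.
* The EDF writer is minimal (plain EDF, int16, 1-s records, no embedded
  annotations) — intended for round-trip testing and export, not as a
  general-purpose EDF library.
* The exhaustive SVM grid is supported but impractical; results quoted
  with the default ladder.
* Per-fold AUC variance is high at desk-scale cohort sizes; conclusions
  from the recovery experiments are directional, not quantitative.
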