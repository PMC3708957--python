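# Methods

`erpdecode` implements a complete single-trial decoding pipeline for
passive-oddball EEG: a synthetic cohort generator with known ground
truth, a rule-based preprocessing chain, spatio-temporal discriminability
mapping, regularized linear decoding within and across participants,
naive-Bayes fusion of consecutive decisions, classifier-weight
decomposition, and group-membership decoding. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic data can and cannot establish.

## Signal model of the generator

Each trial is an epoch on a fixed −200…1000 ms grid (trials abut exactly
at the 1200 ms stimulus-onset asynchrony, so epochs are rendered
directly rather than cut from a continuous record; `to_recording`
concatenates them back into a continuous file with onset events when a
continuous EDF is wanted).

Deviant epochs receive three deviance-related negativities, each a fixed
scalp topography times a Gaussian time course:

| component | latency (ms) | width (ms, SD) | amplitude (µV) |
|---|---|---|---|
| N1-interval effect | 100 | 30 | −2.0 |
| MMN-like N2 effect | 250 | 50 | −4.0 |
| late RON-like effect | 550 | 70 | −2.5 |

All three share a fronto-central topography (Gaussian fall-off in chord
distance from a point just anterior of the vertex, zero on the mastoid
leads, peak weight 1). Standard epochs carry noise only: the components
are modelled as pure deviance-related *enhancements*, which is the
quantity every downstream contrast (difference wave, AUC map, decoder)
measures. A component's rendered amplitude is

    amplitude × condition_gain × group_gain,

with default condition gains 0.5 / 1.0 / 1.5 over the three deviance
conditions (named `63ms`, `41ms`, `19ms` after the voice-onset-time
continuum they emulate) and group gains 1.0 (native-analogue) / 0.7
(non-native-analogue). Those two factors are the generator's entire
ground-truth effect structure; recovery of their ordering is what the
cohort-level tests check.

Background noise is Gaussian with a 1/f amplitude-shaped spectrum
(flat below 1 Hz) and spatial correlation imposed by a Gaussian kernel
in inter-electrode chord distance (scale 0.6). The default noise SD is
2.5 µV. That value was set, once, so that default cohorts decode at
roughly 0.50 / 0.60 / 0.73 across the three gain conditions with ~40-60
paired epochs per participant — the regime reported for real
single-trial passive-oddball decoding — while keeping the graded
condition effect resolvable at desk-scale cohort sizes. Amplitudes sit
in the 0.5–6 µV range typical of passive-oddball negativities.

Artifacts: blink-like transients (120 µV frontal Gaussian pulse, 75 ms
SD) injected per trial at rate 0.05, and transiently bad channels
(200 µV mains-band sinusoid or a +30 mV offset) at rate 0.02.

Behavioral identification is a logistic curve over a 7-step continuum
with a group-dependent boundary (3.6 native / 4.6 non-native, slope
0.7) plus clipped Gaussian response noise (SD 0.05).

The oddball sequence starts with a standard and never presents two
deviants in a row; conditional on a preceding standard, a deviant
follows with probability p/(1−p), which makes the long-run deviant
fraction exactly the nominal p (15% by default). Rates ≥ 0.5 are
rejected as unsatisfiable under the no-repeat constraint.

**What the generator does not emulate:** realistic lead fields or
volume conduction (topographies are smooth kernels, not dipole
projections), latency jitter or amplitude variability across trials,
non-stationary noise, muscle/line artifacts beyond the two injected
kinds, and between-participant topography variability (participants
differ only by noise realization and group gain). Passing tests
therefore demonstrate that the *pipeline* recovers known structure
under realistic SNR; they do not certify performance on real
recordings.

## Preprocessing chain

Stage order: per-epoch bad-channel repair → resample to 128 Hz →
infomax-ICA artifact removal and reprojection → baseline-relative
±75 µV epoch rejection → zero-phase 1–25 Hz band-pass → re-reference to
the mastoid average → baseline correction (−100…0 ms) → deviant/standard
pairing and 0–700 ms crop.

- **Bad channels** (per epoch): integrated 48–52 Hz periodogram power
  above `line_power_limit` (default 5000 µV², calibrated so clean
  simulated epochs flag <1% of channels; an injected 200 µV mains
  sinusoid carries ~20 000 µV²) or |mean amplitude| above ±25 mV.
  Sampling rates below 104 Hz make the mains band unobservable and are
  rejected.
- **Spherical-spline repair**: Perrin interpolation with order m = 4,
  Legendre series truncated at 50 terms, stiffness 1e−5 on the kernel
  diagonal, weights constrained to sum to zero. The interpolation
  matrix is solved once per bad-channel set and applied to all samples.
  Constants are reproduced exactly; agreement with a directly solved
  linear system is at the 1e-13 level.
- **Resampling**: polyphase (`resample_poly`) with the rational
  up/down factors; output length follows ceil(n·up/down), so a 1200 ms
  epoch at 128 Hz has 154 samples.
- **ICA**: infomax run once per participant on mean-centred,
  ZCA-whitened concatenated epochs, estimated on an evenly subsampled
  segment (default cap 4000 samples — estimation does not need every
  sample) and composed with the whitener. Activations are rescaled to
  unit-norm mixing columns so that activation variance equals variance
  accounted for in channel space. Candidates are components with more
  than 1% of overall variance; those whose mean per-epoch variance
  strictly exceeds `threshold_scale` (default 1.0) times the candidate
  average are removed and the data reprojected. The strict inequality
  makes the all-equal case a no-op, and with a single candidate the
  rule can never select at scale ≥ 1 — by design the rule is
  conservative; the per-participant `threshold_scale` is the adjustable
  guard against removing brain components, replacing visual inspection
  with a deterministic, reportable setting.
- **Rejection**: an epoch is dropped iff any channel deviates from its
  own baseline-window mean by more than 75 µV — a pure DC offset
  present in baseline and data alike does not reject.
- **Filtering**: 4th-order Butterworth applied forward-backward
  (zero-phase, ~48 dB at 50 Hz). Filter family/order are our choice;
  only the 1–25 Hz band is given.
- **Pairing**: each deviant is kept only with the standard acquired
  immediately before it (and vice versa), giving exact class balance;
  the decode window is half-open, round(Δt·fs/1000) samples, i.e.
  exactly 90 samples for 0–700 ms at 128 Hz and a 64×90 feature grid at
  the standard montage.

## Decoding

The classifier is quadratically regularized linear logistic regression
on the channel-major flattening of the decode window (reference leads
excluded):

    min_{W,b}  Σ_i log(1 + exp(−y_i(⟨W, X_i⟩ + b))) + λ‖W‖²_F

with the bias unpenalized and labels +1 = deviant (ties at f = 0
resolve to standard). Because trials ≪ features, the minimizer lies in
the span of the training trials; the solver works on the dual
coefficients with a precomputed Gram matrix (damped Newton with
backtracking from zero; the stopping rule evaluates the *primal*
penalized-loss gradient norm √(vᵀKv), v = r + 2λα, driven below 1e−8).
For more than ~1200 trials it falls back to L-BFGS, and a primal
L-BFGS path handles the trials ≥ features case. All paths are
deterministic (no random initialization).

λ is searched over {0.001, 0.01, 0.1, 1, 10, 100} × the total data
variance of the training set (sum of per-feature variances), which
makes the grid scale-invariant; ties resolve to the larger λ.
Within-participant evaluation is stratified 10-fold cross-validation
with the grid search nested inside each training fold (stratified
5-fold by default; the outer test fold never influences λ).
Cross-participant evaluation is leave-one-participant-out with λ chosen
by grouped cross-validation over the training participants only —
the held-out participant is excluded from the nested analysis entirely,
and tests audit that no test-participant row reaches any nested fold.
Significance thresholds come from the exact binomial tail at chance
0.5.

## Evidence fusion

For logistic decisions the naive-Bayes combination of N independent
trials reduces to the logistic of the summed decision values, which is
the numerically stable path (the probability-product form underflows
where p is within rounding of 0 or 1; the package evaluates the product
form with the non-target probability passed explicitly when it is used
as a cross-check). Decisions are grouped per true class in
non-overlapping runs of N consecutive trials; remainders shorter than N
are dropped rather than padded, preserving the consecutive-group
contract. Under the Gaussian decision-value model f ~ N(±d/2, 1) the
fused accuracy has the closed form Φ(√N·d/2), which the tests compare
against Monte-Carlo.

## Interpretation

SVD of the weight matrix gives ranked (topography, time course) pairs
with variance fractions σ²_k/Σσ²; the sign ambiguity is resolved so
each time course's extreme value is negative, matching the negativities
being decoded. The MMN amplitude of a difference wave is the mean over
a 50 ms window centred on the minimum between 200–400 ms, averaged over
the nine fronto-central electrodes (F1, Fz, F2, FC1, FCz, FC2, C1, Cz,
C2) when the montage has them, otherwise over all scalp channels.
Couplings between decoding rates and scalars (MMN amplitude, behavioral
scores) are plain Pearson correlations over participant-condition
pairs.

## Group decoding

Five feature constructions: per-trial standard/deviant segments
concatenated across conditions (70 segments per participant at full
scale); the same segments with each participant's held-out decisions
fused by the sum rule into one decision per participant; per-participant
grand averages over all conditions (standards and deviants); grand
averages of the deviants in the two smaller-deviance conditions only;
and the 7-element behavioral vector. Evaluation is leave-one-pair-out
(one participant per group per fold, paired by sorted id — the pairing
rule is ours), with the same classifier and nested λ selection over
training pairs. Equal group sizes are required; fold count equals group
size.

## Problem sizes

Desk-scale defaults keep every study minutes-long on one CPU: cohort
studies use 8–16 scalp channels, 100–300 trials per condition and 6–22
participants; the demo experiment runs 6+6 participants, 32 channels,
160 trials per condition through all stages including ICA. The
structural 64×90 feature geometry is exercised at the full 64-channel
montage where it matters (window dimensionality, montage handling);
rate-level studies use the smaller layouts since the effect structure,
not the channel count, is under test.

## Known limitations

- Topographies are identical across participants; cross-participant
  transfer is therefore easier than in real cohorts, and the
  native-trained-versus-all-trained asymmetry appears only through the
  group gain, not through genuinely different spatial patterns.
- The ICA variance rule identifies high-variance artifact components
  (blinks) reliably but is conservative when a single component
  dominates; residual blink epochs are caught by the ±75 µV rule.
- The EDF writer emits plain 16-bit EDF (one-second records, events in
  a stimulus channel); quantization error is bounded by the physical
  range over 2^16.
- `binomial_threshold` returns NaN when no accuracy is significant at
  the requested level (tiny n and strict α) rather than raising.
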