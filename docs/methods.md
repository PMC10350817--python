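# Methods

This package implements, end to end, an intracranial (ECoG) analysis of
high-frequency activity (HFA) evoked by omissions of expected speech
sounds in the superior temporal gyrus (STG), together with a synthetic
recording generator that stands in for patient data.  This note documents
the model and procedure, the generator's assumptions, the numerical
choices, and what the tests do and do not establish.

## The paradigm

Subjects listen to a predictable stream of syllable triplets,
"La-La-Ba" alternating with "La-La-Ga".  Syllables last 400 ms with
200 ms gaps within and between triplets.  Which third syllable is
*expected* at a given triplet is fully determined by alternation; on a
subset of triplets the expected syllable is omitted (silent gap) or
replaced by a target "Ta" that must be answered with a button press.
One block realizes exactly 19 omissions, 8 targets, and 68 "Ba" and 68
"Ga" presentations (163 slot-2 trials).  The generator treats these
counts as exact: slot-2 conditions are a seeded uniform arrangement of
the requested multiset subject to the alternation constraint, so an
omission at a Ba-expected position is an "omitted Ba" by construction.
A control task replaces *every* third syllable with an omission; because
those omissions are fully expected, any response to them would indicate
rhythm-driven rather than prediction-violation activity.

Behavioral scoring attributes the first unclaimed press within a 1.5 s
window after a target onset as a hit, and presses attributed to Ba/Ga
onsets by the same rule as false alarms.  The window default exceeds the
slowest plausible median reaction time by a wide margin and is
configurable.

## The synthetic recordings

`simulate` renders channels x samples at 1200 Hz:

- **Background**: per-channel Gaussian noise with power spectral density
  proportional to f^-2 (configurable exponent; flattened below 0.5 Hz),
  scaled to 8 uV RMS with ~10% log-normal channel heterogeneity.
- **Line noise**: shared-phase sinusoids at 60/120/180 Hz (5/2/1 uV) with
  log-normal per-channel amplitude spread; a small fraction of channels
  (5%) carry ~25x amplitudes so the robust channel-exclusion rule has
  realistic outliers to catch.
- **Evoked bursts**: each slot-2 event adds, on responsive channels, a
  band-limited (70-170 Hz) burst whose envelope is a Gaussian bump.  The
  carrier is a constant-modulus band-limited signal (band-passed noise
  divided by its own analytic envelope), so the injected envelope equals
  the bump exactly — ground-truth amplitudes and latencies are exact —
  while the extraction path (filtering + Hilbert transform) is genuinely
  exercised.  A pure-tone carrier is available for closed-form checks.
- **Electrode classes**: `syllable_only` channels respond to heard
  syllables (Ba/Ga/Ta); `omission_and_syllable` channels additionally
  respond to omissions, with the omission burst peaking
  `latency_shift_omission_ms` later; `silent` channels carry only noise;
  `grid` channels model the rest of the clinical implant — they carry
  noise, enter preprocessing (most importantly the common average
  reference, which in real recordings is computed over the whole implant,
  not just the STG subset), and are dropped before envelope analysis.
  Without them, evoked activity leaks through the reference into silent
  channels at levels never seen with realistically sized reference pools.
- **Spatial structure**: electrode Talairach y-coordinates (anterior-
  posterior axis; more negative = more posterior) are Gaussian around
  class means, with the omission class shifted `posterior_shift_mm`
  (default 6.7 mm) posterior, a per-subject implant offset (3 mm SD)
  that the mixed models' random intercepts absorb, and an omission-
  amplitude gradient toward posterior sites (2%/mm).

Default effect parameters: syllable bursts 2.0 uV peak envelope at
160 ms (45 ms SD width, 8 ms trial jitter), omission bursts 1.0 uV at
281 ms (60 ms width, 20 ms jitter — the omission response is endogenous
and less precisely time-locked), ~20% log-normal trial gain spread.
Against the generator's ~0.45 uV envelope noise floor these are ~4x and
~2x baseline, typical of STG HFA responses.  Responses are injected only
at third-syllable positions; "La" responses are omitted so that the
pre-stimulus baselines are response-free.  This is a deliberate departure
from real data, where the preceding syllables evoke activity that decays
into the baseline window — passing tests therefore do not establish
robustness to baseline contamination.

What the generator does **not** emulate: epileptiform artifacts,
non-stationary noise, movement/electrode artifacts, biophysical forward
modeling, refractoriness or adaptation across repeated stimuli, and
correlated (shared) trial-to-trial latency jitter across electrodes.

## Preprocessing

DC removal; zero-phase second-order Butterworth high-pass at 0.05 Hz;
zero-phase IIR notches at 60/120/180 Hz (1 Hz bandwidth, chosen to give
>=30 dB suppression without touching the 70-170 Hz band); common average
reference.  For the reference, each channel's 60 Hz amplitude is
estimated from the raw signal by Welch's method (2 s segments, 50%
overlap, amplitude integrated over a 2 Hz band); channels exceeding
median + 10 x MAD (plain median absolute deviation) across channels are
excluded from the reference but retained — re-referenced and flagged —
in the output.  The threshold statistic is linear in signal scale, so
exclusion is scale-invariant.

All filtering is zero-phase.  The fused pipeline applies the squared
magnitude response of the high-pass + notch cascade in the frequency
domain with 10 s reflection padding; this is mathematically the
forward-backward application of the cascade and is used for speed on
long multichannel records.  The standalone `dc_highpass`/`notch`
operations use forward-backward `sosfiltfilt` directly.  Because the
0.05 Hz high-pass has a settling time of ~20 s, finite records retain a
small residual mean after filtering; the DC-correction contract is
enforced by re-subtracting the channel mean.

## HFA extraction and epoching

Fourth-order Butterworth band-pass 70-170 Hz (zero phase) on the
continuous cleaned signal, analytic-signal magnitude (Hilbert), then
polyphase antialiasing resampling from 1200 to 400 Hz.  Tiny negative
ringing from the resampler is clipped at zero and asserted to be below
10^-3 of the total envelope mass.  Epochs span -200..+500 ms around
slot-2 onsets — for omissions, the *expected* onset of the missing
syllable — in half-open 2.5 ms bins (280 samples).  Two baselines are
used deliberately: -20..0 ms for the t-test screening and -200..0 ms for
per-trial division when relative power change is wanted; both are
configured in one place (`RunConfig`) so they cannot diverge silently.

## Electrode statistics

For each electrode and response timepoint (0..500 ms), a paired t-test
compares across-trial envelope values against each trial's own baseline
mean.  P-values are pooled over the full electrodes x timepoints family
and corrected with Benjamini-Hochberg at alpha = 0.05 (Benjamini-
Yekutieli selectable).  An electrode counts as responsive when it shows a
run of at least `min_run` consecutive significant positive-t bins;
the default is 4 bins (10 ms).  Rationale: the envelope of a 100 Hz-wide
band decorrelates in ~10 ms, so single-bin exceedances are noise-scale
events — and with strong true responses in the family, the BH cutoff
approaches alpha per bin, making isolated false bins common — whereas
real responses last >100 ms (40 bins).  `min_run=1` restores the purely
pointwise reading.  Categories: omission-active, syllable-active, both,
none (mutually exclusive labels).

Peak latency and amplitude are the argmax/max of the trial-averaged raw
envelope over 0..500 ms (ties to the earliest bin), computed per
electrode for pooled Ba/Ga trials and pooled omission trials.

Three linear mixed-effects models (statsmodels MixedLM, REML, Wald
p-values, subject random intercepts):

1. **Position**: Talairach y ~ category, where category contrasts
   omission-responsive electrodes (including those also syllable-active)
   against syllable-only electrodes; silent electrodes are excluded.
   A negative coefficient = omission sites more posterior.
2. **Latency**: peak latency ~ category, with each electrode
   contributing the latency of its own response type (omission-group
   latency for omission electrodes, Ba/Ga latency for syllable-only
   electrodes).  A positive coefficient = omission responses later.
3. **Amplitude-position**: Talairach y ~ omission peak amplitude over
   omission-responsive electrodes.

Group summaries use two-stage aggregation — within-subject mean, then
across-subject median (MAD for spread) — so subjects with many
electrodes do not dominate.

## Condition GLM and differential score

At every electrode x timepoint, trial envelopes are regressed on five
mutually exclusive condition indicators (Ba, Ga, OmittedBa, OmittedGa,
Ta) with no intercept.  With disjoint indicators the OLS solution is
closed-form: each coefficient is the condition mean, with standard error
s/sqrt(n_c) from the residual variance pooled across conditions
(dof = N - k); the implementation vectorizes this over all electrodes
and timepoints, and tests cross-check it cell-by-cell against a general
OLS solver.  A coefficient is significant when its 95% confidence
interval excludes zero; an FDR variant over the pooled coefficient
family is provided.  Conditions with fewer than two trials are excluded
and flagged.

The differential score for conditions i, j is
(beta_i - beta_j) / (CI_i + CI_j) with CI the *half*-width of the 95%
interval (full-width selectable; the half-width reading makes |score| = 1
exactly the point where the coefficient difference equals the summed
interval half-widths, and since CI_i + CI_j >= the CI of the difference,
|score| >= 1 is a conservative significance criterion).  Scores are
antisymmetric in (i, j), invariant to rescaling the data, and undefined
cells (zero denominator) are returned as NaN, not infinity.  The four
standard contrasts are Ba-vs-Ga, Ba-vs-OmittedBa, Ga-vs-OmittedGa and
OmittedBa-vs-OmittedGa, each with a time-averaged variant over the
response window for electrodes with temporally diffuse responses.

## Problem sizes used by the test suite and acceptance script

All sizes below are the package's own choices for routine validation;
every stage accepts arbitrary sizes.

- *Tiny fixture*: 1 subject, 8 STG electrodes + 16 grid channels, one
  reduced block (6 omissions / 2 targets / 12+12 syllables).
- *Null calibration*: 200 replicates of a zero-amplitude (noise-only)
  single-subject dataset with a full session's 57 omission trials
  (3 blocks x 19); at this n the paired t is well calibrated on the
  skewed envelope distribution, so the measured false-discovery
  proportion reflects the BH procedure itself.
- *Parameter recovery*: 100 datasets of 5 subjects x 10 STG electrodes
  (+16 grid), one block with 19 omissions / 30+30 syllables, with
  balanced responsive classes (4 omission-class, 4 syllable-only per
  subject) so the pooled-variance SE of the category coefficient is
  calibrated despite the omission group's larger latency scatter.
- *Contrast structure*: 2 subjects x 12 electrodes (+24 grid), one full
  block.
- *Acceptance script*: the full default design — 6 subjects, 3 blocks
  each, 16 STG electrodes + 32 grid channels per subject.

## Known limitations

- The Wald SEs of the mixed models are anticonservative for very few
  subjects (random-intercept variance poorly estimated below ~4 groups);
  the default design uses 6 subjects.
- The pooled-family BH correction makes electrode-level inference
  sensitive to the amount of true signal elsewhere in the family (the
  adaptive cutoff); the min-run rule mitigates but does not remove this.
- Envelope-based peak latencies are biased estimators under very low SNR
  (argmax can jump to noise peaks); recovery tests operate at SNRs where
  this is negligible.
- The differential score's |score| >= 1 criterion is conservative
  (summed half-widths exceed the half-width of the difference CI), so
  its null exceedance rate sits well below alpha.
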