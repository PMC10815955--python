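# Methods

`gammassr` implements the analysis chain of a rodent pharmaco-EEG study of
NMDAr-antagonist models of schizophrenia: gamma-band auditory steady-state
response (ASSR) phase locking, spontaneous-EEG gamma band power, behavioral
endpoints, and the group-statistics layer, together with a synthetic-data
generator that reproduces the statistical structure the analysis assumes so
every stage can be validated against closed forms.

## ASSR phase-locking factor

The continuous EEG is cut into 1.5-s epochs on [−500, +1000] ms around each
stimulus trigger. Each epoch is offset-corrected by subtracting its own
median, and an epoch is rejected when any sample on any channel strictly
exceeds ±300 µV ("exceeds" is read strictly: samples at exactly ±300 µV are
retained; configurable). The processing order is fixed as extract →
offset-correct → reject, following the order in which the steps are defined.

Time–frequency decomposition uses 9-cycle complex Morlet wavelets on a
0.5-Hz grid over [48, 52] Hz (9 frequencies) at every time sample. The
kernel at frequency *f* is a complex exponential under a Gaussian envelope
with total support *n*<sub>cycles</sub>/*f* seconds — half-length
*n*<sub>cycles</sub>/(2*f*), i.e. 93.75 ms at 48 Hz — Gaussian σ set to
support/7 so the envelope is essentially zero at the kernel ends, truncated
to an odd number of samples and normalized to unit energy. Samples where the
kernel overhangs the epoch edge are flagged invalid and excluded from all
region averages.

The phase-locking factor (PLF, equivalently inter-trial coherence) at a
(time, frequency) cell is

  PLF = | (1/N) Σₙ zₙ / |zₙ| |

over the N retained epochs' complex coefficients zₙ. Cells whose magnitude
is numerically negligible (≤ 10⁻⁹ of the epoch's maximum coefficient
magnitude) are excluded from the average: convolution roundoff in truly
silent stretches would otherwise contribute meaningless phases. Magnitude is
taken after averaging (the ITC reading of "normalized amplitudes averaged");
the alternative — averaging normalized amplitudes and reporting them per
cell — would always equal 1 and carries no phase information, so the ITC
reading is the only self-consistent one.

The scalar endpoint is the mean PLF over the post-stimulus region of
interest [0, 500] ms × [48, 52] Hz minus the mean over the baseline
[−500, 0] ms × [48, 52] Hz, with both windows trimmed by 100 ms (the 48-Hz
half-length rounded up) at *both* ends — effective windows [100, 400] and
[−400, −100] ms. Trimming both ends protects the baseline symmetrically from
epoch-edge invalidity and from smearing across the stimulus transition; the
end-trimming convention is configurable.

For N epochs with uniform phases, E[PLF] = √π/(2√N) (the Rayleigh resultant
expectation) — 0.023 at N = 1500. The ROI−baseline subtraction therefore
removes most of this small-sample bias from the endpoint when the baseline
is phase-random; the residual effect on percent-of-reference ratios is a
downward bias of order (1 − r)·floor/PLF_ref, about 1–2 percentage points at
1500 trials for an attenuation ratio r = 0.4, and proportionally larger in
scaled-down simulations with fewer trials (the acceptance checks account for
this analytically rather than widening tolerances).

## Spontaneous-EEG gamma power (qEEG)

Spontaneous recordings are segmented into contiguous non-overlapping 4-s
epochs (remainder discarded); epochs whose peak-to-peak amplitude strictly
exceeds 400 µV on any channel are excluded. Each retained epoch is
Hanning-windowed and Fourier-transformed; power is the complex spectrum
times its conjugate, one-sided, on a 0.25-Hz grid from 0 to fs/2. The scale
factor 1/(N·Σw²) (doubled for interior bins) makes the bin sum equal the
window-weighted mean-square amplitude exactly (Parseval) and gives a
bin-centered sinusoid of amplitude A a total of A²/2 µV² over its leakage
bins, so amplitudes are comparable across window choices. No detrending or
mean subtraction is applied beyond the windowing, and no 50-Hz mains notch —
note the gamma band includes 50 Hz, so mains interference in real data would
inflate this endpoint. Gamma band power is the sum of bins with
32 ≤ f ≤ 80 Hz (both endpoints inclusive; configurable), and the session
value is the mean over retained epochs (mean, not median, was chosen for
additivity with the per-epoch Parseval identity).

## Behavior

Activity tables hold beam-break counts per 10-min bin from dosing time.
Endpoints are sums over bin-aligned windows — misaligned windows raise an
error rather than pro-rating, keeping endpoints exact integer sums. The
social-interaction endpoint is the time a *pair* of rats spends in active
non-aggressive social behavior during a 600-s test; the pair is the
statistical unit (a single score per couple), so arm n counts pairs.

## Group statistics

Each endpoint is cleared of outliers in a single pass per arm: values more
than 2 sample standard deviations (n−1 denominator) from their arm mean —
both computed including the candidate — are removed. The rule is
deliberately not iterated and uses group-wise (not study-wise) dispersion.
Arms with fewer than 3 values are left untouched, and an all-equal arm
(SD = 0) removes nothing. A one-way fixed-effects ANOVA is followed by
Dunnett's two-sided many-to-one comparisons against the designated reference
arm (vehicle, or the disease-model arm in reversal designs), computed with
scipy's multivariate-t implementation with a fixed internal QMC seed so
reports are reproducible byte-for-byte. Tests run on raw endpoint values;
percent-of-reference (subject value / reference-arm mean × 100) is a
reporting convention only. Significance tiers are 0.05/0.01/0.001/0.0001
(star convention `*` to `****`).

## Synthetic-data generator

The generator emulates a telemetry session rather than a biophysical
circuit. Per channel (default two: global and auditory cortex, independent
noise, no volume-conduction model):

- **Evoked component** — a sinusoid at the click-train rate (50 Hz), active
  on [onset + latency, onset + latency + 500 ms] of each 1.2-s stimulus
  cycle (500-ms train + 700-ms silence; 1500 stimuli ≙ 30-min session),
  amplitude 25 µV, whose phase is drawn per trial from von Mises(0, κ). The
  population PLF of the noise-free component is the Bessel ratio
  A(κ) = I₁(κ)/I₀(κ); κ is the sole phase-synchrony knob, and
  `calibrate.kappa_for_plf` inverts A so designs are specified directly in
  PLF terms. A click-evoked-transient superposition was deliberately not
  used: the jittered sinusoid is the simplest generative model with an
  analytic PLF target.
- **Background** — 1/f^α noise (α = 1, RMS 20 µV) via spectral shaping,
  plus band-limited flat noise on 32–80 Hz whose RMS (default 5 µV) is the
  spontaneous-gamma knob; doubling it quadruples band power exactly (the
  same white-noise draw is scaled, thanks to per-component seed streams).
  `calibrate.gamma_scale_for_band_power_ratio` solves for the amplitude that
  makes the *measured* band-power ratio between arms hit a target, since the
  1/f floor contributes identically to both arms' 32–80 Hz sums.
- **Artifacts** — 200-ms biphasic transients (±amplitude peaks, so
  peak-to-peak 2×amplitude) with Poisson timing; defaults exercise both the
  ±300 µV sample rule and the 400 µV peak-to-peak rule when enabled.
- **Behavior** — activity counts negative-binomial around a per-bin mean
  profile (variance m + m²/θ, θ = 8 by default: Poisson counts would be
  unrealistically tight for beam-break data); social time truncated-normal
  on [0, 600] s. Vehicle arms default to a ~57 s social mean and low
  activity; drug-like arms to a ~14 s social mean and sustained
  hyperlocomotion.

Sampling-rate default is 1000 Hz: 4-s epochs with 0.25-Hz resolution and a
0–500 Hz range jointly imply it, and it satisfies Nyquist for every
synthesized component. All randomness derives from one integer seed through
`numpy.random.SeedSequence` spawning, one stream per (channel × component),
so outputs are bit-reproducible and parameter changes in one component never
perturb another's draws.

Between-subject variability (`StudyDesign.subject_cv`, default 0.15) applies
mean-one lognormal factors per subject to κ, the gamma amplitude and the
behavioral means. Without it, per-subject endpoints at 1500 trials would be
nearly deterministic and percent-of-reference SEMs unrealistically small;
0.15 gives arm-level scatter comparable to the individual-value spread seen
in small-cohort telemetry studies.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: non-stationary background (vigilance states,
movement), harmonic/broadband evoked structure, channel covariance, mains
interference, electrode drift, and any pharmacokinetic time course within a
session.

## Problem sizes

Defaults are the full study conditions (1500 stimuli, 1-h spontaneous EEG,
n = 8/arm). The test and acceptance suites run the package's own scaled
conditions, chosen so closed-form targets remain resolvable: PLF calibration
and the Rayleigh floor at the full 1500 trials; κ-recovery over
{0.5, 1, 2, 4, 8} at 1500 trials × 20 replicates; the Dunnett null
calibration at 2000 replicate studies; end-to-end attenuation recovery at
600 stimuli/subject, one channel, n = 8/arm, 5 replicate studies; the
spontaneous-gamma ratio study at 300-s recordings, n = 6/arm. The demo
drivers under `analysis/` use 200–300 stimuli so they run in seconds.

## Known limitations

- EDF output uses a hand-written minimal 16-bit encoder (whole 1-s records,
  zero-padded tail); reading goes through mne, which also serves as an
  independent check of the writer in the round-trip tests.
- The PLF's small-sample floor is not bias-corrected (no Rayleigh-corrected
  ITC); the baseline subtraction removes most of it, matching the endpoint
  definition.
- With only ~8 subjects per arm, the 2-SD rule rarely removes anything
  (small-n masking: with n = 5 no point can exceed 1.79 SD); this mirrors
  the rule as specified rather than a robust-statistics recommendation.
- One EEG channel per simulated cortex; no spatial leakage, so
  channel-level conclusions about regional specificity cannot be tested on
  synthetic data.
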