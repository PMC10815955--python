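# gammassr

Analysis pipeline for gamma-band EEG biomarkers in rodent NMDAr-antagonist
models of schizophrenia-like physiology, plus a calibrated synthetic-data
generator so the whole chain is testable without animal recordings.

Acute NMDAr blockade (PCP, MK-801, ketamine) reproduces two hallmark EEG
abnormalities of schizophrenia in rats: a collapse of phase synchrony of the
auditory steady-state response (ASSR) evoked by gamma-frequency click
trains, and an increase in spontaneous gamma-band (32–80 Hz) power — along
with hyperlocomotion and reduced social interaction. `gammassr` implements
the full measurement chain for these endpoints:

- **ASSR phase-locking factor (PLF / inter-trial coherence).** Stimulus-locked
  1.5-s epochs ([−500, +1000] ms), median offset correction, ±300 µV sample
  rejection, 9-cycle Morlet wavelets on [48, 52] Hz, then
  PLF(t, f) = |N⁻¹ Σₙ zₙ/|zₙ|| across epochs and the endpoint
  PLF(ROI) − PLF(baseline) with both windows trimmed by 100 ms.
- **qEEG gamma power.** Non-overlapping 4-s epochs, 400 µV peak-to-peak
  rejection, Hanning periodogram (0.25-Hz resolution, 0–500 Hz), band power
  = Σ of bins with 32 ≤ f ≤ 80 Hz.
- **Behavior.** Beam-break activity sums over bin-aligned windows
  (0–90 min, 80–150 min, ...) and paired social-interaction time.
- **Group statistics.** Single-pass 2-SD outlier removal per arm, one-way
  ANOVA, Dunnett many-to-one comparisons against a reference arm, and
  percent-of-reference reporting (subject / reference-arm mean × 100).

The generator plants a 50-Hz evoked sinusoid whose trial phases are
von Mises(0, κ), so the population PLF is the Bessel ratio I₁(κ)/I₀(κ) and
every estimator can be validated against closed forms (including the
Rayleigh floor √π/(2√N) for N uniform-phase trials). See
[docs/methods.md](docs/methods.md) for the model, conventions and
limitations.

## Worked example

Run the numbered drivers (each writes CSV/EDF under `results/`):

```bash
python analysis/01_simulate_session.py   # demo subject: EDF session + events + behavior
python analysis/02_assr_plf.py           # epoching, rejection, PLF map, ROI−BL contrast
python analysis/03_qeeg_gamma.py         # 4-s epochs, spectra, gamma band power
python analysis/04_behavior_endpoints.py # activity window sums, social endpoint
python analysis/05_group_study.py        # full two-arm synthetic study + statistics
```

The demo session (200 stimuli, κ = 4, realistic background) prints:

```
epochs: 200 extracted, 6 rejected, 194 analyzed
PLF contrast (ROI−BL) global_cortex: 0.826
PLF contrast (ROI−BL) auditory_cortex: 0.818
```

— close to the analytic ceiling I₁(4)/I₀(4) ≈ 0.863 minus the baseline
floor, as expected for a strongly entrained response. The two-arm study
(vehicle vs an MK-801-like arm with an injected population-PLF ratio of 0.4
and a 4.06× spontaneous-gamma band-power ratio, n = 6/arm at demo scale)
prints:

```
drug arm, percent of vehicle (mean ± SEM, Dunnett p):
  assr_plf_global_cortex              33.3 ±   2.6 %   p=0.0000 ****
  gamma_power_global_cortex          380.7 ±  47.1 %   p=0.0002 ***
  activity_0_90min                  1100.0 ±  93.3 %   p=0.0000 ****
  social_time_s                       24.9 ±   3.3 %   p=0.0001 ***
```

i.e. the qualitative disease-model signature — collapsed evoked phase
locking, elevated spontaneous gamma, hyperlocomotion, reduced social time —
with the injected effect sizes recovered within simulation error (the PLF
percentage sits slightly below 40% at demo scale because the baseline floor
shrinks both arms' contrasts by the same additive amount; see the methods
note).

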