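# Methods

## Optical model

The forward model is classical Beer–Lambert transmission oximetry.  A single
absorber attenuates light as `A = ln(Ii/It) = a·C·L`; absorbances of mixed
species superpose.  Blood at saturation `S` has effective extinction
`μ_λ(S) = S·ε_HbO2(λ) + (1−S)·ε_Hb(λ)`, and a compartment whose optical path
`l(t)` varies in time transmits

```
I(λ,t) = I0(λ) · exp(−μ_λ(S) · l(t)).
```

Evaluating the log-intensity change between two instants at 660 and 940 nm
cancels the unknown path excursion and leaves the ratio of ratios
`R = μ_660(S)/μ_940(S)`, inverted algebraically as

```
S = (R·ε_Hb(940) − ε_Hb(660)) / [(ε_HbO2(660) − ε_Hb(660)) − R·(ε_HbO2(940) − ε_Hb(940))].
```

`S` multiplies the HbO2 coefficient, so `S = 1` is the fully oxygenated
limit, the standard oximetry convention.  Two coefficient orderings —
`ε_Hb(660) > ε_HbO2(660)` and `ε_HbO2(940) > ε_Hb(940)` — are enforced as
type invariants; they make `R(S)` strictly decreasing and the inversion well
posed.  The inversion denominator vanishes at exactly one (nonphysical) R,
which raises a dedicated error.  Raw inversions outside [0, 1] beyond a
configurable slack (default 0.05) are flagged, and the returned value is
clipped only in the explicitly clipped field, never silently.

Default coefficients are the commonly tabulated Hb/HbO2 molar extinctions at
660/940 nm in mM⁻¹·cm⁻¹ (3.2266/0.3196 red, 0.6934/1.2140 infrared).  Only
products of coefficient, concentration and path enter any result, so any
consistent unit system is accepted; coefficient sets are overridable from
YAML/JSON config blocks.

The AC/DC small-signal form `R ≈ (AC/DC)_red / (AC/DC)_ir` agrees with the
log form to second order in modulation depth (relative error ≈ (m_red² −
m_ir²)/24 for log-swings m, i.e. ~10⁻⁵ at the few-percent modulations used
here).  The pipeline reconstructs per-cycle peak/trough intensities as
DC ± AC/2 and applies the exact log form.

## Synthetic data generator

The generator emulates a finger in transmission with three compartments:
static tissue (fixed absorbance per wavelength), an arterial path pulsating
at the cardiac rate with saturation SaO2, and a venous path compressed by a
cuff at the stimulation rate with saturation SvO2.  Key defaults and the
reasoning behind them:

| parameter | default | why |
| --- | --- | --- |
| sampling rate | 100 Hz | typical pulse-oximeter front end; Nyquist-validated against both rates |
| duration | 60 s | one analysis-grade recording; ~72 pulse and ~240 cuff cycles |
| pulse rate | 1.2 Hz | 72 bpm resting adult |
| stimulation rate | 4.0 Hz | distinct from the pulse and its low harmonics; both orderings (above/below the pulse) are supported |
| SaO2 / SvO2 | 0.98 / 0.75 | healthy arterial value and a typical peripheral venous value (arteriovenous gap 23 points) |
| arterial path amp | 0.03 | gives ~1–5 % intensity modulation, a realistic perfusion index |
| venous stim amp | 0.02 | cuff-driven venous volume swing of the same order as the pulse |
| arterial stim coupling | 1.0 | the cuff squeezes arteries and veins alike, so the stimulation band is an equal arterial/venous mixture — the same mixture the Mixed_SpO2 = (SpO2+SvO2)/2 model assumes; fully configurable |
| noise sd | 0.002 | 0.2 % relative intensity noise, representative of a decent transmission PPG; any stochastic run requires an explicit seed |

The arterial beat is an asymmetric raised-cosine template (fast systolic
upstroke, slower decay, flat diastole); the cuff drive is a smoothed
rectangular inflation profile with 10 % rise time and 50 % duty, so it
carries odd harmonics by construction.  With coupling `c`, the
stimulation-band absorbance modulation at wavelength λ is
`(μ_λ(SvO2) + c·μ_λ(SaO2))·amp·w(t)`; because `μ` is linear in `S` this is
exactly the modulation of blood at the mixture saturation
`(SvO2 + c·SaO2)/(1+c)` — the generator's mixture and the pipeline's
inversion are two independent routes to the same quantity.

What the generator does *not* emulate: motion and respiration artifacts,
scattering and tissue heterogeneity, pulse-rate variability, cuff–tissue
biomechanics, and sensor nonlinearity.  Passing tests therefore demonstrate
correctness of the signal-processing chain under the stated optical model,
not clinical performance on real fingers.

## Decomposition

Spectra are Welch periodograms (Hann taper, 10 s segments, 50 % overlap,
mean-removed).  Peak location is an argmax per search band (defaults:
pulse 0.5–2.5 Hz, stimulation 2.6–9.4 Hz) on the summed two-channel power;
ties break to the lowest frequency.  Narrow zones (±0.25 Hz) around pulse
harmonics are masked out of the stimulation search so a pulse harmonic is
never mistaken for the cuff drive; a peak is *prominent* only if it exceeds
5× the median in-band power and 10⁻⁴× the global spectral maximum (the
absolute term keeps near-zero noiseless bands from passing the ratio test).

Extraction bands default to half-width 0.4× the fundamental, capped at
0.75× the distance to the nearest harmonic (k ≤ 4) of the other component.
At the default rates (1.2/4.0 Hz) the cap binds: pulse harmonics at 3.6 and
4.8 Hz sit 0.4 Hz from the 4 Hz drive, so the stimulation band is
3.7–4.3 Hz.  If either half-width would fall below 0.05 Hz the separation is
declared infeasible — the controller's cue to move the drive frequency.

Filters are odd-length Hamming windowed-sinc band-passes with transition
width equal to the band half-width, applied zero-lag via reflection-padded
convolution; component extrema stay within one sample of the raw signal's.
The *same* filter processes both wavelength channels, so passband ripple and
residual harmonic leakage enter both channels identically and largely cancel
in the red/infrared ratio; what remains is further suppressed by taking the
per-window *median* over cycles, since the 0.4 Hz offset between the
harmonic and the band center rotates the leakage phase cycle to cycle.
Cycles within half a filter length of the record ends are discarded
(`edge_guard`).  DC is a moving mean spanning two periods of the slower
component, which nulls that fundamental exactly.

Per-cycle extrema are detected on the infrared component (the deeper
modulation) with a 0.6-period minimum spacing, and the same indices are read
from the red component: the two channels share the modulation waveform, so
their extrema coincide, and shared indices avoid the positive bias that
independent per-channel peak-picking would take from noise.

## Pipeline

The record is decomposed once (frequencies located globally, or fixed by the
caller when the drive is known), then analysed in 10 s windows with 5 s hop.
Each window yields the median per-cycle SpO2 (pulse band) and Mixed_SpO2
(stimulation band), then `SvO2 = (Mixed − w·SpO2)/(1−w)` with the arterial
mixture weight `w = 0.5` by default; for that default the implementation
computes literally `2·Mixed − SpO2`, so the identity holds bit-exactly in
the output.  Oxygen consumption is `SpO2 − SvO2` per window.  Failures
(too few cycles, no prominent stimulation peak, infeasible separation)
flag the affected window quantities as NaN with quality flags — they never
abort the record, and SpO2 survives the loss of the stimulation channel.
An optional linear calibration map `S = a − b·R`, fitted to paired
(R, reference) points, can replace the theoretical inversion, mirroring
empirical calibration against blood-gas co-oximetry.

## Feedback controller

The physical loop is described only qualitatively, so the policy constants
are engineering choices: required harmonic separation 0.5 Hz (harmonics
k ≤ 3), SNR target 10 dB over the out-of-band median noise floor, frequency
moves upward in 0.2 Hz steps (wrapping below 8 Hz to 0.5 Hz) to the first
candidate clearing the target plus a 0.1 Hz hysteresis margin, amplitude
steps of 10 % of the pressure ceiling, and a hard cap at the ceiling (the
NIBP-derived threshold surrogate) with a saturation warning.  Cuff pressure
maps linearly to venous path amplitude (5·10⁻⁴ per surrogate unit), the
simplest plant consistent with a partially collapsing vein below the
occlusion threshold.  A satisfied state is a fixed point; from a frequency
collision the controller reaches separation in a single adjustment (the
closed loop confirms it on the next measurement).

## Evaluation

Agreement statistics are the ones a validation study reports: RMSE of
estimate − reference, the Pearson product-moment correlation between the two
series (the natural reading of a "correlation of the difference" between
paired series), a difference analysis with ±10-point band membership that
never drops a point, Bland–Altman limits of agreement (mean ± 1.96 sd), and
a per-window oxygen-consumption comparison.  Correlation on a constant
series raises a dedicated error rather than returning NaN.

## Problem sizes and determinism

Default analyses use 60 s records (6 000 samples); the hypoxia ramp uses six
30 s levels (18 000 samples); closed-loop steps simulate 12 s probes; the
simulated stepped-desaturation study runs 24 × 30 s recordings.  These sizes
give every estimator scores of cycles per window while keeping the full test
suite and the acceptance script in the low seconds.  All stochastic paths
are driven by explicit integer seeds (derived seeds stay below 2³¹);
identical seeds give bit-identical traces, results and summaries.

## Known limitations

* The equal-weight mixture inversion is exact only insofar as the cuff
  modulates arterial and venous volumes equally; the weight and the
  simulator coupling are both configurable, but no data-driven estimate of
  the true weight is attempted.
* Band separation assumes quasi-stationary pulse and drive frequencies
  within a record; chirps or large heart-rate swings would require
  re-decomposition per window.
* The AC/DC estimator assumes the band-limited component is symmetric about
  its baseline (true for a single extracted fundamental).
* Saturation steps in ramp protocols ring through the band filters for about
  half a filter length around each transition; level summaries should use
  windows away from the boundaries, as the acceptance script does.
* No motion-artifact rejection: out-of-band artifacts are ignored by design,
  in-band artifacts are not detected.
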