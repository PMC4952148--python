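# venoxim

Noninvasive venous oxygen saturation (SvO2) estimation from cuff-stimulated
dual-wavelength photoplethysmography (PPG), as a fully simulated and tested
signal-processing pipeline.

## The problem

Pulse oximetry reads arterial saturation (SpO2) from the natural cardiac
pulsation of arterial blood volume: the pulsatile (AC) to baseline (DC)
intensity ratio at two wavelengths forms the *ratio of ratios*

```
R = ln(I_red(t1)/I_red(t2)) / ln(I_ir(t1)/I_ir(t2)) = μ_660(S) / μ_940(S),
μ_λ(S) = S·ε_HbO2(λ) + (1−S)·ε_Hb(λ),
```

which Beer–Lambert optics makes invertible to the saturation `S`.  Veins,
however, carry no pulse, so venous saturation — a key marker of tissue
oxygen extraction — normally requires an invasive blood draw.

The measurement idea implemented here creates an artificial venous pulse: a
finger cuff inflates and deflates periodically at a stimulation frequency
distinct from the pulse rate, making the venous compartment optically
pulsatile.  The recorded PPG then carries two spectrally separated
components.  Band-pass filtering splits them; the pulse band yields SpO2 in
the ordinary way, and the stimulation band — whose volume oscillation
samples both the compressed veins and the co-compressed arteries — yields a
mixed saturation.  Under the equal-mixture model

```
Mixed_SpO2 = (SpO2 + SvO2) / 2    ⟹    SvO2 = 2·Mixed_SpO2 − SpO2,
```

and tissue oxygen extraction is proxied by the arteriovenous difference
`SaO2 − SvO2`.

## What the package provides

| module | role |
| --- | --- |
| `venoxim.optics` | Beer–Lambert forward model, ratio of ratios, saturation inversion |
| `venoxim.simulate` | three-compartment finger simulator (static tissue, pulsatile artery, cuff-driven vein), hypoxia-ramp protocols, sampling schedules |
| `venoxim.decompose` | Welch spectra, peak location, FIR band separation, per-cycle AC/DC extraction |
| `venoxim.pipeline` | windowed SpO2 / Mixed_SpO2 / SvO2 / consumption with quality flags |
| `venoxim.control` | simulated cuff feedback loop (frequency separation, SNR, pressure ceiling) |
| `venoxim.evaluate` | RMSE, Pearson r, difference/Bland–Altman analysis, consumption comparison |

A `venoxim` console script exposes `simulate`, `decompose`, `oximetry`,
`closed-loop` and `evaluate` subcommands over CSV/YAML/JSON files.

## Worked example

```python
import numpy as np, venoxim as vx

cfg = vx.SimulationConfig(seed=1)          # SaO2 98 %, SvO2 75 %, pulse 1.2 Hz, cuff 4 Hz
ppg = vx.simulate_ppg(cfg)
result = vx.run_pipeline(ppg)

print(f"windows analysed : {len(result.window_times)}")
print(f"SpO2  (median)   : {np.nanmedian(result.spo2):.2f} %")
print(f"Mixed (median)   : {np.nanmedian(result.mixed_spo2):.2f} %")
print(f"SvO2  (median)   : {np.nanmedian(result.svo2):.2f} %")
print(f"SaO2 - SvO2      : {np.nanmedian(result.oxygen_consumption):.2f} points")
```

prints

```
windows analysed : 11
SpO2  (median)   : 97.89 %
Mixed (median)   : 86.57 %
SvO2  (median)   : 75.42 %
SaO2 - SvO2      : 22.51 points
```

The simulator was programmed with SaO2 = 98 % and SvO2 = 75 %: the pulse
band recovers the arterial value, the stimulation band the 50/50 mixture
(86.5 %), and the inversion the venous value, all within a fraction of a
percentage point at the default measurement noise.  Disabling the cuff
(`venous_stim_amp=0`) leaves SpO2 intact and flags every SvO2 window —
venous stimulation never compromises ordinary pulse oximetry.

The same flow from a shell:

```sh
venoxim simulate --seed 1 --out trace.csv
venoxim oximetry --input trace.csv --out result.csv --summary summary.json
```

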