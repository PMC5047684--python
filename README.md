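# calcimetry

Quantification of Ca²⁺ handling and beating rhythm in recordings from
iPSC-derived cardiomyocytes, built for studies of arrhythmia phenotypes such
as CPVT (catecholaminergic polymorphic ventricular tachycardia), where RyR2
mutations cause diastolic sarcoplasmic-reticulum (SR) Ca²⁺ leak and drug
responses (isoproterenol, β-blockers, flecainide) are compared across
patient-derived lines.

The package covers four recording modalities end to end, plus a
ground-truth-emitting simulator for all of them:

* **Line-scan Ca²⁺ sparks** (`calcimetry.sparks`) — confocal X–T images are
  normalized to ΔF/F₀ against a per-position baseline; elementary release
  events are detected by thresholding at
  `background_mean + criteria × background_sd` (detection criterion 3.8 by
  default) and measured for amplitude (ΔF/F₀), FWHM (µm) and FDHM (ms);
  summaries report spark frequency in events·(100 µm)⁻¹·s⁻¹ and Gaussian
  kernel density estimates (Silverman bandwidth) per parameter, plus the
  r² of FDHM against amplitude.
* **Wave classification** (`calcimetry.waves`) — whole-line transients are
  segmented from the spatially averaged trace; diastolic spontaneous Ca²⁺
  waves (SCW; whole-cell) and wavelets (regional) are detected from their
  spatial extent; each scan is triaged normal / SCW / other (irregular
  amplitude or beat period, alternans, double peaks, plateau decay), with
  SCW taking precedence.
* **SR leak/load protocol** (`calcimetry.leakload`) — the Shannon–Bers
  protocol (1 Hz pacing → 0 Na⁺/0 Ca²⁺ → 1 mM tetracaine → 30 mM caffeine)
  yields four statistics per cell: transient amplitude
  ΔF_trans/F₀,diastolic, SR leak ΔF_tet/F₀,diastolic, SR load
  ΔF_caff/F₀,leak, and fractional release (their ratio), along with
  spontaneous-oscillation counts in the 0 Na⁺/0 Ca²⁺ window.
* **Field potentials** (`calcimetry.fieldpotential`) — microelectrode-array
  traces are annotated for depolarization spikes, T-waves, beat period (BP),
  field-potential duration (FPD) and its Fridericia correction
  FPDcF = FPD / BP^⅓, delayed afterdepolarizations (DADs; low-amplitude
  diastolic deflections), modified Poincaré pairs (beat *n* vs *n*−1) and
  coefficients of variation CV = 100·s.d./mean.
* **Statistics & report** (`calcimetry.stats`, `calcimetry.report`) — the
  line-pooling rule (pool two sub-lines of a group when a two-sample t-test
  finds no difference), Welch t-tests, one-way ANOVA with Tukey HSD, −ΔC_T
  qPCR expression tables with low/medium/high heat bins, and a deterministic
  cohort report.
* **Simulator** (`calcimetry.simulate`) — renders all of the above with
  known planted truth (separable Gaussian × rise/decay spark kernels,
  propagating wave fronts, protocol-shaped traces, spike/T-wave/DAD
  templates, C_T tables) so every analysis stage can be validated against
  ground truth. Drug conditions are parameter presets over event rates and
  morphologies, not pharmacological models.

## Worked example

```python
from calcimetry.simulate import LineScanSimConfig, generate_linescan
from calcimetry.sparks import analyze_linescan

cfg = LineScanSimConfig(spark_rate=6.0, duration_s=2.0, noise_sd=0.08, seed=42)
img, truth = generate_linescan(cfg)          # 258 x 1000 px line-scan + truth
events, summary, norm = analyze_linescan(img)
print(len(truth.of_kind("spark")), summary.n_events)
print(f"{summary.frequency_per_100um_s:.2f}")
for name, s in summary.stats.items():
    print(f"{name}: mean={s['mean']:.3f} sd={s['sd']:.3f} n={s['n']}")
```

prints

```
8 8
10.00
amplitude: mean=0.652 sd=0.080 n=8
fwhm_um: mean=1.976 sd=0.228 n=8
fdhm_ms: mean=32.973 sd=3.872 n=8
```

all eight planted sparks are detected; the frequency (10 events per 100 µm
per second: 8 events / 0.4 of 100 µm / 2 s) and the measured morphology
means sit on the generator's planted distributions (amplitude 0.65 ± 0.08,
FWHM 2.0 µm, FDHM 30 ms).

The same flow is available from the shell, stage by stage:

```sh
calcimetry simulate linescan --condition iso --seed 3 --out sim/
calcimetry sparks sim/linescan.tif --criteria 3.8 --out analysis/
calcimetry simulate leakload --seed 1 --out ll/
calcimetry leakload ll/trace.csv --annotations ll/phases.json --out llout/
calcimetry simulate fp --seed 1 --out fp/
calcimetry fp fp/fp.csv --out fpout/
calcimetry report --measurements measurements.csv --out report/
```

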