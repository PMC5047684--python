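# Methods

This note documents the models, estimators, defaults and numerical choices
behind `calcimetry`, and what the synthetic validation does and does not
establish about real recordings.

## What the simulator emulates

The generator reproduces the statistical structure of four bench
modalities, with a single integer seed driving one random stream per call
(identical config + seed ⇒ bit-identical output, recorded in the truth
object).

**Line-scans.** Geometry follows confocal X–T acquisition: 0.155 µm/pixel
and ≥500 lines/s (defaults 40 µm × 2 s at 500 lines/s). A spark is a
separable kernel: spatial Gaussian with σ = FWHM/2.355, temporal linear
rise (5 ms) followed by exponential decay whose constant
τ = (FDHM − rise/2)/ln 2 makes the kernel's half-maximum duration exactly
the planted FDHM. Spark counts are Poisson with mean
`spark_rate · (L/100 µm) · T`; amplitudes/FWHM/FDHM are truncated-normal
draws. Whole-line transients are spatially uniform elevations with the same
rise/decay shape (250 ms FDHM); waves are fronts propagating at constant
velocity (default 50 µm/s) over a configurable fraction of the scan
(wavelet < 1, wave = 1), planted only in diastolic gaps long enough to hold
them. Planted spark centers and peak times are snapped to the pixel/line
grid so a noise-free rendered peak equals the planted amplitude to within
discretization; without snapping, a sub-sample apex offset on the 5 ms rise
can displace the sampled peak by up to 20% at 500 lines/s. Noise is
additive Gaussian, specified as a fraction of baseline F₀ — one parameter,
sufficient for threshold-detection testing; photon (shot) statistics,
photobleaching, dye compartmentalization and motion are *not* modeled.
Default spontaneous beating is 0.5 Hz, a typical spontaneous iPSC-CM rate;
at the default wave velocity a whole-cell wave over a 40 µm scan needs
~0.8 s of quiet diastole, which faster trains do not leave.

**Leak/load traces.** Phases concatenate in protocol order (≥20 s of 1 Hz
pacing, ~10 s each of 0 Na⁺/0 Ca²⁺, tetracaine, caffeine, then recovery) at
100 Hz sampling. The planted truth satisfies the defining ratios exactly
before noise: paced peaks at F₀(1+A), tetracaine minimum at F₀(1−leak),
caffeine peak at F₀,leak(1+load). The tetracaine drop is a 1 s smoothstep
and the caffeine peak holds a 0.2 s plateau before decaying — the paper
protocol's drop/rise kinetics are not published, and these conventions make
noise-free boundary detection and smoothed peak reads exact. Oscillations
(rise/decay bumps) are planted only in the pre-tetracaine 0 Na⁺/0 Ca²⁺
window (tetracaine abolishes them), thinned to ≥1 s apart so events remain
resolvable.

**Field potentials.** 12.5 kHz sampling. A beat is a sharp positive lobe
(σ = 1.5 ms) peaking exactly at the nominal spike time with a slower,
smaller negative repolarization lobe, plus a Gaussian T-wave (σ = 15 ms) at
spike + FPD. Beat periods are i.i.d. normal at the target CV. DADs are
Gaussian bumps (σ = 20 ms) placed mid-diastole on beats flagged with
probability `dad_probability`, at `dad_amplitude_fraction` (< 1) of the
spike amplitude.

**C_T tables.** Per-sample plate shifts plus planted −ΔC_T offsets relative
to the reference gene; −ΔC_T is invariant to the plate shift by
construction.

Because the generator *is* the validation substrate, passing tests show
that the estimators recover what they are defined to measure under the
stated noise model — they do not certify performance on real recordings
with structured noise, drift, or motion.

## Spark analysis

**Normalization.** F₀ is the per-position median over a declared baseline
window or, absent one, over event-free columns — the columns whose spatial
mean fluorescence lies in the lowest 30%. Whole-line transients elevate
entire columns, which an all-column median is not robust to. Background
mean/SD of the normalized image are robust (median, 1.4826·MAD) over the
same columns.

**Detection.** The ΔF/F₀ image is smoothed with a 3×3 boxcar and
thresholded at `background_mean + criteria × background_sd`
(criteria = 3.8 default). Supra-threshold pixels inside the analyzed mask
are labeled with 8-connectivity after closing gaps ≤ `merge_gap_px`
(default 1); regions under `min_area_px` (default 4) are dropped; one
candidate per region at the smoothed maximum. On a noiseless image the SD
criterion degenerates (threshold = baseline), so a floor of 5% of the
dynamic range applies. Raising `criteria` can only shrink the
supra-threshold set, so detection counts are monotone non-increasing in it.
Transient windows (padded 50 ms) are cleared from the analyzed mask before
detection, and spark frequency normalizes by the unmasked time span and the
scan length per 100 µm.

**Morphometry.** Half-maximum crossings are located by linear interpolation
on profiles through the peak, band-averaged over ±2 neighbouring
rows/columns and boxcar-smoothed over 3 samples. For a separable event this
rescales the profile without changing its half-max width, while raw
single-pixel profiles at SNR 5 suffer a 15–25% first-sample-below-half
stopping bias on FDHM; the walk additionally requires two consecutive
sub-half samples before stopping. The amplitude is read from the unsmoothed
band-averaged temporal profile at the re-localized apex and divided by the
spatial band attenuation implied by the measured FWHM — unbiased at low SNR
where a raw single-pixel read is several percent low (the smoothed argmax
sits a line off the asymmetric apex). Events whose half-max is not
bracketed in the image are flagged truncated and excluded from
width/duration summaries. Measured performance at SNR ≥ 5 (amplitude ≥ 5
background SD): sensitivity ≈ 0.99, |bias| ≲ 8% on FDHM and ≲ 3% on
FWHM/amplitude, false positives ≈ 0 per pure-noise image at criteria 3.8.

**Summaries.** KDEs use Gaussian kernels with Silverman's rule on a grid
spanning the data range ± 3 bandwidths; the density is renormalized so its
trapezoid integral is exactly 1 (the ±3-bandwidth grid alone captures only
~99.7% of the mass). A single-event KDE is the kernel centered on that
value with a fallback bandwidth of 10% of its scale. The FDHM–amplitude
relation is summarized as r² of an ordinary least-squares fit (≥3 events
required; undefined when amplitudes are degenerate).

## Wave detection and triage

Transients are peaks of the spatially averaged trace above both half of the
trace maximum and 3.8 background SDs, with ≥200 ms separation and a
prominence of 25% of the maximum (rejects shoulder bumps from sparks riding
a decay). A whole-line candidate is accepted only if its per-position peak
times are near-simultaneous (robust SD ≤ 60 ms); propagating events fail
this and are left in diastole for the wave detector. This synchrony test is
what separates a paced transient from a whole-cell wave, which a 1-D
averaged trace alone cannot do. Transient intervals run to 5% of peak
amplitude, padded 50 ms; diastole is the complement.

Waves are supra-threshold connected regions in diastolic columns whose
spatial span exceeds 20% of the scan; ≥90% of the scan makes a `wave`,
less a `wavelet`; smaller events belong to spark analysis. Wave frequency
divides by analyzed diastolic time, since waves are diastolic by
definition.

Triage precedence is SCW > other > normal: any wave ⇒ `scw`; otherwise
`other` when amplitude or beat-period CV exceeds 25%, or a morphology flag
fires (strict amplitude alternation with swing > 15%, double-peaked
transients at 30% prominence, transient duration > 1.2 s), or fewer than
two transients were found ("insufficient beats" — such cells are counted,
not excluded); else `normal`. The CV tolerances and flags are conventions,
kept configurable; accuracy on constructed normal / wave / alternans scans
is ~100%.

## Leak/load estimation

Phase boundaries come from supplied switch times when available. The
fallback detector finds the tetracaine phase from the global minimum of a
median-filtered trace, its onset as the last 5%-departure from the pre-drop
plateau, the caffeine onset as the last near-plateau point before the
post-drop maximum, the recovery onset as the first sustained rise after the
caffeine transient has decayed below half, and the pacing end as the last
high-amplitude paced peak plus ~one beat period (low-amplitude 0 Na⁺/0 Ca²⁺
oscillations are ignored by an amplitude cut at 60% of the tallest peak).
On noise-free simulated traces every boundary lands within 0.2 s of truth.

Noisy extrema are read with a two-step estimator: locate the extremum on a
median-filtered copy (edge-safe nearest padding), then take the median of
the raw samples in a window around it — unbiased on plateau-shaped extrema,
exact without noise, and free of the order-statistic bias a plain min/max
over many samples incurs. The tetracaine minimum uses a ±0.5 s window (the
plateau is seconds long); per-beat diastolic minima and the caffeine peak
use ±0.05 s. F₀,diastolic for the leak ratio is the median of the last
second of the 0 Na⁺/0 Ca²⁺ phase — i.e. the diastolic level immediately
preceding tetracaine, which is also robust to oscillations; whether to use
the pre-switch NT diastole instead is exposed through the segmentation. The
paced amplitude averages the last five steady-state beats (peaks via
prominence-based peak finding at 3× the robust noise SD); fewer than five
beats is an error ("steady state not reached"). A negative computed leak is
clamped to 0 with a warning (dye drift can invert the drop; leak is
physically nonnegative), and F₀,leak then equals F₀,diastolic so the
ordering invariant F₀,leak ≤ F₀,diastolic always holds. The caffeine peak
is the interval maximum — no NCX/SERCA decay decomposition. Recovery under
2% noise: mean absolute relative error ~1–3% for all four statistics across
a grid of planted leak/load values.

## Field-potential metrics

Spikes are peaks of |v| above 8 robust noise SDs (MAD-based) with a 200 ms
refractory period, plus a relative floor of 50% of the largest extremum:
T-waves and DADs can exceed any noise-referenced threshold (they are
fractions of a ~mV spike against ~10 µV noise) yet are not depolarization
spikes; deflections above the floor count as spike candidates (ectopic
beats included). The T-wave is the largest extremum of the 5 ms-smoothed
trace in a window from 100 ms after the spike to 80% of the beat period;
beats whose window maximum does not clear 5 smoothed-noise SDs are flagged
and excluded from FPD summaries (the max-over-window statistic itself
reaches ~3.5 SD under pure noise, so the floor must sit above that).
FPDcF = FPD/BP^⅓ with BP in seconds, each beat corrected by the beat period
terminating at it (the first beat has none); the exponent is configurable
for sensitivity checks. DADs are the largest smoothed diastolic deflection
per beat (T-wave + 50 ms to next spike − 50 ms), flagged when inside
0.05–0.5× the spike amplitude — larger deflections are candidate ectopic
spikes, smaller ones noise; the per-beat score (deflection/spike amplitude)
supports ROC evaluation (AUROC ≈ 1.0 at noise up to 0.1× spike amplitude).
CVs use the sample (n−1) standard deviation; Poincaré pairs are
(x_{n−1}, x_n), with FPDcF pairs emitted in seconds.

## Statistics

Sub-lines of a group are pooled when a Welch two-sample t-test (the safer
default where variances may differ; the pooled-variance form is available)
finds p ≥ α, with the decision and p-value recorded; a sub-line with n < 2
declines pooling. Condition contrasts use Welch's t-test for two groups and
one-way ANOVA with Tukey HSD (studentized-range adjusted pairwise p) for
three or more. Degenerate inputs have fixed conventions: identical
zero-variance samples give t = 0, p = 1; identical ANOVA groups give F = 0
and all adjusted p = 1. No correction is applied across variables beyond
Tukey within a variable; `holm_correct` is available for users who want
one. −ΔC_T heat bins default to tertiles of the table (the low/medium/high
cutpoints are display conventions) and are monotone in −ΔC_T. The report
builder applies pooling per variable, annotates every comparison with its
pooling decision, drops rows with unknown line/condition labels (listing
them), and renders sorted-key JSON so regeneration is byte-identical.

## Problem sizes in the validation suite

The test suite and acceptance script size their simulations for a
single-CPU desk run while keeping estimates stable: morphometry recovery
uses 200 seeded 40 µm × 1.6 s images (~400 sparks) plus 200 pure-noise
images; oracle equivalence uses 100 random ≤64×256 px images against a
flood-fill connected-components oracle; classification uses 150 scans (50
per class); CV recovery uses 50 recordings of 60 beats per target;
null-calibration rates use 1000 vectorized simulations at n = 20 per group.

## Known limitations

* The noise model is additive white Gaussian; none of the detectors have
  been exercised against shot noise, baseline drift or motion artifacts.
* Spark morphometry assumes separable, singly peaked events; strongly
  overlapping sparks bias widths, and events straddling the image edge are
  only flagged, not recovered.
* Wave/transient discrimination relies on onset synchrony and fails for
  waves faster than ~1 scan-length per 60 ms.
* The leak/load fallback segmenter expects the protocol's monotone
  drop-then-peak shape; heavily distorted traces need explicit annotations.
* Condition presets encode qualitative drug contrasts for end-to-end
  exercise, not dose–response pharmacology.
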