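# Methods

This package implements a ratiometric Ca²⁺ optical-mapping analysis for
the beating two-chambered heart of larval zebrafish, together with a
synthetic data generator that renders movies and bioluminescence traces
with known ground truth. This note documents the models, the default
parameters and why they were chosen, the numerical decisions, and what
the synthetic data does and does not establish about real recordings.

## The measurement problem

Fluorescence optical mapping of the larval heart quantifies chamber
Ca²⁺ in fixed ROIs, but the heart moves: bright tissue enters and
leaves the ROI with every beat, so single-channel intensity confounds
Ca²⁺ with motion. Two-channel ratiometric biosensors solve this because
motion modulates both emission channels identically, while Ca²⁺ moves
them differentially (FRET pair) or moves only one (Ca²⁺-sensitive
channel fused to an insensitive reference). The per-pixel emission
ratio is therefore motion-insensitive, and an ROI ratio weighted by
channel intensity inherits that robustness.

## Synthetic heart model (`synthetic_heart`)

**Ca²⁺ dynamics.** The atrium fires periodically at `heart_rate`
(default 150 min⁻¹, a typical 3-days-post-fertilization rate at 28 °C).
Every `conduction_ratio`-th atrial event conducts to the ventricle after
`av_delay` (default 80 ms); `conduction_ratio=0` expresses complete
atrioventricular block. Each event launches a peak-normalized
double-exponential transient
`(1 − e^(−t/τ_rise)) e^(−t/τ_decay)` between the diastolic and systolic
Ca²⁺ levels (defaults 0.10 and 1.00 µM; τ_rise = 40 ms,
τ_decay = 180 ms). The waveform is a modelling convenience: only the
levels, the event times and the rate matter to the analysis under test.
Transient tails overlap at physiological rates, so the steady-state
trace minimum sits above the configured diastolic level; analyses are
validated against the steady-state per-cycle extrema of the noise-free
trace, which is what any estimator of systole/diastole observes.

**Sensors.** Emission follows a Hill saturation
`s = ca^h / (ca^h + Kd^h)`. The FRET model (default Kd 2.8 µM, the
troponin-C-based sensor's apparent affinity) emits
`donor = 1 − f_d·s`, `acceptor = 1 + f_a·s` (default f = 0.4); the
reference-fused model (for the calmodulin-based sensor, Kd 0.375 µM)
emits `sensitive = 1 + f·s` over a flat reference. Both ratios are
strictly increasing in Ca²⁺.

**Geometry and motion.** Chambers are ellipses at fixed fractional
positions of the field (default 128×128 px at 1.45 µm/px, 50 frames/s
for 5 s). The ventricular area oscillates between its end-diastolic
value and `(1 − contraction_fraction)` of it, in phase with the
ventricular Ca²⁺ transient. Because the raw Ca²⁺-derived activation
never returns to zero between beats (decay tails), it is renormalized
to its steady-state range so the chamber reaches end-diastole each
cycle, as real chambers do; without this the rendered fractional area
change would systematically undershoot the configured target.
Rasterization is by pixel-center containment; area is pixel count ×
pixel size². Both channels share the motion; the denominator channel is
additionally translated by `channel_pixel_shift` to emulate the
image-splitter offset.

**Camera.** Expected counts are `background + photon_scale × emission`
(defaults 100 and 2000 counts); shot noise is Poisson on that
expectation, followed by additive Gaussian read noise (SD 2 counts).
Noise-free renders (`shot_noise=False`) are bit-exact forward models.

**Aequorin.** The photoprotein pool is consumed as
`dA/dt = −k(ca)·A`, `k = kmax·s(ca)` (default kmax 3 s⁻¹), integrated
exactly per frame with `k` held at the frame-averaged saturation;
counts per 1-s frame are `photon_scale × ΔA + background`. Light
emitted over an infinite record sums to the initial pool, which the
tests verify to the truncation term `e^(−kT)`.

**Scenario presets.** The four study conditions are fixture constants,
not measurements: a beating control (FAC 0.30, 0.10/1.00 µM, 150 min⁻¹);
two arrested-heart conditions — troponin knockdown and myosin
inhibition — with contraction ≈ 0, elevated diastolic and systolic
Ca²⁺ (0.30/1.55–1.60 µM) and reduced rate (105–110 min⁻¹); and a
partial washout recovery. The elevation of diastolic Ca²⁺ was set large
enough that the *measured ratio* effect clearly exceeds the inter-larva
spread (≥1.5 SD): in ratio units the arrested-vs-beating diastolic
difference must beat the trough-tail contamination of the beating
trace, which a smaller elevation does not. A five-condition
incubation/washout series couples contraction inversely with Ca²⁺
levels. Per-larva variability is multiplicative Gaussian jitter
(CV 5%) on rate and Ca²⁺ levels and additive jitter (SD 0.02) on the
contraction fraction.

## Ratio imaging (`ratio_imaging`)

Pixel shift between the channels is estimated as the integer
translation (within ±`max_shift`) maximizing normalized
cross-correlation of the time-averaged channel images, ties broken
toward the smaller shift; correction translates the denominator stack
and *invalidates* out-of-field pixels rather than zero-filling them.
Sub-pixel registration is deliberately off: a beamsplitter offset is a
fixed integer-pixel artifact and integer correction preserves exactness.

The ratio is numerator/denominator per pixel per frame. A pixel is
invalid when the denominator is ≤ 0 or the ratio falls below (minimum
displayed ratio)/4 or above (maximum displayed ratio)×4 — ratios of
near-background pixels are unbounded noise. Invalid pixels are
*excluded* from statistics, never clamped; clamping exists only in the
pseudocolor display (hue = ratio over the display range, brightness =
mean channel intensity). Display ranges default to (0.5, 3.0) for
FRET-type and are user configuration, not measurements. No background
subtraction is applied before ratioing by default.

The ROI ratio is the weighted mean over valid ROI pixels with weights
`(I_num + I_den)/2`. Frames with no valid pixel yield missing values.
ROIs are polygons (pixel-center containment, 0-based row/col
coordinates); JSON polygons and ImageJ `.roi` zip archives are read.

## Trace kinetics (`trace_kinetics`)

Traces are smoothed with a Savitzky–Golay filter (default window 11
frames = 220 ms, order 3; the kernel's noise-variance factor caps
white-noise RMS reduction at √(1/Σc²), ≈2.2× at this window). The
default window was selected where the two opposing biases of per-cycle
extremum extraction — upward inflation of extremes by residual noise
and attenuation of the transient peak by smoothing — cancel to within
~1% of ΔRatio under the reference noise condition; smaller windows
leave a net upward amplitude bias, larger ones a net attenuation. Missing samples are linearly
interpolated before filtering and re-flagged after.

Peaks are local maxima with prominence ≥ `prominence_fraction`
(default 0.3) × the robust amplitude (95th − 5th percentile) and
spacing ≥ `refractory` (default 0.1 s, resolving up to 600 min⁻¹).
Cycles run trough-to-trough: the minima between consecutive peaks plus
the post-final-peak minimum, so m peaks delimit m − 1 complete cycles
(the leading partial cycle is discarded). Whether real cardiac-cycle
boundaries are peak-to-peak or trough-to-trough is immaterial for
cycle-averaged extrema on clean periodic traces; trough-to-trough was
chosen and is documented here.

Systolic and diastolic ratio are the means over complete cycles of the
per-cycle maximum and minimum of the smoothed trace; ΔRatio is their
difference; frequency is peak count / recording duration × 60 min⁻¹
(the count-based definition is canonical; the mean inter-peak-interval
estimate is reported alongside). A quiescent trace (robust amplitude
below an absolute floor) reports frequency 0 and missing level metrics
instead of erroring, so arrested hearts do not crash batch runs.

At the reference noise condition (SD = 10% of CaT amplitude, 50
frames/s, 5-s window, ~12 cycles), recovery is unbiased for all four
metrics; the per-fixture scatter of ΔRatio has a floor of ≈2.3%
(1 SD) because each fixture averages only ~11 per-cycle extremes of
smoothed noise — a variance floor intrinsic to the per-cycle-extremum
estimator, not removable by any Savitzky–Golay parameter choice.

**AV-block classification.** Blocks are called from chamber CaT counts:
block when the ventricle has ≥2 fewer CaTs than the atrium (one event
of slack for window edges); a count ratio within 0.1 of an integer
n ≥ 2 is class "n:1"; a silent ventricle with an active atrium, or any
other deficit, is "irregular". The ventricular peak detector uses an
absolute prominence floor of 0.4 × the atrial amplitude, since
conducted ventricular transients are comparable in size to atrial ones;
this prevents noise peaks in a silent ventricle from masquerading as
CaTs. Limitation: the count-ratio rule is window-parity sensitive — a
5-s window holding 9 atrial and 5 conducted events has ratio 1.8 and is
reported "irregular" rather than "2:1".

## Morphometry (`morphometry`)

Raster (pixel-count) area is canonical; the polygon shoelace area is
reported for QC (the two converge with resolution). FAC =
(ED − ES)/ED. End-diastolic and end-systolic areas are per-cycle
extrema of the area trace, selected with the same cycle logic as the
kinetics and averaged (cycle averaging is the default; a trace without
a full cycle falls back to global extremes, flagged). Negative FAC is
reported with a flag, not clamped — it diagnoses swapped frames.

## Aequorin quantification (`aequorin_quant`)

Raw counts become a rate `L = (raw − background)/exposure`, floored at
zero. `Ltotal` is the summed counts; `Lconsumed[t]` sums frames
strictly before t; `Lmax[t] = Ltotal − Lconsumed[t]` sums frame t to
the end. The exclusive/inclusive split makes conservation
`Lconsumed + Lmax = Ltotal` hold identically at every frame (a
both-inclusive reading would double-count the boundary frame).
`L/Lmax` is proportional to Ca²⁺ and invariant to detector gain and
expression level; it carries units s⁻¹, and proportionality — not
absolute calibration — is what is claimed and tested. It is undefined
where `Lmax` falls below `lmax_floor_fraction` (default 0.05) of
`Ltotal`: with <5% of the pool left the estimate is noise-dominated and
division would blow up. A finite record also biases `L/Lmax` upward by
the unconsumed tail (`Lmax` misses `A(T)`); quantitative comparisons
should use records consumed to ≳99%, as the validation fixtures do.

## Group statistics (`group_stats`)

Each comparison is routed by a Shapiro–Wilk gate at α = 0.05;
"parametric" requires every group to pass (the aggregation rule across
groups is this package's choice). Two groups: pooled-variance unpaired
t-test (Welch available) or Mann–Whitney. More groups: one-way ANOVA
with Tukey HSD (all pairs) or Dunnett (versus control), or
Kruskal–Wallis with Dunn's rank z-tests (tie-corrected,
Bonferroni-adjusted; both all-pairs and versus-control are provided
since many-to-one designs appear in both forms). Nominal outcomes use
Pearson χ² without continuity correction (Yates available); regression
is ordinary least squares with R². Significance codes: */**/***/****
at 0.05/0.01/0.001/0.0001 for parametric branches and x/xx/xxx/xxxx
for nonparametric ones. All tests are two-sided.

## Workflow (`workflow`)

A `RunConfig` fixes the groups (scenario presets + overrides + n), one
base seed, and every stage's parameters; per-larva seeds derive
deterministically from (base seed, group index, larva index) and stay
below 2³¹. Two pipeline levels exist: full movie rendering per larva
(render → shift-correct → ratio → weighted ROI traces → kinetics; area
from chamber-mask pixel counts), and a trace-level shortcut
(forward-model ratio plus Gaussian noise at 10% of CaT amplitude,
analytic area plus 0.5% noise) used for large repeated-seed designs;
the imaging stages are validated on rendered movies separately, and the
two levels agree on every effect direction. Outputs (per-larva metrics,
tidy group table, test results, AV reports) are CSV with a JSON
manifest of SHA-256 content hashes; reruns of the same config reproduce
all outputs bit-for-bit.

## Validation scale and runtime choices

Validation designs run at desk scale: 30 noise fixtures for kinetics
recovery, 20 AV-block fixtures, 2000 Monte-Carlo replicates per
statistical null, 20 seeds for the two-group effect design
(n = 15/group), 50 seeds for the five-condition washout regression, and
64×64 2-s movies for the bit-reproducibility check. These sizes give
stable estimates (binomial SE ≲ 1% on rates) while keeping the full
suite in a few minutes.

## What synthetic validation does not show

The generator emulates the statistical structure the analysis assumes —
uniform chamber Ca²⁺, rigid ellipse deformation, Poisson-Gaussian
camera noise, a fixed integer channel offset. It does not model
nonrigid wall motion, out-of-plane movement, photobleaching, spectral
bleed-through, optical blur, or spatial Ca²⁺ gradients. Passing tests
therefore establish correctness of the computations and robustness to
the modelled artifacts, not performance on every real-microscope
pathology; preset effect magnitudes are constructed fixtures, and
group-level results on synthetic larvae are demonstrations of the
pipeline's sensitivity, not biological estimates.
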