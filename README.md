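# cardioratio

Ratiometric Ca²⁺ optical-mapping analysis for the beating heart of
larval zebrafish, with a synthetic beating-heart generator that makes
every analysis stage testable against exact ground truth.

## The problem

Optical mapping of chamber Ca²⁺ in larval zebrafish uses genetically
encoded biosensors imaged at high frame rates, but the beating heart
moves relative to any fixed region of interest: single-channel
fluorescence confounds Ca²⁺ with motion. Ratiometric sensors emit in
two channels that share the motion but respond differently to Ca²⁺ —
a FRET pair (donor emission falls, acceptor rises with Ca²⁺, e.g. a
troponin-C-based sensor with Kd ≈ 2.8 µM) or an intensiometric
indicator fused to a Ca²⁺-insensitive reference fluorophore. The
per-pixel emission ratio cancels motion while remaining a monotone
readout of Ca²⁺. A third, orthogonal readout is the bioluminescent
photoprotein aequorin, which is consumed as it emits: its light rate L
normalized by the remaining pool, L/Lmax, is proportional to Ca²⁺ and
independent of expression level and detector gain.

`cardioratio` implements the full measurement chain:

* **`synthetic_heart`** — two-chamber heart simulator: periodic atrial
  Ca²⁺ transients with atrioventricular delay and optional conduction
  block, Hill-saturation sensor photophysics, deforming-ellipse
  chambers (motion artifacts by construction), beamsplitter pixel
  shift, Poisson + Gaussian camera noise, aequorin consumption, and
  scenario presets (control, *tnnt2a* morphant, myosin inhibition,
  washout).
* **`ratio_imaging`** — integer pixel-shift estimation and correction,
  pixel-by-pixel ratio with a validity mask (pixels below the minimum
  displayed ratio/4 or above the maximum×4 are excluded, since
  near-background ratios are unbounded), intensity-weighted ROI traces
  (weights = mean of the two channels), pseudocolor display.
* **`trace_kinetics`** — Savitzky–Golay smoothing, cycle segmentation,
  systolic/diastolic ratio, CaT amplitude (ΔRatio), CaT frequency
  (min⁻¹), and atrioventricular-block classification from chamber
  event counts.
* **`morphometry`** — ROI areas (raster + shoelace) and fractional area
  change, FAC = (end-diastolic − end-systolic)/end-diastolic area.
* **`aequorin_quant`** — L, Ltotal, Lconsumed, Lmax bookkeeping with
  exact conservation and the time-averaged L/Lmax Ca²⁺ proxy.
* **`group_stats`** — Shapiro–Wilk-gated comparisons (Student's
  t / Mann–Whitney; ANOVA+Tukey or Dunnett / Kruskal–Wallis+Dunn), χ²
  for nominal outcomes, OLS regression with R², and the */x
  significance-code families.
* **`workflow`** — seeded, manifest-hashed end-to-end experiment runs;
  `cli` exposes everything as the `cardioratio` command.

## Worked example

Simulate one control larva (50 frames/s, 5 s, 128×128 px at
1.45 µm/px, channel shift (1, 4)), then run the complete analysis:

```python
import numpy as np
from cardioratio import synthetic_heart as sh
from cardioratio.ratio_imaging import (
    Roi, apply_shift, compute_ratio_movie, estimate_pixel_shift,
    roi_weighted_ratio,
)
from cardioratio import trace_kinetics as tk, morphometry as mm

cfg = sh.scenario_preset("control", channel_pixel_shift=(1, 4), seed=7)
movie, gt = sh.render_dual_channel_movie(cfg)

shift = estimate_pixel_shift(movie, max_shift=5)
corrected = apply_shift(movie, shift)
ratio = compute_ratio_movie(corrected, display_range=(0.5, 3.0))
roi = Roi.from_polygon(
    "ventricle", sh.chamber_polygon(cfg, "ventricle"), cfg.image_shape
)
trace = roi_weighted_ratio(ratio, corrected, roi)

smooth = tk.smooth_trace(trace, window=11, polyorder=3)
cycles = tk.segment_cycles(smooth, prominence_fraction=0.3, refractory=0.1)
m = tk.cat_metrics(smooth, cycles)

area = gt.chamber_masks_per_frame["ventricle"].sum(axis=(1, 2)) * cfg.pixel_size**2
fac = mm.fac_from_area_trace(area.astype(float), 1 / cfg.frame_rate)

print(f"estimated channel shift : {shift}")
print(f"systolic ratio          : {m.systolic:.3f}")
print(f"diastolic ratio         : {m.diastolic:.3f}")
print(f"CaT amplitude (dRatio)  : {m.amplitude:.3f}")
print(f"CaT frequency           : {m.frequency:.1f} min^-1")
print(f"FAC                     : {fac.fac:.3f}")
```

Output:

```
estimated channel shift : (1, 4)
systolic ratio          : 1.240
diastolic ratio         : 1.082
CaT amplitude (dRatio)  : 0.158
CaT frequency           : 144.0 min^-1
FAC                     : 0.295
```

The shift matches the configured beamsplitter offset; systole/diastole
bracket the forward-model ratio range (1.028–1.261 for 0.1–1.0 µM Ca²⁺
through the FRET model); 144 min⁻¹ is the configured 150 min⁻¹ rate
minus one edge-truncated event in the 5-s window; FAC 0.295 recovers
the configured contraction fraction 0.30 within rasterization error.
Despite the beat moving ~30% of the chamber's pixels across the ROI
every cycle, the ratio trace tracks the underlying Ca²⁺ — that is the
point of ratiometric mapping.

From the shell, the same stages are available as subcommands:

```bash
cardioratio simulate --scenario pab --seed 7 --out run/
cardioratio ratio --in run/movie.tif --split vertical --rois rois.json --out traces/
cardioratio kinetics --traces traces/ --out metrics.csv
cardioratio aequorin --trace lum.csv --exposure 1.0 --window 0:60 --out aeq.csv
cardioratio run --config exp.yaml
```

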