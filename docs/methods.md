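# Methods

## The assay being modelled

Cells expressing a GFP fusion to the 53BP1 IRIF-binding domain form countable
nuclear foci after irradiation. The screen images 96-well plates (two channels:
Hoechst-stained nuclei and the GFP reporter, four fields per well, typically
60–80 nuclei per field, hence ~240–320 nuclei per compound), counts foci per
nucleus with a granularity rule, normalizes each well to vehicle controls
matched for plate, dose and time point, and calls hits by fold change. The
package implements that chain plus a calibrated simulator that stands in for
the microscope.

## Kinetic model of focus counts

Mean true foci per nucleus:

λ(D, t) = A·D/(1 + D/D_sat) · [f·e^(−t/τf) + (1−f)·e^(−t·s/τs)] + b

* **Saturating induction** A·D/(1+D/D_sat) reproduces the observed plateau of
  *countable* foci above ~6 Gy (dense damage merges optically; counting
  saturates even though physical break number keeps rising).
* **Biexponential resolution** captures the fast (NHEJ-like, τf) and slow
  (residual/HR-like, τs) phases of focus disappearance.
* Defaults: A = 23.7 foci/Gy, D_sat = 6 Gy, f = 0.75, τf = 0.6 h, τs = 21.1 h,
  b = 0.2 foci. The paper-level constraints are qualitative (fast-then-slow
  resolution, plateau above 6 Gy); the numeric values are this package's
  calibration, chosen once so that the *full pipeline* detects ≈13.8
  foci/nucleus at (6 Gy, 2 h) and ≈5.6 at (6 Gy, 24 h) — the assay's stated
  operating points — and they live in the default config, not in code paths.
  The time constants are free parameters of the simulator, not measurements of
  MCF7 biology.

Drug action is multiplicative: `formation_scale` on the induced term,
`slow_resolution_scale` on the rate 1/τs (<1 = persistence), `width_scale` on
rendered focus width, `survival_fraction` on nuclei per field. Shipped presets:
CGK733-like (formation 0.48), etoposide-like at 6.25 μM (slow-rate scale 0.36,
expected detected fold ≈1.95 at 24 h) and at 25 μM (formation 1.10 — etoposide
nucleates foci without IR — plus slow-rate scale 0.33, expected fold ≈2.2, used
as the Z′ positive control), topotecan-like (width 0.3), and a toxicity
reference (survival 0.4).

## Count distribution and rendering

* **Per-cell heterogeneity**: counts are gamma-mixed Poisson with a constant
  excess-Fano factor d = 0.3 (cell i draws rate from Gamma(λ/d, d), then a
  Poisson count; Var = λ(1+d)). This keeps per-well fold noise near the
  counting floor, which is the regime the assay's own Z′ > 0.8 implies; an
  NB2-style Var = λ + dλ² at the same d would make that Z′ unreachable at
  240–320 nuclei/well.
* **Nuclei**: non-overlapping (touching allowed) ellipses, lognormal area
  (mean 180 μm², CV 0.16), aspect 0.70–0.95, placed fully interior by dart
  throwing with a retry cap (exceeding it raises a simulation error naming the
  constraint). Stain and diffuse-reporter levels vary mildly per nucleus.
* **Foci**: Gaussian spots, lognormal intrinsic FWHM (2 h mean 0.62 μm growing
  to 0.75 μm at 24 h, CV 0.20) and lognormal peak amplitude (mean 350 gray
  levels, CV 0.30), convolved analytically with the 0.15 μm PSF. A stated
  fraction of foci (15% at 2 h, 0% at 24 h, linear in between) is rendered at
  0.3 μm — below the 3-px width gate — to reproduce the small-foci artifact
  class. Centers are sampled uniformly in the nucleus with **hard-core
  repulsion** (minimum separation = mean at-threshold footprint of the pair
  + 1.5 px, best-of-K fallback when crowded). IRIF are discrete chromatin
  domains that do not interpenetrate, and this choice is what keeps detection
  approximately *linear* in the true count, so planted fold effects are
  recovered with low bias. Without it, random placement at 2 h densities
  merges >10% of spots and compresses fold changes by 5–7%.
* **Channels**: uniform background (150), additive Gaussian read noise
  (SD 12), rounded to uint16. Pixel size 0.3667 μm/px so that the 3-px
  minimum width equals 1.1 μm exactly (the assay's stated px↔μm conversions
  are mutually inconsistent; the pixel gates are taken as primary).

## Analysis chain

* **Segmentation**: Gaussian smoothing (1 μm) → global Otsu → hole filling →
  distance-transform watershed (markers = peaks of the smoothed EDT,
  min distance 10 px, deterministic (row, col) marker order) → area gates
  [40, 400] μm². Border-touching nuclei are flagged and excluded from counts
  by default (partial nuclei bias foci counts). Otsu is histogram-relative,
  so segmentation is invariant to constant intensity offsets.
* **Local background**: grayscale opening of the (0.6 px Gaussian-denoised)
  reporter with a disk of radius 10 px — it erases every structure narrower
  than the disk (max focus gate 19 px < 20 px) while following illumination
  gradients. Implemented exactly via row decomposition of the disk into 1-D
  min/max filters; tests assert bit-equality with the naive opening. The
  mild pre-smoothing is required because the minimum filter of white noise
  is biased low by ~2.5 SD, which would otherwise spend the entire 50-level
  threshold on noise.
* **Detection**: candidates = pixels ≥ 50 gray levels above background inside
  a nucleus; 8-connected components; "width" = equivalent-circular diameter
  √(4·area/π) (rotation-invariant; the gates' "width" is otherwise
  undefined); accepted in [3, 19] px, smaller tallied per nucleus as
  sub-threshold granules, larger rejected. Components are assigned to the
  majority nucleus label (smallest label on ties); peripheral foci are kept.
* **Quantification**: nuclei pooled across fields (not a mean of field
  means); fraction of nuclei with >20 foci uses strict inequality; a
  zero-nucleus well is flagged degenerate, never silently 0.
* **Normalization**: vehicle reference = unweighted mean over non-degenerate
  vehicle wells of the (plate, dose, time) stratum; vehicle wells average to
  fold 1.00 exactly by construction. Missing or zero references are errors
  naming the stratum.
* **Hit calling**: toxicity first (nuclei fold < 0.5, strict, or degenerate
  well), then inclusive cutoffs fold ≤ 0.5 / ≥ 1.5 (the assay description
  uses both strict and inclusive phrasings; the inclusive reading is adopted
  and configurable). The visual secondary screen is automated as a
  non-blocking `sub_threshold_review` flag at ≥2 mean sub-threshold granules
  per nucleus. Note that at 2 h the deliberate 15% small-foci fraction puts
  vehicle wells themselves near ~3 granules/nucleus, so at the default flag
  level the flag marks *all* 2 h wells for review and is informative mainly
  at 24 h and for width-artifact compounds (which reach 15–20).
* **Z′**: 1 − 3(σp+σn)/|μp−μn| with sample (n−1) SDs over per-well normalized
  fold scores (raw means can be supplied instead); undefined when the class
  means coincide.

## Problem sizes used by the test and validation suites

Z′ validation runs the full layout (48 vehicle + 48 positive wells, 4
fields/well, default rendering) for both time points. Operating-point checks
use triplicate vehicle wells (~850 nuclei). Parameter recovery plants
formation scales {0.25, 0.5, 1.0, 1.5, 2.0} at 6 Gy/24 h, one well each plus
four vehicle wells per stratum and the four exemplar phenotypes, over 15
seeded replicates — enough to estimate recovery bias to ~1.7% (SE) against
its 5% bound. The detection oracle check compares against a brute-force
implementation on 200 random ≤128² patches.

## Known limitations and honest misses

* **The suppressor-at-0.48 call rate.** With the CGK733-like formation scale
  fixed at 0.48 and ≤320 nuclei per well, the expected measured fold is
  ≈0.497 (baseline and residual merging push it slightly above 0.48) while
  the per-well fold SD has a counting floor of ~0.012–0.015. The margin to
  the 0.5 suppressor cutoff is therefore ≲1 SD and the per-well correct-call
  probability caps near 50–90% for *any* simulator setting — the published
  control separation itself implies the same arithmetic. The pipeline
  reports this phenotype honestly; the validation test demanding ≥95%
  correct suppressor calls fails and is left failing. Z′-based validation
  (which measures the separation band rather than thresholding single
  wells) passes with margin, which is precisely why Z′ is the right QC
  statistic for this assay.
* The simulator draws i.i.d. per-cell rates; it has no cell-cycle structure,
  no apoptotic/mitotic morphologies, no spatial plate effects (edge wells,
  illumination gradients beyond a linear test ramp), and no time-lapse or 3-D
  rendering. Passing tests therefore demonstrate correctness of the analysis
  chain under those idealizations, not robustness to every real-world
  artifact.
* The >20-foci tail at 24 h comes out near zero under the quasi-Poisson
  heterogeneity (the published value is merely "<5%"); a heavier-tailed
  mixture would reproduce a few-percent tail but would degrade the Z′ window
  below what the assay achieved, so the lighter tail was kept.
* Grayscale values are native units of the stored 16-bit TIFF; the 50-level
  threshold is configurable because camera bit depth differs between setups.
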