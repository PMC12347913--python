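# Methods

## Scope and data model

`nephromorph` operates strictly downstream of segmentation: its input is
a calibrated multiclass label image (or polygon annotation set) of one
kidney tissue section, not the stained image itself. The 20-class
taxonomy covers tissue/cortex/medulla compartments, glomerular
subclasses (non-sclerosed, globally sclerosed, empty Bowman capsule),
the tubulointerstitium with proximal/distal tubules and tubular-atrophy
(TA) clusters, and vessels with arteriolar hyalinosis (AH), intimal
thickening and lumen (cortical arteries/arterioles and medullary
interlobar arteries).

Storage is **multilayer**: one boolean mask per class rather than one
mutually exclusive code per pixel. This is essential because aggregate
layers legitimately overlap — e.g. "Cortex excluding arteries and
atrophic tubules" overlaps the tubulointerstitium layer. The taxonomy's
single-parent containment tree constrains only child ⊆ parent, validated
on load with zero-pixel tolerance. TA clusters nest under the
tubulointerstitium so that %ITA (interstitium-plus-TA fraction) has the
full tubulointerstitial compartment, TA included, as its denominator.

Coordinates are pixel-centered, 0-based, x right / y down; areas are
always reported in µm² (calibration default 0.5 µm/px at 20×, section
thickness 2.5 µm — both configurable).

## Component extraction and edge effects

Connected components use 8-connectivity by default (thin PAS-delineated
structures fragment under 4-connectivity); ordering is area-descending
with centroid tie-breaks so results are deterministic. Component
boundaries are half-level marching-squares contours, which puts the
polygon half a pixel outside the outermost pixel centers; two components
separated by `g` empty pixels therefore have boundary distance exactly
`g·mpp`, which keeps strict distance thresholds unambiguous.

A structure is **edge-bisected** when any of its pixels lies within ε
(default 1 px, configurable — no published tolerance exists for
"adjacent to the cortex edge") of the tissue boundary *excluding*
capsule-marked boundary segments: structures under the anatomical
capsule are complete, structures at a needle/block cut edge are clipped.
With no capsule annotation the whole boundary is treated as cut edge
(conservative: more structures flagged, with a warning). Edge-bisected
structures are excluded from mean-profile-area and glomerular-volume
estimates but retained in counts and densities; both behaviors are
configuration flags, since only the identification rule, not its use, is
standardized.

## Derived measures: choices that were genuinely open

* **Glomerular volume** uses the Weibel–Gomez model `V = (β/d)·Ā^{3/2}`
  with β = 1.38 (spherical shape) and d = 1.01 (narrow size
  distribution), the coefficients of the aging-kidney stereology
  literature; both are config.
* **Cortex per glomerulus** converts areal to volumetric profile density
  by `N_V = N_A/(D + T)` with sphere-equivalent diameter
  `D = (6V/π)^{1/3}`. The choice is supported by a consistency check
  (in the acceptance suite): feeding donor-cohort-scale inputs
  (N_A = 2.46/mm², V = 0.0028 mm³, T = 2.5 µm) yields ≈ 0.072 mm³,
  inside the 0.060–0.080 bracket around published donor means. Profiles
  counted are NSG+GSG; empty capsules are excluded (config).
* **%TA denominator** includes the TA area itself (tubules + TA), and
  the TA foci density shares that denominator.
* **Artery vs arteriole** within the joint vessel class is decided by
  the only printed size criterion: profiles strictly above 7850 µm² are
  arteries (stenosis average), the rest arterioles (AH measures).
* **AH merging** uses minimum boundary-to-boundary distance (not
  centroids) with a strict `< 500 µm` rule and transitive closure; the
  retained representative is the largest lesion and contributes its own
  area, not the cluster sum.
* **Stenosis** treats absent intima as 0% (intima is segmented only when
  thickened), and applies the same gate to cortical and medullary
  arteries, pooled by default with per-compartment values in `extras`.
* **Missing values propagate**: a measure with an absent denominator is
  `None` with a recorded reason, never a silent zero — real cohorts do
  have sections with no qualifying artery.

## Chronicity scores

Band cut points are fixed by the printed thresholds (see README). The
percent measures' printed bands "(<10, 10–25, 26–50, >50)" leave
(25, 26) and the point 50 ambiguous for continuous values; they are read
as [0,10), [10,26), [26,50], (50,∞), i.e. values in (25,26) fall in the
middle band by continuity and 50 exactly stays in band 2. The other
three measures are printed with "≤" lower bands and are read
upper-inclusive: (c₁,c₂] style. Both conventions are overridable via
`BandSpec`. Totals are 0–12 sums of four 0–3 bands; a missing component
propagates by default (`treat-as-0` is available). The reference-limit
report uses the 95th percentile of a reference cohort (≥ 20 observations
per measure) as the upper limit; the percentile is config, as reports of
this kind do not standardize it.

## Synthetic sections and what they do (not) show

The generator lays out vector shapes — circles for glomeruli, tubules
and arterioles, annuli for empty capsules and artery intima/lumen,
smooth Fourier-perturbed star polygons for TA foci — and rasterizes
them afterwards, so true areas are known analytically before
discretization. Ground truth uses:

* exact pixel rectangle areas for compartments (cortex, medulla);
* analytic vector areas for counts, ratios, and mean areas of large
  structures (glomeruli ≳ 4000 px at the default 2 µm/px);
* the generator's own per-structure rasterization bookkeeping for mean
  AH-lesion area and luminal stenosis, because those quantities are
  defined on regions of tens to a few hundred pixels (AH lesions, thin
  intima rings) where the measurand is the label raster itself.

Edge-clipped glomeruli are placed straddling needle-cut edges with the
retained area computed by the circular-segment formula; the capsule band
is drawn only along the anatomical outer edge. Placement keeps guard
margins around the two strict decision thresholds (AH pair distances
outside (470, 530) µm; artery areas outside (7450, 8250) µm²) so the
analytic truth and the rasterized measurement can never disagree about a
strict inequality through discretization alone.

Default presets are **scaled-down** sections (cortex 3–4 mm² at
2.0 µm/px rather than full-slide rasters at 0.5 µm/px) with structure
sizes, densities and composition matched to published donor-like and
tumor-like cohort means (glomerular profile areas consistent with
V ≈ 0.0028 mm³, proximal/distal tubule areas 2768/1523 µm² donor-like
and 4205/2598 µm² tumor-like, AH areas 300/405 µm², stenosis ≈ 16%/28%).
Scale-equivariance of the measures makes this sound for density/ratio
recovery, and keeps 25-scene recovery runs under a minute.

Known limitations of the emulation: tubules are packed circles on a
jittered alternating-row grid, which tops out near 50% tubular fraction,
so the synthetic %ITA (~55–60%) is higher than real cohorts (~25–37%);
no photorealistic texture, staining or scanner variability is simulated;
proximal vs distal tubules differ only in size bookkeeping; interstitial
fibrosis is not distinguished from normal interstitium (the measures are
defined so as not to need that distinction). Passing recovery tests
therefore demonstrate the correctness of the measurement pipeline on
known geometry, not segmentation robustness on real tissue.

The annotator-perturbation operator (seeded dilation/erosion within the
tissue silhouette plus whole-component class flips) exists to exercise
the agreement module; zero magnitude reproduces the input exactly.

## Agreement statistics

TP/FP/FN are pixel areas inside an evaluation region; the default region
is the union of both tissue silhouettes (configurable: full frame or
per-class union), since the denominator of the FP/FN percentages is not
standardized. Within-panel aggregation averages all ordered pairs so the
swap symmetry (precision↔sensitivity, FP%↔FN%) is explicit; mean-of-pair
metrics is the default, pooled-area aggregation is available. Published
per-class agreement tables from real annotator panels are *not*
reproduced — they require the original annotations; only the metric
semantics are implemented and verified against set-arithmetic oracles.

## Numerical notes

* Rasterization fills pixels whose centers lie inside the polygon
  (even-odd parity; boundaries inclusive on the low side), making
  rasterize∘vectorize the identity on boolean masks — verified
  property-based.
* All randomness flows from a single `numpy` PCG64 generator per scene
  spec; identical specs give bit-identical rasters.
* Test problem sizes: recovery uses 25 scenes of 1–4 mm² cortex;
  oracle equivalence uses 50 random rasters ≤ 256×256; the glomerular
  size-distribution check pools 300 profiles over 100 seeds.
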