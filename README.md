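# nephromorph

Morphometry of chronic changes on multiclass kidney-histology
segmentations.

Chronic kidney damage leaves structural fingerprints on a PAS-stained
tissue section: globally sclerosed glomeruli, interstitial expansion and
tubular atrophy (TA), arteriolar hyalinosis (AH), intimal thickening of
arteries, and compensatory nephron enlargement. Modern segmentation
models can label all of these structures on a whole-slide image; what
remains is turning a calibrated 20-class label image into the measure
battery a nephropathologist actually reports. `nephromorph` is that
downstream pipeline, for anyone who has (or simulates) such
segmentations: it computes nephron-size and nephrosclerosis measures,
pixel-agreement validation statistics, and two 0–12 ordinal chronicity
scores, and it ships a seeded synthetic-section generator with exact
ground truth so every measure can be verified end to end.

## The measures

With calibration `mpp` (µm/px) and section thickness `T` (µm, default
2.5), from a label image with one mask per taxonomy class:

* **Glomerular volume** (Weibel–Gomez stereology): from the mean
  non-sclerosed glomerular profile area `Ā` (µm², edge-bisected profiles
  excluded), `V = (β/d)·Ā^{3/2}` with shape coefficient `β = 1.38` and
  size-distribution coefficient `d = 1.01`.
* **Cortex per glomerulus**: areal profile density `N_A = n/A_cortex` is
  converted to volumetric density via the sphere-equivalent diameter
  `D = (6V/π)^{1/3}`: `N_V = N_A/(D + T)`, and the result is `1/N_V`
  (mm³ of cortex supplying one glomerulus).
* **Mean proximal/distal tubular areas** (µm², per-profile mean,
  excluding edge-bisected profiles and tubules inside TA clusters).
* **%GSG** = 100·GSG/(NSG+GSG); **%TA** = 100·TA/(tubules+TA);
  **%ITA** = 100·(tubulointerstitium − tubules)/tubulointerstitium;
  **TA foci density** = TA component count per mm² of tubular area.
* **AH measures**: lesions whose boundaries lie strictly closer than
  500 µm (≈ two adjacent glomerular profiles) are counted once, keeping
  the largest lesion as representative; reported as density per cortex
  mm², % of arterioles carrying AH, and mean lesion area.
* **Luminal stenosis**: for each artery with profile area strictly above
  7850 µm², 100·intima/(intima+lumen); arteries with no detected intima
  (intima is only segmented when thickened) contribute 0%; unweighted
  mean over qualifying arteries.
* **Chronicity scores**: %GSG, %ITA, TA foci density, mean AH area and
  cortex per glomerulus are each banded 0–3 (%GSG/%ITA at <10, 10–25,
  26–50, >50%; TA density at ≤5, 6–10, 11–20, >20 /mm²; AH area at
  ≤500, 501–750, 751–1000, >1000 µm²; cortex/glomerulus at ≤0.075,
  0.076–0.125, 0.126–0.175, >0.175 mm³). The **nephrosclerosis**
  score sums the %GSG, %ITA, TA-density and AH-area bands (0–12); the
  **nephron hypertrophy and nephrosclerosis** score replaces the %ITA
  band with the cortex-per-glomerulus band.

## Worked example

```python
import nephromorph as nm

section, truth = nm.generate(nm.tumor_like_spec(seed=7))
res = nm.quantify(section)
cs = nm.score(res)
```

With the bundled tumor-like synthetic wedge preset this prints (via the
obvious f-strings):

```
cortex area        4.00 mm^2
glomeruli          10 NSG + 2 GSG -> %GSG 16.7%
glomerular volume  0.0025 mm^3
cortex/glomerulus  0.057 mm^3
mean tubule areas  prox 4161 / dist 2555 um^2
%TA 4.0%  %ITA 59.0%  TA foci 3.7/mm^2
AH: 2 lesions, mean 346 um^2, 20.0% of arterioles
luminal stenosis   29.8%
chronicity: nephrosclerosis 4/12, hypertrophy 1/12
```

Counts match the generator's ground truth exactly and every area/ratio
measure agrees with it to well under 2% (`truth.measures` holds the true
values). `%GSG 16.7` falls in the 10–25% band (score 1); the TA focus
density 3.7/mm² scores 0; the mean AH area 346 µm² scores 0; `%ITA`
scores 3 — hence nephrosclerosis 1+3+0+0 = 4 and hypertrophy 0+1+0+0 = 1
(the synthetic interstitium fraction is deliberately generous; see
`docs/methods.md`).

The same pipeline is available from a shell:

```sh
nephromorph simulate --preset tumor --seed 7 --out scene/
nephromorph quantify --in scene/ --out result.csv
nephromorph score --in result.csv --out scores.csv
nephromorph report --in result.csv --reference donors.csv --out report.json
nephromorph agree --test scene/ --ref other_annotation/ --out table.csv
```

Sections are read/written either as per-class indexed PNG layers with a
versioned `meta.json` sidecar, or as GeoJSON feature collections in
pixel coordinates (QuPath-style annotation workflows).

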