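# Methods

## The mapping problem

The target class is rare (< 1% of land at national scale, ~2% in the
default synthetic scenes) and spectrally ordinary at any one date. The
pipeline therefore classifies *seasonal trajectories*: per-season median
reflectance composites, reduced to spectral indices, fed to a random-forest
ensemble. Two facts shape everything downstream:

* **Rarity** means commission error dominates: even a good classifier
  predicting a rare class produces more false than true positives, so the
  mapped area must be corrected with validation-derived error rates before
  it means anything.
* **Confusion classes** (agricultural grasses whose seasonal signature
  overlaps reed's) and **inter-scene reflectance error** (gain/offset
  differences between passes and swaths) are the two degradation mechanisms
  the synthetic experiments isolate.

## Synthetic scene model

`synthetic_scene` generates the study conditions; its defaults are the
conditions every test runs under.

**Landscape.** Class maps are grown from Poisson-placed seeds by randomised
dilation (acceptance probability 0.7 per frontier pixel per round), which
yields contiguous, irregular, monodominant patches; rare classes are grown
first so they are never boxed in. The reedbed fraction is capped below 0.05
by construction (the rare-class regime); the default fixture uses 0.012,
and the validation-prevalence regime (0.042) is reachable by setting the
fraction. The DEM is a base altitude plus an optional linear gradient plus
a Gaussian-smoothed hill field (amplitude 25–30 m, correlation length
~15 px by default) — enough structure for the slope/altitude mask to bite.

**Phenology.** Reflectance is piecewise-constant per season: each class has
a 13-band mean vector per season phase ('green'/'brown') and a per-band
Gaussian scatter (default sd 0.015, independent per band, clipped to
[0, 1]). No quantitative band-level reflectances are published for reedbed,
so the profiles are the package's own choices, set once to plausible
top-of-atmosphere values: summer reed is a vigorous canopy (NIR 0.45),
winter reed is wet senescent litter (NIR 0.22, elevated red, NDWI pulled
towards water); grassland stays green year-round; arable is green in summer
and bare soil in winter. The `confusion_overlap` parameter (default 0.6)
linearly pulls the arable winter profile towards reed's winter profile —
this is the knob that makes arable a genuine confusion class rather than a
trivially separable one. A `latitude_shift` (days of phenological delay per
km of northing) moves season boundaries with latitude; it defaults to 0 and
matters only for scenes hundreds of km tall.

**Acquisition effects.** Per pass: reflectance = gain × (mean + noise) +
offset, with gain > 0 and offset ≥ 0 per band; clouds are smooth-field
threshold blobs overwritten with bright values (≥ 0.6 in all bands,
pre-gain), shadows are displaced blobs darkening the surface to 40%;
the whole grid is then translated by an integer shift (|dx|, |dy| ≤ 3) with
the exposed margin invalid. Cloud truth is recorded for clouds only — the
cloud classifier is deliberately never taught shadows, so the median
composite is the only shadow defence, as in the workflow being modelled.

**Truth polygons** are the vectorised class patches eroded by one pixel
(polygon edges sit away from class boundaries, so point samples are robust
to one-pixel mis-registration). Very large components (class backgrounds)
contribute several window-sized sub-polygons rather than one giant outline.

**What the simulator does not emulate:** radiative transfer, BRDF,
topographic illumination, sub-pixel mixing at patch edges, within-class
spatial autocorrelation of reflectance, swath-boundary geometry, and real
phenological interannual variation. Passing tests therefore demonstrate
that the *pipeline machinery* is correct and that the qualitative
confusion/reflectance-error mechanisms behave as expected — not that the
classifier would achieve any particular accuracy on real imagery.

## Numerical and design choices

* **Dark object** = 1st percentile of valid pixels per band (not the
  minimum), subtracted and clamped at 0: robust to single hot/dead pixels.
  At percentile 0 the operation is idempotent on noise-free input.
* **Registration band** is B8 (NIR) — strongest land contrast. Shifts are
  integer-only: sub-pixel resampling would smooth reflectance, and the
  mis-registration being corrected is itself quoted in whole pixels. Ties
  in the correlation are broken by smallest |dx|+|dy|, then row-major
  scan order. A secondary with < 3% valid content raises a
  registration-failure error and the caller drops the pass.
* **Median compositing**: per pixel per band over valid contributions; even
  counts average the two central values; the composite never leaves the
  convex hull of its inputs.
* **Index formulas** (B-numbers are Sentinel-2 bands): NDVI = (B8−B4)/(B8+B4),
  NDWI = (B3−B8)/(B3+B8) (McFeeters, water-positive — chosen because winter
  flooding is part of reed's signature; Gao's SWIR form is the noted
  alternative), SAVI with L = 0.5, EVI with standard coefficients,
  RG = B4/B3, GB = B3/B2, SB4 = B4 divided by total 13-band brightness
  ("standardised band"). Zero denominators yield invalid pixels, never
  exceptions.
* **Dual forest**: RF1 is fit on the full point sample; RF2 differs by seed
  and, by default, trains on a class-balanced subsample (majority class
  downsampled to the minority count — the analogue of balanced per-class
  bootstrap sampling; reweighting alternatives were measurably weaker at
  equalising per-class OOB errors). Fusion is the per-pixel minimum of the
  two reedbed probabilities, which can only shrink false-positive area at
  a fixed threshold.
* **Threshold**: candidates are 0, 1 and midpoints between consecutive
  sorted unique probabilities; presence is p > t; the smallest candidate
  attaining maximal κ wins. κ is computed on held-out probabilities (OOB
  for points a forest trained on, plain predictions for points outside
  RF2's balanced subsample) to avoid in-bag optimism. Degenerate κ
  (chance agreement = 1) is defined as 0.
* **Terrain mask**: strict inequalities (slope > 10°, altitude > 470 m);
  cells at exactly the limits survive. Slope uses Horn's 3×3 kernel with
  replicated edges. Masking is applied to hectare cover after aggregation,
  with slope and altitude block-averaged to the hectare grid.
* **Hectare aggregation** divides presence count by *valid* pixel count per
  origin-aligned 10×10 block, so Σ(cover × valid count) conserves the
  presence pixel count exactly; partial edge blocks use what they have.
* **Mosaic** overlap rule is the mean of valid values (min/max exposed).
* **Validation design**: the "quarter of the scene" is interpreted as the
  geographic quadrant (2×2 split) containing the most non-zero-cover
  hectares. Strata are {p = 0; (0, 0.33]; (0.33, 0.66]; (0.66, 1]}; strata
  with fewer than 10 qualifying hectares contribute all of them. Observed
  hectare cover is quantised to the nearest 10% by the virtual observer.
  Hectare-scale presence means cover > 0 on both sides. With a rare class
  it is entirely possible for a sampled quadrant to contain no true reed;
  the validation report then omits the undefined statistics rather than
  fabricating them.
* **Extent correction**: true-positive area P·(1−c) divided by (1−o)
  (standard design-based form) or by o (`as_printed`, the form that
  reproduces the published national estimate from its printed inputs; the
  published text does not disambiguate, so both are exposed and the
  standard form is the default).

## Problem sizes

The test suite and acceptance script run everything at desk scale, chosen
as the package's own trade-off between statistical resolution and a
comfortable single-CPU run: 100×100–200×200-pixel scenes, 4–7 passes,
100-tree forests in replicated experiments (500 trees, the production
default, in the single fixture run), 20 paired replicates for the
clean-vs-confusion comparison in the test suite and 10 in the acceptance
script. The Monte-Carlo landscape check uses 20 seeds at 500×500.

## Known limitations

* The two forests differ by seed and balancing; the alternative of
  perturbed training areas is available only as manual polygon subsetting
  (`TrainingSample.subset_polygons`), not automated.
* Cloud polygons for model training come from simulator truth; no visual
  digitisation heuristic is modelled.
* All rasters are assumed on one shared grid: no reprojection, mosaicking
  across projections, or coastline masking.
* 20 m/60 m band resolutions are not modelled; the simulator emits all 13
  bands at 10 m.
* The χ² test for false positives vs land-cover composition is implemented
  and tested on derivable examples, but the corresponding published value
  cannot be recomputed from the published marginals alone.
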