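# Methods

## The classification model

`canopymap` maps 4-band (R, G, B, NIR) sub-meter aerial orthoimagery into
three land-cover classes — tree canopy (3), non-vegetation (2), grassland
(1) — with a fixed-structure, threshold-based decision tree applied
per pixel, followed by morphological cleanup. The model assumes uncalibrated
8-bit digital numbers (DNs), not reflectance: all thresholds are expressed
in DN-derived units and are re-calibrated per acquisition year, because
sensors, solar geometry and phenology change between surveys.

Four per-pixel metrics drive the decisions:

* **NDVI** = (NIR − R)/(NIR + R) — vegetation abundance;
* **NDWI** = (G − NIR)/(G + NIR) — positive over open water;
* **brightness** = R² + G² + B² + NIR² (DN², bounded by 4·(2⁸−1)² = 260 100
  for 8-bit inputs) — grassland reflects uniformly and brightly, tree
  crowns absorb and self-shade;
* **texture** — a second-order gray-level co-occurrence statistic of the
  NIR band over all 8 unit offsets inside a moving window: crowns are rough,
  grass is smooth.

The decision tree is:

1. **Stage I (vegetation delineation).** Non-vegetation iff
   `NDWI > ndwi_min AND NDVI < ndvi_max`. Water satisfies both; impervious
   surfaces and bare soil satisfy both through their low NDVI and
   green ≥ NIR balance.
2. **Sieve.** Connected non-vegetation components smaller than a minimum
   pixel count are merged back into vegetation (see below).
3. **Node 1.** Non-vegetation additionally iff
   `brightness > brightness_nonveg_min`: some building materials have a
   NIR/red ratio high enough to mimic vegetation NDVI but are far brighter
   than any foliage. Node 1 can overturn a Stage-I vegetation call, never a
   non-vegetation call.
4. **Node 2.** Within remaining vegetation, tree canopy iff
   `brightness < brightness_tree_max OR texture > texture_tree_min`;
   everything left is grassland.

All inequalities are strict; a boundary-equal value falls through to the
next rule. The partition is exhaustive and mutually exclusive by
construction, and the vectorized implementation is tested for exact
agreement with a naive per-pixel evaluation of the same rules.

### Texture details

The published threshold (`texture > 50`) is only meaningful relative to a
specific texture definition, which is configurable and defaults to:
statistic = *contrast* (Σ P(i,j)(i−j)²), window = 3×3 (the 8-neighbour
adjacency kernel), and DNs quantized to 32 gray levels to bound the
co-occurrence table. *Dissimilarity* and *variance* are also implemented.
Pairs are tallied symmetrically over all 8 offsets whose endpoints both fall
inside the window; edges use reflection padding; constant rasters score
exactly 0. The fast path (per-offset box correlations) is verified against a
brute-force enumeration of every pixel pair.

### Sieve filtering

Sub-meter imagery produces speckles of false non-vegetation — mostly
tree-occlusion shadows and sensor noise. The sieve removes every connected
non-vegetation component *strictly smaller* than the threshold (size-9
components survive a threshold of 9), with 8-adjacency by default
(4-adjacency available). The operation is idempotent and is checked against
an independent flood-fill component enumeration.

The threshold is held at a fixed **ground area**, not a pixel count:
`ceil(min_area / pixel_size²)` gives 9 px for 9 m² at 1 m and 9 px for
3.24 m² at 0.6 m, so the same 3×3-kernel footprint tracks the survey's
resolution change (3 m at 1 m; 1.8 m at 0.6 m).

### Saturation-consistency correction

An acquisition whose NIR response saturates (the radiometric response
plateaus at high radiance) inflates the NDVI of impervious surfaces and
under-detects non-vegetation. The correction anchors the suspect year on
stable features seen by other surveys:

    corrected = low_ndvi AND (anchor₁ OR anchor₂ OR … OR own_mask)

where `low_ndvi` is the suspect year's `NDVI < 0.15` mask (restricting the
transfer to pixels the year itself considers plausibly non-vegetated) and
the anchors are other years' post-sieve non-vegetation masks; the year's own
mask joins the union. The result is contained in `low_ndvi` and in the
anchor union, and is monotone in each anchor — properties tested
exhaustively on all 16 per-pixel boolean combinations.

### Threshold initialization

`propose_thresholds` seeds manual calibration: each feature's sampled values
are split by the exact 1-D two-cluster minimum-variance partition (prefix-sum
scan over sorted values) and the cutoff is the midpoint between the facing
cluster boundaries. The output is explicitly *initial*; the packaged per-year
YAML file is the hand-refined artifact and is meant to be edited. The same
logic backs `ThresholdTreeClassifier.fit`, which only fills thresholds left
as `None`.

## Synthetic scenes

The generator renders labeled scenes embodying exactly the contrasts the
classifier exploits, so the full pipeline is testable without any imagery
download. Radiometry is specified in DN space. Defaults (8-bit means
R, G, B, NIR; chosen to sit on the correct side of the packaged year-2013
thresholds with multi-sigma margins):

| surface     | label | means              | noise model                    |
|-------------|-------|--------------------|--------------------------------|
| grassland   | 1     | 90, 110, 70, 180   | additive σ = 4 DN              |
| tree canopy | 3     | 60, 80, 55, 150    | per-crown gain U(0.85, 1.30) × per-pixel speckle |
| water       | 2     | 30, 60, 70, 20     | additive σ = 3 DN              |
| impervious  | 2     | 150, 145, 135, 115 | additive σ = 4 DN              |
| roof        | 2     | 220, 220, 215, 200 | additive σ = 5 DN              |
| bare soil   | 2     | 155, 140, 100, 120 | additive σ = 4 DN              |

Crown pixels carry a multiplicative illumination factor
`gain × clip(1 + speckle·z, 0.3, 1.8)`: because it scales all four bands
equally it moves brightness and texture strongly while leaving NDVI/NDWI
untouched. The per-crown speckle rises with the crown's gain
(σ = 0.25 + 0.8·(gain − 0.85), jitter 0.04): brighter, more sun-exposed
crowns also show stronger internal shading contrast, which keeps dark *and*
bright crowns classifiable while leaving realistic confusion at crown edges.
The "roof" surface is deliberately adversarial — its NDVI (−0.048) slips
past the Stage-I cutoff so only Node 1 catches it.

The default layout is an urban mosaic: grassland background, a road cross,
building and bright-roof rectangles, a pond, a bare-soil lot, and clusters
of 2–4 px-radius tree crowns (≈15 % canopy cover). Layout comes from a
`layout_seed`; the spec's `seed` drives only radiometric noise, so specs
differing only in seed share identical truth (emulating repeated surveys of
the same place). All randomness uses numpy's PCG64.

**Shadows** are crown silhouettes swept `height/(pixel_size·tan(elev))`
pixels along the anti-solar azimuth, darkened ×0.35 in the visible bands and
×0.12 in NIR — shade is lit by NIR-poor diffuse skylight, so shadows trip
the Stage-I rule the way real occlusion shadows do; small ones are then
sieved away, large ones persist as the method's acknowledged limitation
(reproduced in a dedicated test). Canopy pixels are excluded (self-shading
is already in the speckle); truth under a shadow remains the underlying
surface. The default sun elevation is 70°, reflecting surveys flown near
solar noon in the growing season.

**NIR saturation** is a compressive plateau: DNs above a knee (60) decay
exponentially (τ = 60) toward a plateau (230). This lifts impervious NIR
enough to hide it from Stage I while keeping its NDVI below the 0.15
correction cutoff — water's low NIR passes through unchanged.

### What the generator does not emulate

Hard-edged patches instead of mixed boundary pixels; no atmospheric or
BRDF effects, no seasonal phenology, no sensor PSF, no shrubs or mixed
grass/tree understory, no wetland water-level dynamics. Consequently the
synthetic scenes are *cleaner* than real survey imagery: passing tests
demonstrate the pipeline's logic (rule semantics, cleanup behaviour, the
vegetation ≫ tree/grass accuracy ordering, the correction's recovery), not
the absolute accuracy attainable on real imagery. In particular tree/grass
separation on synthetic scenes (~91 %) sits above what heterogeneous real
landscapes yield, while remaining clearly below vegetation delineation
(~99 %).

## Validation machinery

Accuracy assessment mirrors a stratified design: a validation tile is
subdivided into a regular grid (20×20 by default) and up to `per_cell`
pixels are drawn from every cell, cycling over the classes present in the
cell so each is represented before any repeats. Confusion matrices are
truth-by-prediction; `overall_accuracy` is trace/total. Two headline
figures are reported because they answer different questions:
`vegetation_accuracy` collapses {grass, tree} vs non-vegetation (Stage-I
quality), and `tree_grass_accuracy` scores only vegetated-truth samples
(Stage-II quality; a non-vegetation prediction there counts as an error).
Binary tree-vs-everything and full three-class accuracies are also
available.

`mask_overlap(A, B) = |A∩B|/|A|·100` is deliberately asymmetric (A is the
mask under scrutiny, B the reference); a symmetric Jaccard variant is
provided.

## Numerical and I/O choices

* Division-by-zero in NDVI/NDWI yields 0 plus a flag rather than an error —
  black nodata borders are routine in orthoimagery.
* Internal band order is fixed (R, G, B, NIR); files stored otherwise are
  remapped at read time. Pixels are area cells, origin top-left, row-major
  0-based indexing. Non-square pixels are rejected.
* Class maps serialize with nodata sentinel 0 (a repo convention — valid
  labels are 1/2/3); a multiband pixel that is 0 in all four bands reads
  back as nodata.
* GeoTIFF I/O goes through `tifffile` with ModelPixelScale/ModelTiepoint and
  GDAL_NODATA tags; ENVI output is band-sequential binary + text header.
  The georeferencing payload is carried through every stage unchanged.
* Cross-resolution mask/map comparison resamples the coarser raster to the
  finer grid by nearest neighbour, which preserves categorical values.
* `ceil` in the area-to-pixels conversion is guarded against float fuzz so
  exact multiples (3.24/0.36) do not round up.

## Problem sizes

Unit and property tests run on rasters between 2×2 and 192×192; the
pattern-recovery checks use ten 512×512 scenes (≈2.6 M pixels per
condition), which stabilizes the reported accuracies to well under a
percentage point across seeds. The acceptance script uses the same sizes.

## Known limitations

Thresholds are only transferable between images with matching bit depth and
texture settings; the decision tree has no notion of mixed pixels; large
contiguous shadows survive the sieve and are misclassified non-vegetation by
design (matching the method's stated behaviour); the correction assumes the
anchor years themselves are well classified and co-registered.
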