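# Methods

## What the pipeline computes

`synoquant` quantifies immunofluorescence-stained synovial membrane the way
a semi-automated histomorphometry workflow does.  The inputs per sample are
multi-channel grayscale images (DAPI plus up to two or three marker
channels), manually delineated region polygons, manually punctuated
intimal-cell centers, vessel outline polygons, and — at cohort level —
group labels and analyte concentration tables with detection limits.

The tissue is partitioned into three regions of interest plus exclusions:

* **ICL** — the intimal cell layer, the apical two-to-three-cell lining of
  a synovial villus (a projection morphologically taller than wide);
* **SI-V** — the subintimal layer of the villous region;
* **SI-N** — the subintimal layer not associated with a villus;
* **EXCLUDED** — damaged tissue or processing artefacts, which never enter
  any numerator or denominator.

Per sample and region the pipeline reports: marker-positive area fractions
(% of region area), co-localization ratios (double-positive area as % of
the parent marker's area), intimal cell density (punctuated centers per
mm² of ICL), and vessel density (outlines per mm², assigned by centroid)
with mean outline perimeter in µm.

## Segmentation primitives

**Locally adaptive binarization.**  A pixel is marker-positive iff its
intensity strictly exceeds the unweighted mean of the square neighbourhood
of half-width `window_px` (default 50, i.e. a 101×101 window), with
edge-inclusive symmetric padding at the borders.  The local statistic,
comparator and padding are the simplest faithful reading of a
local-adaptive-binarize primitive with a stated filter width; all three are
fixed but the half-width is configurable.  Two numerical paths exist:
integer-typed images (the 16-bit outputs of the renderer and any scanner
export) are thresholded in exact int64 arithmetic
(`value·n_window > window_sum`), which is bit-reproducible and makes a
constant image provably all-negative; float images use a box filter with a
relative guard of 2⁻³⁶ so accumulated rounding cannot flip a
mathematically-equal pixel to positive.  The guard is ~10³ above the box
filter's worst-case accumulation error and ~10⁷ below any meaningful image
contrast.  A window larger than the image degenerates to a global-mean
threshold with a warning.  Because the threshold is a local mean compared
strictly, the mask is invariant to global multiplicative rescaling and to
any sufficiently smooth per-channel gain — which is also why each channel
is binarized independently with identical parameters despite differing
acquisition exposures, and why no cross-channel calibration is attempted.

**Co-localization.**  Double-positive masks are the elementwise product
(logical AND) of two binary masks.  The ratio reported downstream is
area-based: double-positive pixels as a percentage of parent-marker pixels
within the region (e.g. CD14⁺ area 10, CD14⁺CD16⁺ area 8 → 80 %).  A
cell-count-based view (`per_cell_marker_positivity`) is provided as a
clearly separated secondary output.  A ratio whose parent area is empty in
a region propagates as a flagged missing value — never 0 or 100 — so it
cannot bias group statistics.

**Per-cell masks.**  Cell masks grow from manually marked centers: every
pixel within `cell_radius_px` (default 15, inclusive) of at least one seed
is assigned to its nearest seed by Euclidean distance, ties to the lower
seed index; pixels farther than the radius from every seed stay unlabeled.
This is exactly the watershed of the seed distance transform restricted to
the union of radius-limited disks (the watershed of a nearest-distance
field is the Voronoi partition of the seeds), realized directly so the tie
rule is explicit and seed-order-deterministic.  The equivalence is
cross-checked in the test suite against an exhaustive nearest-seed oracle
and against an independent watershed implementation.

**Rasterization and assignment.**  A pixel belongs to a region iff its
center (integer coordinates, x = column, y = row, 0-based, origin top-left)
lies inside the polygon; overlaps resolve by the fixed precedence
EXCLUDED > ICL > SI_V > SI_N, chosen because the intimal band is drawn atop
the villus and artefact exclusions must always win.  Pixel-center inclusion
(rather than any-overlap) is unambiguous and matches common rasterizers;
boundary pixels are well under 1 % of region area at realistic scales.
Points (cell centers, vessel centroids) map to the pixel containing them
(floor of coordinates); points on EXCLUDED or BACKGROUND, or out of bounds,
are flagged unassigned and counted, never silently dropped.  Region areas
in mm² are pixel counts times `(pixel_size_um / 1000)²`; vessel lumina are
not subtracted from subintimal denominators (a documented choice).

## Statistics

Group comparison is normality-gated, per variable and region.  Every group
is Shapiro-Wilk tested at α = 0.05; only if **all** groups pass is the
parametric path taken — Welch's t-test for two groups (the unequal-variance
form, since plain "t-test" leaves the variance assumption open), one-way
ANOVA with Tukey's HSD for three or more — and descriptives are reported as
mean ± SD.  Otherwise the non-parametric path is used — Mann-Whitney
rank-sum for two groups, Kruskal-Wallis with Dunn's post-hoc test under a
Bonferroni-type correction for more — with median [Q1–Q3] descriptives
(linear-interpolation quantiles).  Groups smaller than n = 3 or with zero
spread make the gate indeterminate and route non-parametrically.
Significance is α = 0.050 throughout.  Adjusted pairwise p-values are
never below their unadjusted counterparts (asserted property).  Pairwise
`significant` flags are Fisher-protected: both the omnibus p and the
adjusted pairwise p must fall below α.  Protected flagging is a design
choice: it keeps family-wise false positives of null variables near or
below the nominal level while leaving raw and adjusted p-values fully
reported for readers who prefer unprotected inference.

Analyte values strictly below their limit of detection are censored;
analytes censored in 100 % of samples are excluded from testing and listed
in a dedicated below-LOD report block; partially censored analytes are
analyzed complete-case (censored rows dropped, censored fraction reported)
rather than substituted at LOD/2, matching the convention of reporting
below-LOD analytes as untested.

Under a three-group Gaussian null at the cohort's group sizes (11/9/10),
the gated omnibus rejects at close to the nominal 5 % (the acceptance suite
verifies the rate lies in [0.035, 0.065] over 2000 replicates): the gate
occasionally routes Gaussian data to Kruskal-Wallis, but both branches hold
their level.

## The synthetic-data generator

The generator exists so every downstream stage can be tested against exact
ground truth.  Each section is a pure function of (scenario, seed):

* **Geometry.**  A basal subintimal band (SI-N, bottom 22 % of the frame)
  with one villus rising from it: a superellipse-profile finger whose
  bounding-box height/width ratio is drawn from [1.2, 2.5] (the defining
  property of a villus is only that it is taller than wide).  The ICL is an
  annular band of default thickness 30 px (≈ 2–3 lining-cell layers at
  ~10–15 px per cell) along the apical 80 % of the villus outline; the
  villus interior below it is SI-V.  One small circular EXCLUDED patch is
  placed in the basal band so exclusion handling is always exercised.
* **Cells.**  Per-region counts are Poisson with mean density × area;
  positions are uniform over the region's pixels, jittered within the
  generating pixel so that rasterization + floor assignment reproduces the
  recorded region class for 100 % of cells, by construction.  Marker flags
  follow the region's marginal probabilities; co-expression pairs (e.g.
  CD16 given CD14) are drawn through their conditional probability with the
  negative branch chosen so the configured marginal is preserved exactly —
  the scenario validator rejects inconsistent (marginal, conditional)
  combinations.
* **Rendering.**  DAPI nuclei are isotropic Gaussians (σ = 3 px at the
  default 0.5 µm/px — a typical 20× slide-scan resolution, at which the
  15 px cell radius is a plausible 7.5 µm); marker stains are compact
  flat-top blobs `a·(1 − (d/R)⁸)` with support radius R = 6 px and random
  per-cell amplitude.  The flat-top profile is a deliberate choice: under
  local-mean thresholding its recovered area equals its true support disk
  up to a sub-pixel shell for any plausible local background, so
  ground-truth area fractions are recoverable to well within a percentage
  point, whereas a Gaussian's thresholded radius drifts with the local
  signal density.  A multiplicative smooth illumination ramp of amplitude
  0.2 (random orientation) and Poisson shot noise with relative SD
  `noise_level` = 0.05 at unit intensity are applied; intensities live in
  [0, 1] and are quantized to unsigned 16-bit.
* **Ground truth.**  `true_marker_area_fractions` computes the exact truth
  the measurement should recover: per region, the union of support disks of
  marker-positive cells (evaluated at pixel centers exactly as the renderer
  does), intersections for double-positive areas, realized cell counts per
  area for density, and recorded vessel counts per area.
* **Analytes.**  Log-normal per group with configurable detection limits;
  the default panel echoes the magnitudes, wide skewed IQRs and orderings
  of the emulated study's synovial-fluid table, with four analytes
  generated entirely below their limits (IL-1β < 61, IFN-α < 12,
  IL-4 < 40, CCL3 < 5 pg/ml) and total protein higher in foals.

**Scenario presets.**  The packaged F/CTRL/OA presets encode the emulated
study's qualitative contrasts as package defaults — they are calibration
choices, not claims about real tissue: CTRL carries the largest CD14⁺
areas in ICL and SI-V; foals the largest CD206⁺ areas; CD16⁺ areas are flat
across groups (ICL CD16 probabilities are scaled inversely with the group's
ICL cell density, since area ∝ density × positivity and the emulated
finding is flat *area* alongside differing densities); intimal density is
elevated in foals (5532/mm²) and OA adults (5641/mm²) against control
(4300/mm²); vascularization is highest in SI-V with an OA excess only in
SI-N.  Effect sizes for the true contrasts are set large (standardized
differences ≈ 3 at the study's group sizes of 10/11/9) so that cohort-level
orderings are detected in ≥ 90 % of cohort seeds; with six true contrasts
at near-unit power, the binding constraint on that rate is the required
*non*-significance of CD16 in two regions, which under protected flagging
caps the expected pass rate near 0.93.

**What the generator does not emulate** — and hence what passing tests do
not show about real slides: optical blur beyond the blob profiles, spectral
bleed-through between channels, autofluorescence texture, staining
batch effects, tissue folds beyond the single exclusion patch, 3-D
structure, or biological covariance between markers beyond the configured
pairwise conditionals.  Recovery results certify the measurement chain, not
the biology.

## Problem sizes and numerical choices

Synthetic sections are 512×512 px at 0.5 µm/px (≈ 0.066 mm² of tissue,
roughly one villus with its basal band), the package's chosen desk-scale
field of view; preset cell densities then put ~20–30 cells in each region.
Because a region holds only a handful of vessel outlines at this field of
view, preset vessel densities are set so each region contains a countable
number, and vessel-density group statistics remain underpowered by
construction.  Quantile computation uses linear interpolation; Tukey HSD
comes from SciPy's studentized-range implementation; Dunn's z statistics
use the tie-corrected pooled-rank variance.  Degenerate inputs are handled
explicitly: empty regions raise (never NaN), constant data skip testing
with p = 1, duplicate watershed seeds and self-intersecting polygons are
rejected with their indices.

## Reproducibility plumbing

Every output table carries a 12-hex hash of the analysis configuration
(paths excluded); stages refuse to consume tables whose hash differs from
their own configuration.  All cohort randomness descends from a single
seed through a `SeedSequence`, so re-running a configuration reproduces
`measurements.csv` byte-for-byte; the simulate manifest records per-file
checksums of all annotation outputs.

## Known limitations

* Villus delineation is an input, as in the emulated workflow — there is no
  automatic villus detection or ICL band extraction.
* No minimum-object-size filter is applied after binarization (none is
  part of the primitive's definition); speckle robustness therefore relies
  on the signal model.
* The co-localization ratio inherits the instability of ratios whose
  parent areas are small; the pipeline's answer is flagging (missing when
  empty), not shrinkage.
* One measurement row per sample; no averaging of repeated biopsies per
  joint is performed or modelled.
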