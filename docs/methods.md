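# Methods

## The measurement model

`tdluquant` treats one slide as a pixel grid with a physical resolution
(μm/pixel; 0.16 is the default, matching a ×40 whole-slide scan) carrying
four observations: a tissue-foreground mask, an adipose estimate, a TDLU
instance label image, and a set of acinus detection points. All
coordinates are 0-based `(x, y)` with `y` down and points at pixel
centers; rasters are indexed `[row, col]`. The measurement stage is
deliberately agnostic about where the observations came from — a CNN, a
color-threshold rule, or human annotation — so the same measures apply to
every arm of a validation study.

### Adipose-adjusted tissue area

Densities are computed per mm² of *non-adipose* tissue:
`A_adj = A_tissue · (1 − f)`. The adipose fraction `f` comes in two
granularities, reflecting how automated and manual assessments differ: a
pixel mask (then `f = |adipose ∧ tissue| / |tissue|`) or an observer's
quartile bin, mapped to its center value (12.5, 37.5, 62.5 or 87.5%).
Both forms reduce to a fraction through one function so downstream code
never branches.

### TDLU span

The span of a TDLU is the major-axis length of the ellipse having the
same normalized second central moments as the region:
`span = 4·√λ_max · res`, with `λ_max` the largest eigenvalue of the
population covariance of the region's pixel-center coordinates. For a
filled disc of radius `r` the coordinate variance is `r²/4` in every
direction, giving span `2r`; for an ellipse with semi-axes `a ≥ b` it
gives `2a`. No pixel-extent (+1/12) variance correction is applied: a
single pixel therefore has span 0, and rasterized shapes agree with the
continuous closed form to within about one pixel (≤ 2% at the radii of
interest, verified in the test suite). The computation agrees with
scikit-image's `regionprops` major-axis length to numerical precision;
it is implemented directly so that the definition is explicit and
testable against closed forms.

### Acinus assignment and calibration

Each acinus is assigned to the TDLU instance whose pixel contains its
centroid; there is no nearest-TDLU snapping (a snap radius could be
added, but centroid containment is the simplest rule consistent with
defining TDLUs as clusters of acini). Acini on background count toward
`acini/mm²` — that measure is defined per tissue area, not per TDLU —
but not toward any per-TDLU count.

Automated acinus counts are systematically lower than manual counts (a
detector counts distinct ring profiles in one section; an observer counts
spherical structures). The calibration model is a multiplicative
coefficient fitted by least-squares regression *through the origin* of
manual on automated counts: `c = Σ(a·m) / Σa²`. The default, 3.888, is
the coefficient established for this measurement protocol on paired
manual/automated assessments; `fit_calibration` also
reports the free-intercept fit's intercept estimate and standard error as
a diagnostic (the origin model is retained — a zero count must calibrate
to zero). The slide-level measure takes the median of raw per-TDLU
counts and multiplies it by `c`, which by linearity of the median under
positive scaling equals calibrating each count first; the per-TDLU
records carry both scales.

### Qualitative classification

Russo lobule types are a step function of the acinus count: type 1
below 12, type 2 from 12 through 80, type 3 above 80. The boundary value
80 is assigned to type 2 (the conventional phrase "between 12 and 80" is
read inclusively). Classification consumes *calibrated* counts by
default since the thresholds were defined on manual counting
(`use_calibrated=False` switches to raw). The slide summary is the modal
type, with ties broken toward the higher (less involuted) type — a
deterministic, conservative choice that errs toward flagging less
involution. "Predominantly type 1" in the Baer categories is read as a
strict majority (> 50%); exactly half is not predominant. Consensus
among raters is a strict majority as well, with no winner flagged as
undefined for adjudication rather than silently resolved. Type 4
(pregnancy/lactation) lobules are out of scope.

## Agreement statistics

Detection agreement uses maximum-cardinality one-to-one matching
(Hungarian algorithm) between predicted and true points, with pairs
farther than a physical radius disallowed. The radius defaults to
15 μm — on the order of an acinus radius — because no standard hit
criterion exists for this task; it is surfaced in every report. The
matched-pair count is unique even when the matching itself is not, so
precision/recall/F1 are permutation-invariant. Dice is implemented as
`2|A∧B|/(|A|+|B|)` and equals F1 computed on pixel sets exactly (a
property test asserts this); two empty masks score 1 (perfect agreement
on absence). Per-slide scores aggregate as mean ± sample SD.

ICC(3,1) — two-way mixed effects, consistency, single rater — is
computed from the ANOVA decomposition
`ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E)`, with the 95% CI from the
F-distribution bounds on `F = MS_R/MS_E` with `(n−1, (n−1)(k−1))`
degrees of freedom. Consistency means rater main effects are removed:
adding a constant to one rater's column does not change the statistic.
Fleiss' κ follows the original formulation with the large-sample null
standard error for the z-test against κ = 0. Both are validated against
independent brute-force oracles and against pingouin / statsmodels in the
test suite; the generic association tests (Spearman, Mann–Whitney U,
Kruskal–Wallis, χ²) simply delegate to scipy, as they are standard
machinery rather than part of this method. Intra-observer agreement
between two sessions of one observer reuses the same κ computation with
`k = 2`; the "raters" are then sessions, which is a repeatability, not a
reproducibility, statement.

## Synthetic slides

The generator emulates the geometry the measures respond to, not H&E
texture. A slide is a tissue region (rectangle with margin, or a wobbled
ellipse "blob") colored as pink stroma; bright near-white discs form
adipose; each TDLU is a disc of slightly basophilic intralobular stroma
containing non-overlapping annular acini (purple epithelial ring, pale
lumen) — the annulus gives detectors the ring signature that real acini
present. TDLU discs are placed by random sequential addition, largest
first, fully inside tissue and non-overlapping; when a disc cannot be
placed it shrinks by 8% down to a floor that still packs its planted
acini (the floor keeps the acinus packing fraction near 30%, well below
the ~55% random-packing jam). Requested configurations that cannot fit
even at the floor raise an error rather than silently degrade. Adipose
blobs are added until the achieved fraction is within 0.01 of target or
the attempt budget runs out (±0.05 for feasible targets).

Default magnitudes are chosen at realistic scale: TDLU radii 150–350 μm
(spans ~300–700 μm), 12 TDLUs on a 2048² frame, acinus radii 12–20 μm,
log-normal acinus counts (median ~20, range ~5–80), adipose fraction
0.30. The synthetic frame uses 2 μm/pixel — coarser than a ×40 scan — so
these structures fit a desk-scale raster; all outputs are in physical
units, so the resolution choice does not propagate into the measures.

Ground truth is exact: planted counts and analytic spans/areas
(`2R`, `πR²`) plus rasters rendered from the same geometry. Densities in
the truth are computed from the rendered rasters, so a noiseless pipeline
run reproduces counts and densities *bit-exactly*, while spans and areas
agree within rasterization error (≤ 2%). What passing these tests shows
is that the measurement chain is correct on its inputs; it does not show
that any segmenter works on real H&E — slide realism (texture, stain
variation, touching TDLUs, lesions) is explicitly not modeled.

`perturb_observations` degrades the true detections — independent drops,
uniform spurious points at a Poisson rate per mm² of tissue, Gaussian
jitter — to place the detector at a controlled operating point for
metric-fidelity tests. `simulate_observer` emulates the manual protocol:
a ~50 mm² square region of interest containing at least one TDLU, a
binned adipose estimate, TDLU counting within the region, and span/count
reads on up to 10 randomly chosen TDLUs, with optional Gaussian noise
and a counting-scale factor (the quantity calibration corrects). With
zero noise and unit scale the observer reproduces truth exactly, which
anchors the calibration-recovery and ICC simulation tests.

## Backends

The measurement pipeline consumes `SlideObservations` from any source.
The *reference* backend is a deterministic color-threshold segmenter
tuned to the synthetic palette (tissue = non-white; adipose = near-white
tissue; TDLUs = blue-excess stroma with lumen holes filled, 4-connected
components; acini = size-filtered ring components' centroids). It is a
test double enabling end-to-end runs without data or trained models, not
a histology segmenter. The *learned* backend is a per-pixel logistic
regression (L-BFGS, warm-started rounds, features: RGB plus
Gaussian-smoothed RGB at σ = 2 and 4 px) trainable on labeled synthetic
patches in seconds on a CPU; it demonstrates the full train / serialize
/ predict / evaluate loop and reaches Dice > 0.8 on held-out synthetic
adipose patches. `tile_and_stitch` runs any per-patch function over a
large frame with central-crop blending: for functions whose output
depends only on a neighborhood smaller than half the overlap, stitching
is exactly equivalent to whole-frame application. Seeded k-fold
splitting by slide id is provided for cross-validation studies.

## Numerical and interface choices

- Medians use the even-`n` mean-of-central-order-statistics convention
  (numpy's default).
- A slide with zero TDLUs reports densities of 0 and undefined (NaN)
  medians, with a warning — never a silent 0.
- `min_tdlu_area_mm2` defaults to 0 (no size filter); when set,
  instances are removed before *all* statistics.
- Label images are stored as 16-bit single-channel TIFF (instance counts
  can exceed 255); binary masks as 0/1 PNG. Readers reject multi-channel
  images and missing CSV columns rather than coercing.
- Annotation polygons are filled by pixel-center containment; acinus
  annotations drawn as small squares reduce to their centroids (the
  square extent is a drawing convenience, not a measurement).
- All CLI outputs carry a JSON/YAML provenance record (configuration,
  seed, package version) sufficient to reproduce them.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use 1024² synthetic slides
(20 seeds) for measure recovery, a 4096² slide with ~2 100 planted acini
for the detection operating point, a 2048² slide for the end-to-end
chain, 1000 random 5×3 tables for the ICC oracle, and 12 synthetic 192²
patches (8 train / 4 held out) for the learned segmenter — sizes at
which every check runs in seconds to a few minutes on one CPU while
keeping estimator noise well below the asserted tolerances.

## Known limitations

- The reference backend and the synthetic palette are co-designed;
  neither transfers to real H&E.
- The synthetic generator plants disjoint disc TDLUs; complex clustering
  and boundary ambiguity — major sources of real-world segmentation
  error — are absent, so segmentation Dice on synthetic data is near 1
  by construction.
- The span definition is the moments-ellipse major axis; manual span
  (two points chosen on the boundary) measures a related but not
  identical quantity, and the two should be compared through agreement
  statistics, not assumed equal.
- Fleiss' κ significance uses the large-sample null SE; for very few
  subjects the p-value is approximate.
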