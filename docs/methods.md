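# Methods

This note documents the models, measurement procedures, numerical choices
and known limitations of `hevscape`. It is the package's own account of its
science; every number quoted as a result is computed by the test suite or by
`scripts/acceptance.py`, not asserted here.

## The measurement problem

High endothelial venules (HEVs) are the specialized post-capillary venules
through which naïve lymphocytes enter a lymph node (LN). In invasive breast
cancer, tumor-draining LNs show remodeling of these vessels — lumen
dilation, thinning of the normally cuboidal endothelium, discontinuous
expression of the HEV addressin PNAd — together with dysregulation of the
perivascular fibroblastic reticular cells (FRCs): loss of perivascular
CCL21, loss of CCL21-binding heparan sulfate (HS), and accumulation of
CCL21-saturated lymphocytes around dilated vessels. `hevscape` turns the
manual scoring scheme behind those observations into an automated pipeline
over multichannel immunofluorescence images (DAPI, PNAd, Claudin-5, CCL21,
αSMA, cytokeratin, CD3, HS), plus a synthetic-image generator that provides
exhaustive ground truth so the whole analysis is testable at desk scale
without patient material.

## Regions

* **Tissue.** The total LN area is the DAPI plane inside the fixed 6–255
  intensity window (8-bit scale), hole-filled, with components below
  1000 µm² discarded. 16-bit planes are linearly rescaled to 8-bit
  (divide by 257) before any fixed window applies, since the windows are
  defined on the 8-bit scale.
* **Tumor.** Cytokeratin inside 35–255, restricted to tissue. Foci are
  hole-filled before labeling — tumor cells surround vessels, and a vessel
  enclosed by a focus belongs inside it — and components below 200 µm²
  are discarded: an isolated suprathreshold pixel is noise, and without
  this floor each such pixel would carve a 200 µm exclusion disc out of
  the paracortex. Metastatic burden is tumor area as a percentage of
  tissue area.
* **Paracortex.** The T-cell zone is defined by CCL21⁺ FRC staining: the
  CCL21 plane is thresholded (per-plane Otsu with a 20-intensity floor,
  overridable per channel), morphologically closed with a 25 µm radius to
  bridge the reticular mesh into a solid region, hole-filled, then
  everything within 200 µm of the tumor border or of parenchymal fat is
  removed. Fat is a user-supplied mask (or absent); automated adipocyte
  detection is out of scope.
* **Zones.** A vessel is zoned by its centroid: inside a (hole-filled)
  focus → IM; within 200 µm of a focus → MA; inside the paracortex mask →
  PARACORTICAL; otherwise EXCLUDED. The zones are exclusive by
  construction. Distances are Euclidean on the pixel grid times the
  µm-per-pixel calibration.

All binary morphology with physical radii (dilation, erosion, closing) is
implemented through exact Euclidean distance transforms, so the cost is
independent of the structuring-element size.

## Vessel detection

Candidate walls are Claudin-5⁺ pixels (Otsu threshold) closed with a 2 µm
radius — enough to seal staining gaps up to ~4 µm without merging vessels
kept ≥ 13 µm apart. Connected components become vessels when (a) their
area is at least 50 µm² (there is no printed inclusion criterion; this is
our floor), (b) at least 10% of the component lies within 2 µm of PNAd⁺
signal, and (c) the centroid falls inside the analysis mask. The PNAd gate
is applied at **component level** rather than per pixel: a pixel-level
CLDN5 ∧ near-PNAd gate would delete the PNAd-negative arc of a
discontinuous-PNAd wall and artificially open its lumen, whereas the
component gate keeps the Claudin-5-defined wall intact and PNAd coverage
is then scored on it. The lumen is the hole-fill of the wall minus the
wall; lumens under 5 µm² count as closed (sub-cellular "lumens" are
staining artifacts). Vessels touching the image border are flagged and
excluded from all statistics, because partial annuli bias the diameter.

## Morphometry

* **Lumen diameter.** The manual protocol ("mean of three measurements of
  the shortest cross-sectional diameter") is operationalized as the
  inscribed-circle diameter: twice the Euclidean distance-transform value
  on the lumen medial axis, averaged over up to the three largest
  medial-axis local maxima (plateaus clustered; a disc has a single
  peak). For a disc this is the diameter, for an elongated lumen the
  shortest cross-section; the estimate is within one pixel of the
  analytic value for discs, ellipses and rectangles (property-tested
  against a brute-force max-EDT oracle). The medial axis is computed by
  topological thinning (`skimage.morphology.skeletonize`) with a separate
  exact EDT.
* **Dilation class.** 0 → NON (closed lumen); 0 < d < 10 µm → INT;
  d ≥ 10 µm → HIGH. The class boundary is assigned upward: the defining
  rule covers "<10" and ">10" and leaves equality unstated, so the
  boundary assignment is documented here and configurable
  (`dilation_high_um`).
* **Endothelial thickness.** Mean of twice the EDT along the wall medial
  axis — the local wall width averaged over the annulus. The thin flag
  compares it with 3 µm (config `thin_ec_um`): the underlying criterion
  ("lack of cuboidal endothelium") is qualitative, so the numeric
  threshold is ours and the flag is only meaningful relative to it. For a
  closed (non-dilated) vessel the wall is a filled profile, so the value
  measures the whole collapsed cross-section rather than a single wall
  layer; thin-EC analysis is about dilated vessels, where the annular
  width is well defined.
* **PNAd continuity.** Wall pixels are binned by polar angle around the
  lumen centroid (72 bins); a bin is positive when more than half of its
  wall pixels are PNAd⁺; coverage is the positive fraction of occupied
  bins. A wall is *discontinuous* when coverage < 0.90 **and** the longest
  contiguous negative arc is ≥ 10 µm at the wall mid-radius — the second
  condition stops pixel-level noise from being called discontinuity.

## Perivascular scoring

The scoring ring is the band within 10 µm outside the wall (≈ one
perivascular FRC layer; no width is printed for "vessel-lining"), minus
other vessels' walls and lumens. Marker coverage (CCL21, αSMA, HS) is the
fraction of angular bins whose ring pixels contain ≥ 2 positive pixels,
mapped to categories by two cutoffs: ≥ 0.80 → CONTINUOUS, ≤ 0.10 → NONE,
else PARTIAL. The visual continuous/partial/none scheme has no printed
cutoffs; both are config fields and are recorded in every run manifest.
HS uses the same scorer; "full or partial loss" maps to NONE/PARTIAL.

**CCL21 morphology.** CCL21⁺ signal inside the paracortex is decomposed
into lymphocyte-shaped blobs versus remainder. A blob is a connected
component whose hole-filled outline has area 20–120 µm² and circularity
≥ 0.6 (blobs are rim-stained, so shape measures use the filled outline);
αSMA⁺ blobs are excluded from immune-cell candidates. An LN is labeled
IMMUNE_CELL when blob-assigned CCL21⁺ area reaches 50% of all CCL21⁺ area
(config `morphology_blob_fraction`).

**CD3 co-positivity.** For each highly dilated vessel, candidate
CCL21⁺/αSMA⁻ blobs within 25 µm of the wall (`cd3_search_um`) are scored:
the CD3⁺ fraction f maps to 100% (f = 1), >50%, <50%, or 0%; no candidates
→ NA. The association radius is deliberately wider than the 10 µm marker
ring: CCL21-coated lymphocytes accumulate around, not on, the vessel, and
blobs inside the marker ring would contaminate the CCL21 coverage score
with their own rims. Blobs lying between two vessels can be counted for
both; with dense crowding an occasional category flip is expected.

## Statistics

Group endpoints are per-LN values (dots-are-LNs), not per-vessel. Every
endpoint passes a normality gate before branch selection: Shapiro-Wilk,
D'Agostino-Pearson, and Lilliefors-corrected Kolmogorov-Smirnov run once on
the pooled group-mean-centered residuals, each at α = 0.02; the gate passes
when all applicable tests pass (tests that cannot run at the available n
are skipped). Pooling residuals instead of testing every group separately
keeps the gate's false-alarm rate low (three correlated tests at 0.02,
Gaussian pass rate ≈ 0.95) while the union of the three tests retains high
power against heavy tails; with per-group testing, twelve tests at α = 0.05
would send almost half of perfectly Gaussian 4-group endpoints down the
non-parametric branch. At four groups of 20 the gate selects the parametric
branch on Gaussian data and the non-parametric branch on t₂ data in ≥ 90%
of simulations each (tested); at the study's smaller per-group sizes the
separation is weaker.

Parametric branch: one-way ANOVA with Holm-Sidak-adjusted pairwise t tests
(paired/unpaired t for two groups). Non-parametric branch: Kruskal-Wallis
with Dunn's rank-based post-hoc z tests (tie-corrected), Holm-adjusted —
Dunn's correction method is not printed, so Holm is our choice —
Mann-Whitney or Wilcoxon signed-rank for two groups. Correlation endpoints
use Spearman. Dunn's test is implemented in-package (no post-hoc library in
the dependency set) and is unit-tested against a hand-computed example.
Every result records the branch, the gate outcome and the adjustment.
Groups with n < 3 cause the endpoint to be skipped with a logged reason.

## Synthetic cohorts

The generator emulates exactly the structures the pipeline measures:

* **Vessels** are elliptical annuli (Claudin-5 on the whole wall, PNAd on
  a contiguous angular fraction with one gap). Lumen semi-axes (a, b) with
  a ≥ b; the shortest lumen diameter is 2b by construction; a closed lumen
  (b = 0) renders as a filled ellipse. Wall thickness is uniform in
  4–6 µm (normal) or 2.2–2.8 µm (thin). Class diameter ranges are
  INT [5.5, 8.5] µm and HIGH [13, 28] µm — at least 1 µm clear of the
  10 µm boundary so rasterization (≤ 1 px ≈ 0.5 µm) cannot flip a class.
  Closed vessels are never thin: a thin-walled filled ellipse would fall
  under the 50 µm² detection floor, and thinning rarely occurs without
  dilation anyway.
* **Perivascular marker bands** (CCL21/αSMA/HS, 2 µm wide) are rendered on
  angular arcs drawn from the per-class category probabilities: NONE →
  coverage ≤ 0.04, PARTIAL → 0.35–0.65, CONTINUOUS → 0.93–1.0, i.e. safely
  inside the scoring cutoffs. Coverages are in angular measure, matching
  how the pipeline scores them; for mild aspect ratios (≤ 1.6) the angular
  and arc-length fractions differ by less than the 0.03 recovery
  tolerance.
* **Stroma** is a jittered-grid reticular mesh (CCL21/αSMA/HS) over the
  tissue, cleared around vessels so the controlled perivascular band is
  the only signal inside each scoring ring, and absent inside tumor foci.
  The paracortex closing re-bridges these clearances, so cleared zones
  stay inside the paracortex mask.
* **Lymphocyte blobs** are discs of radius 3.2–4.5 µm with CCL21 on the
  rim (surface-bound chemokine) and brighter rims than interiors; CD3⁺
  blobs carry interior CD3. LNs drawn with the lymphocyte phenotype get
  ~18 blobs per highly dilated vessel, ~8 per intermediately dilated one
  (placed 12–25 µm outside the wall, clear of all marker rings), a
  scattered population of 800 blobs/mm² between mesh lines, and a sparser
  mesh (60 µm vs. 18 µm spacing) — reduced reticular CCL21 accompanies
  the phenotype. Non-phenotype LNs carry at most one blob per dilated
  vessel. This makes the blob-area fraction cleanly separable around the
  0.5 morphology cutoff (≈ 0.6–0.8 vs. ≲ 0.1).
* **Metastases** are cytokeratin discs (85–110 µm radius, one per LN in
  the packaged node-positive profile) with dense DAPI, placed off-center;
  intrametastatic vessels sit fully inside, metastasis-associated vessels
  within 8–175 µm of the border, paracortical vessels beyond 225 µm.
* **Noise** is additive Gaussian, SD 8 on the 8-bit scale (≈ 5% of the
  wall amplitude 160), clipped to [0, 255] and stored as 16-bit
  (value × 257).

Placement is rejection sampling, largest vessels first, with ≥ 13 µm
wall-to-wall separation (so no vessel's 2 µm rendered band can reach a
neighbour's 10 µm scoring ring). A paracortical vessel that cannot be
placed after 500 draws restarts the whole placement with fresh positions
(up to five attempts; retries re-place, never drop, so the class mix
driving the dilated fractions is untouched) before a generation error is
raised. MA/IM vessels that cannot fit are dropped with a warning instead —
their focus is simply full, and their CCL21 category is drawn
independently of geometry, so the zone CCL21 fractions are unaffected by
which vessels fit (the zone dilation mix, a non-headline readout, can
shift slightly toward smaller vessels in crowded foci). The paracortical
vessel count per LN is deterministic (`vessels_per_ln`); MA/IM counts are
Poisson, capped at what a focus can host. The truth table always reflects
exactly what was rendered.

**Packaged profiles.** Four profiles encode printed group-level fractions
as generative probabilities: organ donors (15 LNs, 10% dilated), DCIS
(19 LNs, 34% dilated, 5% lymphocyte phenotype), node-negative invasive
carcinoma (25 LNs, 48% dilated, 50% phenotype) and node-positive invasive
carcinoma (25 LNs, 49% dilated, 55% phenotype, one metastatic focus per
LN with CCL21-none probability 0.87 inside and 0.35 within 200 µm). Only
the total dilated fraction per group is printed; the INT/HIGH split, the
thin/PNAd-discontinuity rates and the per-class CCL21/HS category
probabilities are this package's choices, set once to plausible values
consistent with the qualitative findings (strongest dilation and CCL21/HS
loss around highly dilated vessels in invasive disease). Field sizes are
1792² px (2304² for the metastatic profile, so the 200 µm exclusion zone
leaves a usable paracortex) at the default calibration of 0.5 µm/px — no
pixel size is printed for the original scans, so the calibration is a
configurable free choice. Profiles ship as YAML data files, not code.

**Problem sizes.** The packaged cohorts use 70–110 paracortical vessels
per LN (1750–2750 pooled vessels per group), chosen so the four-cohort
acceptance run completes at desk scale; the parameter-recovery tolerance
is 3 binomial SE *of the vessel count actually generated*, so it scales
with this choice rather than being loosened by it. The test suite runs
further-scaled cohorts (3–6 LNs, 40–60 vessels/LN) under the same rule.

## What the synthetic data does and does not show

The generator reproduces the geometry and intensity structure that the
scoring rules act on, with controlled ground truth — so passing tests
demonstrate that the pipeline measures what it claims to measure
(diameters to ±1 px, coverages to ±0.03, exact class/zone/category
recovery at the rendered contrast). It does **not** emulate optics (PSF,
chromatic shifts), staining variability, autofluorescent red blood cells,
densely packed touching lymphocytes, irregular vessel cross-sections, or
3D sectioning effects. Real-image performance therefore depends on
upstream image quality in ways these tests cannot certify; the config
exposes every threshold so they can be recalibrated per staining batch.

## Degenerate inputs and tie-breaks

Empty tissue masks yield an undefined-burden flag, not a crash; an empty
CCL21 plane yields an empty paracortex and zero analyzable vessels; a
zero-width scoring ring yields NA scores. Truth matching is greedy
nearest-centroid with ties resolved to the lower vessel id. d = 10 µm
classifies as HIGH. Unreadable images in a dataset are logged and skipped;
an empty dataset is an error. All randomness flows from a single seed via
`numpy` `SeedSequence` spawning, and reruns are bit-identical.
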