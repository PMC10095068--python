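# Methods

`histomorph` quantifies stained mouse-skin sections along three readouts —
layer thickness, cellular infiltration, and mast-cell activation — and
tests treatment effects in a 2×2 factorial design. Because no imaging data
accompany the study design it targets, the package ships a synthetic
histology generator with exact ground truth; every quantitative guarantee
the test suite makes is a statement about recovery of that generator's
known parameters. This note records the models, the defaults, and the
choices made where the method left room.

## Fiber-breadth thickness morphometry

A skin layer isolated inside a rectangular ROI is an irregular horizontal
fiber with traced area TA (μm²) and perimeter PR (μm). Identifying it with
the rectangle of equal area and perimeter, the short side is

FB = ¼ · [ PR − √(PR² − 16·TA) ],

the smaller root of w + l = PR/2, w·l = TA. The discriminant PR² − 16·TA
is non-negative iff such a rectangle exists; compact regions (disks,
blobs) are flagged invalid and never silently clamped. A square sits
exactly on the validity boundary, where FB's sensitivity to PR diverges —
FB is a *fiber* statistic and is only accurate for elongated regions, so
ROIs default to a width of max(400 μm, 4 × expected thickness).

**Perimeter estimation.** FB error is dominated by PR error. Two standard
estimators fail here: weighted boundary-pixel counting overestimates
oblique boundaries by up to ~8%, and 4-direction Crofton-type estimators
(exact on average over orientations) read ~5% low on the axis-aligned
bands that layer ROIs produce, inflating FB by 6–8%. We instead measure
the marching-squares contour (computed on a one-pixel pad so regions
touching the ROI edge close), simplify it with Douglas–Peucker at 0.9 px
tolerance — staircase runs collapse onto straight segments while corners
survive — and add π per closed contour to offset the half-pixel contour
level out to the full-pixel area convention (offsetting a simple closed
curve by r adds 2πr). Measured error is ≤0.5% on digital rectangles at
orientations 0–80°, giving FB within 2% on fiber-like rectangles
(aspect ≥ 2) and within ~3% under rotation.

**Surveying.** ROIs are placed uniformly at random along the section
(seeded). The ROI's vertical extent is fitted to the layer's band over
the ROI's own columns (from ground truth for synthetic images; a
user-supplied band for real ones) plus a 5% margin, floored at 1.5 × the
expected thickness — wide ROIs must absorb boundary drift. Traces that
fill the whole ROI (no boundary captured) or return a negative
discriminant are dropped and counted, never raised mid-survey. Holes in
the traced band (unstained nuclei) are filled before measurement: FB
models the layer as a solid band.

## HSI thresholding and optical density

Stain-positive pixels are selected in the classic intensity-mean HSI
decomposition: I = (R+G+B)/3 (normalised), S = 1 − 3·min(R,G,B)/(R+G+B),
angular hue with H(achromatic) := 0. Hue windows may wrap through 360°;
a stain mask is the conjunction of hue, saturation and intensity windows.
Commercial packages do not document their HSI variant, so the formulas
are fixed here for reproducibility and the default windows are calibrated
against the synthetic palette, not against any real stain. Achromatic
pixels report hue 0 and fail any saturation window with a positive lower
bound.

Optical density is Beer–Lambert against a background reference:
OD = −log₁₀(I / I_bg), clamped to [0, 3] (the dynamic range of 8-bit
data), zero at or above background. I_bg defaults to the 95th percentile
of image intensity — robust to illumination, immune to a handful of
saturated pixels — and can be overridden by a constant. Absolute OD is in
package-defined units; only ratios and calibrated thresholds are
interpreted.

## Nucleus detection and infiltration counting

Hematoxylin-like nuclei are connected components of the nucleus stain
mask. Components larger than 1.5 × the area ceiling are treated as clumps
and split by watershed seeded at distance-transform maxima (minimum seed
separation = the radius of the smallest admissible nucleus); smaller
components pass unsplit, which keeps lobed single nuclei intact.
Candidates must satisfy morphometric windows — area 10–80 μm², major/minor
elongation ≤ 3, solidity ≥ 0.8 by default, all config-overridable; the
defaults were calibrated on the generator's nucleus shapes (ellipse
diameters 7–11 × 5–8 μm).

Counting uses circular ROIs of fixed 75 μm diameter. Membership is
centroid-in-closed-disk (boundary counts as inside). The hypodermal band
is tiled hexagonally with disjoint ROIs whose centres keep one radius
clear of the band edges; perivascular ROIs are centred on annotated
vessel lumens, and a vessel too close to the image edge for a full ROI is
dropped and logged. Whether the original protocol overlapped its ROIs is
unknowable; disjoint tiling is this package's policy.

## Mast-cell activation scoring

Mast cells are segmented from the methylene-blue-like stain mask; mask
fragments within a 10 μm linking radius merge into one cell (degranulated
cells shed granules around the soma; the grouping radius is a package
choice). Per cell: A = stained-pixel count × scale², IOD = Σ OD × scale²,
and the intensive ratio IOD/A = mean per-pixel OD. A compact resting cell
stacks overlapping granules, so its per-pixel density is high; dispersal
thins the deposit — hence **lower IOD/A ⇒ activated**. The direction is
an assumption exposed as a flag (`low_ratio_is_activated`).

The decision threshold is calibrated from labelled training cells by an
exhaustive sweep over candidate cuts minimising misclassification
(midpoint of class means when separable), and persisted for use on
unlabelled data. Densities per mm² divide by total imaged tissue area.

## Statistics

The experimental unit is the mouse: per-ROI and per-image values are
averaged within mouse before any group statistic, avoiding
pseudoreplication (figure legends in this literature often leave the unit
ambiguous; per-mouse is the conservative reading). Group summaries are
mean ± SEM (sd/√n; absent for n = 1).

The 2×2 antigen × resveratrol ANOVA uses an OLS fit with interaction and
type-II sums of squares (robust to mild imbalance). Pairwise comparisons
cover the four biologically meaningful contrasts {SV–OV, OV–OR, SV–SR,
SV–OR}, each a t-test on the pooled residual mean square with
Bonferroni adjustment (p_adj = min(1, 4·p)); α = 0.05. The family size is
a package decision — the protocol this mirrors does not enumerate its
family.

Relative expression follows 2^(−ΔΔCt): ΔCt = Ct_target − mean of the two
reference-gene Cts (arithmetic mean of Cts = geometric mean of linear
quantities at efficiency 2, which is fixed — no standard curves exist to
estimate it); ΔΔCt subtracts the control-group (SV) mean, making the
control geometric-mean fold change exactly 1. Duplicate wells are
averaged; a missing duplicate is used singly and flagged; a missing
reference gene is an error.

## The synthetic generator

**Skin sections.** Three wavy layers (epidermis/dermis/hypodermis) span
the image width. Per-layer thickness profiles are
t(x) = t̄ + A·sin(2πx/P + φ) + ε(x), with A = 8% of t̄, period
P = min(10·t̄, 1000 μm) (slopes stay gentle; whole cycles fit a section),
and ε a smooth Gaussian process (sd 1.5% of t̄, correlation
max(20, t̄/2) μm). The per-column profile is recorded analytically before
rasterisation — ground truth is exact, not re-measured. Nuclei are drawn
as filled ellipses, count ~ Poisson(density × tissue area), uniform over
the tissue band, with minimum centre separation (largest major axis +
1 μm) unless overlap is allowed; optional perivascular enrichment adds
Poisson extras within 75 μm of vessel centres. Vessels are rings in the
hypodermis. Background is near-white with RGB noise (sd 3/255) so
thresholding is non-trivially exercised. Defaults: 1 μm/px for sections,
0.25 μm/px for mast-cell fields — scale is the only quantity the
measurements consume, so magnification is not modelled.

**Mast-cell fields.** Each cell deposits granules (disks of radius
1.2 μm, OD 0.5 each, additive where they overlap) until the stained
footprint reaches granule_fraction × soma area — the fraction is met by
construction, and dense packing raises per-pixel OD, which is exactly the
physics the IOD/A readout exploits. Resting cells: fraction 0.9 inside
the soma (12–18 μm diameter). Activated cells: fraction 0.3, scattered up
to 6 μm beyond the soma. Cells are auto-placed at ≥50 μm separation;
failure to place is an error naming the constraint. OD converts to RGB
through per-channel attenuation weights (1.4, 1.1, 0.35), a blue-violet
stain.

**Cohorts.** The 2×2 design (SV, OV, SR, OR; SV the reference with unit
multipliers) applies per-group effect multipliers to baseline epidermal
thickness 30 μm, dermal 250 μm, nucleus density 300/mm², activated
fraction 0.2. Mouse-level variability is lognormal with mean 1 and CV
0.15 (strictly positive quantities; only SEM-level dispersion is reported
in this literature, so the CV is a package choice). The default effect
table mimics the study outcome: antigen doubles epidermal thickness and
infiltration and triples activation; resveratrol rescues everything
except dermal thickening (OV and OR both ×1.3). Per-image sub-seeds
derive from (seed, mouse, image); identical designs are bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real slides: staining variability and artefacts, uneven
illumination, out-of-focus blur, touching/overlapping nuclei in dense
infiltrates beyond what watershed splitting is exercised on, mast-cell
subtypes, and any texture within layers. Recovery results here bound the
*algorithmic* error of the pipeline, not its robustness to acquisition
artefacts.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make sampling error small
relative to the tolerances they test: thickness recovery uses 5 sections
× 3 ROIs per thickness; count recovery uses 1 mm² fields at 50–2000
nuclei/mm²; activation recovery uses 15 fields × 8 cells per target
fraction; statistical power and null calibration use 200 truth-level
cohort replicates at n = 6 mice/group (statistics operate on per-mouse
values, so truth-level draws are the correct substrate; image-level
recovery of those truths is established separately). The end-to-end
determinism check runs a deliberately small cohort (2 mice/group, 1
image/mouse) twice and compares reports byte-for-byte.

Ties and degenerate inputs: achromatic hue := 0; a centroid exactly on a
ROI circle counts as inside; an all-identical-values ANOVA reports F = 0,
p = 1; threshold calibration rejects single-class or identical-ratio
training sets; surveys that lose every ROI fail loudly with the layer
named.

## Known limitations

- FB is ill-conditioned near the discriminant-zero boundary; square-ish
  traces are unavoidable when a ROI is too small for its layer, and are
  dropped (and counted) rather than measured.
- The HSI windows, nucleus shape filters, and the IOD/A threshold are
  calibrated to the synthetic palette; real slides require re-calibration
  (the config accepts overrides for every window and threshold).
- Absolute IOD is meaningful only relative to the in-package OD scale.
- Vessel detection is out of scope: perivascular analysis takes vessel
  annotations as input (ground truth when synthetic, a CSV when real).
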