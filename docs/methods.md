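# Methods

## Scope and model

`scarchar` implements the quantitative analysis layer of a contrast-enhanced
(CE) short-axis CMR study of post-infarction ICD recipients: scar zone
sizing by the full-width-at-half-maximum (FWHM) rule, AHA 17-segment
ordinal scoring, LV volumetrics by disc summation, and the two-group
statistics used to compare primary- vs secondary-prevention cohorts.
Acquisition, contour drawing, and wall-motion grading are *inputs*
(contours as polygons, wall motion as expert labels); the package never
re-derives them from images.

## FWHM scar quantification

The reference intensity `SI_max` is the maximum over the intersection of
the hyperenhancement ROI with the myocardium mask. The intersection is
essential: the blood pool is typically brighter than scar, and a
generously drawn ROI must not let it set the reference (the phantom makes
this failure mode detectable by putting blood at 120 vs a core plateau of
100). Classification is per voxel: core at `SI ≥ 0.5·SI_max`, peri-infarct
at `0.35·SI_max ≤ SI < 0.5·SI_max`, both inclusive on the left exactly as
stated. Zone sizes are voxel counts over the total LV myocardial voxel
count of the stack — scar as % of LV myocardium; slices without a drawn
ROI still contribute myocardium to the denominator. `SI_max` is global
over the stack by default (one reference region per study); a per-slice
mode and a top-k robust mean exist behind flags and default off. No
morphological cleanup is applied by default; a connected-component
minimum-size filter is available for noisy data. Hypo-enhanced
microvascular obstruction is *not* reclassified into the core.

Because the thresholds are pure ratios to `SI_max`, zone labels are
exactly invariant under positive linear intensity rescaling (`SI → a·SI`,
`a > 0`). They are **not** invariant under an additive offset: a baseline
shift `+b` moves the 35%/50% cuts relative to the tissue plateaus. This is
an inherent property of half-maximum thresholding, worth knowing when
comparing scanners with different background offsets.

### Noise behavior

Two error mechanisms dominate on noisy images. First, the single-voxel
maximum is biased upward by roughly 2.5 noise standard deviations when
taken over a few hundred ROI voxels, which drags both cuts upward.
Second, and more fundamentally, the peri-infarct band is only 15% of
`SI_max` wide; once the voxel noise sd approaches that width, border-zone
voxels diffuse out of the band no matter how well `SI_max` is estimated.
With the default phantom (contrast `si_core − si_remote = 90`), the
measured mean absolute recovery error (`analysis/02_noise_sweep.py`, 50
replicates per level) is:

| SNR = contrast/sd | core MAE (pp) | peri MAE (pp) |
|---|---|---|
| 10 | 0.12 | 2.90 |
| 20 | 0.02 | 1.26 |
| 25 | 0.01 | 0.69 |
| 30 | 0.00 | 0.32 |

The core zone is robust down to SNR 10 (its 50% cut sits ~5 sd from both
plateaus); peri-infarct sizing needs SNR ≈ 25 before its mean error drops
under one percentage point. We verified numerically that neither a
region-mean nor a top-k reference estimator changes this conclusion at
SNR 10 — even an oracle handed the true plateau maximum leaves a ~1.3 pp
peri error there, because band-edge diffusion, not reference bias, is the
binding constraint.

## Synthetic phantom

Each phantom slice is an annulus (endo/epi circles) on a square pixel
grid; a scar is an angular wedge growing from the subendocardium to a
chosen transmurality, with the outer `border_rim_fraction` of its radial
thickness at an intermediate intensity (the heterogeneous rim) and the
rest at the core plateau. Labels are decided at voxel centers from polar
coordinates — no partial-volume subsampling — so an independent per-voxel
loop reproduces every label and the noiseless pipeline recovery is exact
by construction. Contours are dense polygons (720 vertices) of the same
circles; the rasterization convention (voxel center inside epicardium and
not inside endocardium) matches the truth convention.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| grid / spacing | 96 px, 1.5 mm | clinical in-plane resolution |
| slices / thickness | 8 × 10 mm | CE stack geometry |
| endo / epi radius | 20 / 30 mm | mid-sized post-infarct LV |
| wedge extent / transmurality | 90°, 0.6 | a sizable single-territory infarct |
| rim fraction | 0.3 | peri ≈ ⅓ of total scar, matching the core:peri ratios such cohorts report |
| si_remote | 10 | inversion time nulls viable myocardium, so remote muscle sits near the noise floor |
| si_border / si_core | 42 / 100 | rim in the middle of the 35–50% band; plateaus bracket both cuts |
| si_blood | 120 | blood brighter than scar, outside the myocardium mask |
| noise | Gaussian, sd 0 | additive; Rician (magnitude) optional |

What the phantom does **not** emulate: partial-volume mixing at zone
boundaries, cardiac-motion blur, coil-profile shading, inversion-recovery
signal curves, papillary muscles, or through-plane scar variation beyond
on/off per slice. Passing recovery tests therefore demonstrates the
correctness of the *computational* pipeline under a known signal model,
not the in-vivo accuracy of FWHM sizing, which those physical effects
degrade.

## AHA 17-segment assignment

Slices (ordered base → apex) are split into basal/mid/apical thirds by
count, remainder assigned basal-ward. Angles are measured at voxel centers
in image-plane mm coordinates, relative to the ray from the LV center to
the anterior RV-insertion landmark; increasing angle (counterclockwise in
the (x, y) frame) runs from the insertion into the anterior wall. Basal
and mid tiers use six 60° sectors ([1, 6, 5, 4, 3, 2] and [7, 12, 11, 10,
9, 8] counterclockwise from the insertion), the apical tier four 90°
sectors ([13, 16, 15, 14]). The chirality is stated because a flipped
convention relabels septal as lateral without any error signal; the
equivariance test (joint rotation of image and landmark) guards the
implementation, not the convention. The apex cap (17) is taken from
caller-identified slices where the cavity has closed; phantoms whose
cavity never closes simply have no segment 17, and it is carried as
unobserved (NaN) thereafter. Territories default to LAD {1,2,7,8,13,14,17},
RCA {3,4,9,10,15}, LCX {5,6,11,12,16}; the map is configuration (with an
`include_apex` switch) because institutional variants exist.

## Ordinal scores

Segmental scar percentage uses total scar (core + peri). The printed
integer score bins are realized as the half-open partition (0,25],
(25,50], (50,75], (75,100] with 0 ↦ 0 — the unique continuous partition
consistent with integer bin labels. Transmural extent counts observed
segments scoring ≥ 3. Regional scores are unweighted means of segment
scores over a territory's observed segments (a territory with none
observed yields NaN, flagged rather than raised, so tables carry the gap).
WMSI divides the sum of observed wall-motion grades by the number of
observed segments; unobserved segments are NaN throughout and never coded
as 0, since 0 means *normal motion*. The 0–4 wall-motion scale differs
from the 1–5 echocardiographic convention; it is implemented as 0–4.

## Volumetrics

Disc summation: every slice carrying a contour contributes polygon area ×
(thickness + gap); no partial-slice weighting at base or apex. Papillary
muscles count toward the cavity and are excluded from mass (the common
convention; the phantom has none). Myocardial density 1.05 g/ml,
configurable. BSA defaults to Mosteller √(h·w/3600) with DuBois as an
option; the two agree within 5% over the physiologic BMI range. Polygon
areas come from exact shoelace geometry (shapely), so volume is invariant
under in-plane rotation/translation and scales as s² under scaling —
properties the suite asserts.

## Cohort statistics

Two-sided p-values throughout. Student's t uses the classical
equal-variance form (Welch behind a flag); Mann–Whitney U uses the exact
null for small samples. The 2×2 tests are chi-square without Yates
correction by default and Fisher exact, whose two-sided p is the sum of
probabilities of all fixed-margin tables no more probable than the
observed one (conventions differ; this one is stated and checked against
full hypergeometric enumeration). Because published clinical tables
rarely state which test produced which p, the `auto` rule is documented
package policy: Shapiro–Wilk on both groups at α 0.05 chooses t vs
Mann–Whitney (and mean ± SD vs median (range) presentation); any expected
cell below 5 chooses Fisher over chi-square. Simulated null tables at the
study margins (95 patients, 12 events, 66/29 split) keep the auto-selected
test's type-I error at or below 0.065 at nominal 0.05. Named stratifiers
(`lvef_le_35`, `anterior`, `nonanterior`) reproduce the study's subgroup
analyses; an empty stratum yields a flagged row, not an exception. The
composite MACE flag is appropriate ICD therapy and/or death. Survival
modeling and multiplicity adjustment are out of scope.

## Numerical conventions and degenerate inputs

Contour coordinates are millimetres, origin at the image corner, 0-based
pixel-center convention: pixel (r, c) is tested at (c·col_spacing,
r·row_spacing). All boundary rules are half-open and identical between
the generator and the analyzer (myocardium `endo ≤ r < epi`, wedge
`−extent/2 ≤ Δθ < extent/2`, sectors by floor division), which is what
makes noiseless recovery a bit-exact identity rather than an approximate
one. Degenerate inputs fail loudly with specific exceptions: epi ≤ endo,
self-intersecting polygons, missing geometry sidecars, ROIs disjoint from
the myocardium, non-positive `SI_max`, zero-margin 2×2 tables, constant
identical samples under t, zero observed segments under WMSI. Simulation
sizes in the test and acceptance layers use a reduced phantom (48² px,
4 slices, 2 mm pixels) so that hundreds of full-pipeline replicates remain
cheap; the geometry is scaled, not simplified — every code path matches
the full-size phantom.

## Known limitations

* Peri-infarct sizing degrades quickly with noise (see table above);
  reported peri% from low-SNR data should be treated as noise-sensitive.
* FWHM thresholds are baseline-dependent (no additive-offset invariance).
* Segment tiering by slice-count thirds is one defensible convention among
  several; comparisons across packages should check it.
* The denominator for zone percentages is LV myocardial voxel count;
  area-, mass-, or volume-based denominators coincide only under uniform
  density and slice weighting.
* The phantom's blood pool sits strictly inside the endocardial contour;
  real trabeculation blurs that boundary.
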