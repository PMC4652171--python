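# Methods

`strokemap` implements a complete pipeline for flattening 3D
diffusion-weighted MRI (DWI) brain volumes into 2D maps by a closed-form
Mollweide-style geoprojection, and for computer-aided recognition of the
stroke-affected brain-artery territory from those maps, including cut-off
optimisation and cross-validated diagnostic-accuracy evaluation.  No
patient data ship with the package; every stage is exercised end-to-end on
synthetic brain phantoms whose statistical structure matches what the
method assumes.

## Intensity segmentation

All voxel intensities of a volume are pooled into an equal-width histogram
(default bin width 1 a.u., appropriate for data in the 0–400 a.u. regime).
Three landmarks are extracted from the smoothed counts (moving average,
window 5 bins; raw counts are too noisy for extremum detection):

* **background cut-off** — the intensity at the minimum of the dip between
  the two most *prominent* local maxima (the intense background peak and
  the broad healthy-brain peak).  Prominence rather than raw height ranks
  the peaks because intensity clipping at 0 piles probability mass into the
  first bins and can produce a tall but shallow bump there.  Ties take the
  lowest-intensity bin.
* **brain mode** — the location of the tallest smoothed maximum above the
  background cut-off.
* **stroke cut-off** — acute stroke is hyperintense on DWI and skews the
  brain peak to the right.  Assuming the healthy-brain values are symmetric
  about their mode, the stroke cut-off is the left minimum *reflected*
  across the mode: `stroke_cutoff = 2·brain_mode − left_minimum`.  The left
  minimum and the background cut-off coincide by construction here (both
  name the dip minimum), so the function takes the background cut-off as
  its reflection anchor.

The symmetry/Gaussianity assumption can be probed with a one-sample
Kolmogorov–Smirnov test against a Gaussian fitted to the sample
(`gaussianity_check`).  Because the parameters are estimated from the same
sample the test is conservative; a rejection is logged as a warning and
never blocks the pipeline — the check is advisory, used to justify
applicability, not as a gate.

## Geoprojection

Brain voxels (everything above the background cut-off) are projected
*radially* from a fixed anatomical centre onto an enclosing sphere: two
voxels on one ray share a direction (longitude λ from the anterior
direction, positive toward the brain's left; latitude θ positive toward
superior) and hence one map position.  The sphere radius defaults to the
largest centre-to-brain-voxel distance.  The sphere is flattened with the
closed-form transform

    x = 8·r·λ·cos θ / π        y = 2·r·sin θ

implemented exactly in this form.  Note this spans a 16r × 4r plane
(aspect 4:1), unlike the classical equal-area Mollweide projection, which
solves a transcendental auxiliary-angle equation and spans a 2:1 ellipse;
the classical variant is available behind `variant="canonical"` for
comparison but is not the default.

Plane coordinates are scaled linearly into the raster (default 1080 × 270,
preserving the 4:1 aspect) with nearest-pixel assignment; pixels that
receive no contributor are marked outside.  Where several voxels land in
one pixel the **maximum** intensity is kept, so hyperintense stroke signal
can never be hidden behind healthy-brain contributors; per-pixel
contributor counts (multiplicity) are retained.  At the default raster and
phantom resolution roughly 37 % of inside pixels receive more than one
voxel — the regime reported for the method on clinical data ("about 40 %").
A coarser raster (e.g. 720 × 180) at this volume resolution drives that
fraction above 70 %, which is why 1080 × 270 is the default.

Conventions: the left hemisphere renders on the left half of the map,
superior at the top; at the poles the longitude is canonicalised to 0.

## Healthy reference and stroke flagging

A per-pixel healthy diffusion-level reference (mean μ(p) and SD σ(p),
population divisor n) is built from projected maps of healthy hemispheres:
the affected half of each training map is replaced by the mirror of its
healthy half (λ → −λ is a column flip) before averaging.  Pixels covered
by fewer than half of the contributing maps (minimum 2) are left
undefined, so rim pixels with unstable SD estimates never participate in
area counts downstream.

A patient pixel is *stroke-indicating* when its value exceeds
μ(p) + k·σ(p) — one-sided, since DWI stroke is hyperintense (a two-sided
mode exists behind a flag).  The sigma level k (default 2) can be selected
by minimising the cohort-mean **SPB difference**: the relative mismatch
|p3D − p2D| / p3D between the stroke-per-brain proportion measured in the
3D volume (voxels above the stroke cut-off over voxels above the
background cut-off) and in the 2D map (flagged pixels over defined inside
pixels).  Relative rather than absolute difference is the default (an
absolute mode exists) because typical stroke burdens are a few percent of
the brain and an absolute difference would be insensitive there.  Ties
take the smaller k.

## Territory atlas and classifier

The territory atlas holds five binary map masks (ACA, supMCA, infMCA, PCA,
PICA; superior cerebellar artery territory is not modelled).  It is built
by merging — set union — the stroke-indicating masks of cases with a
distinct single-territory diagnosis and widespread lesions; contributing
case identifiers are recorded so atlas cases are excluded from evaluation
(an identifier guard refuses any overlap).

Each territory t is tested with two criteria, either sufficient:

1. **coverage**: |stroke ∩ t| / |t|  >  area_cutoff[t]
2. **bulk**:     |stroke ∩ t| / |stroke|  >  bulk_cutoff[t]

Strict inequalities are used, and a bulk cut-off of exactly 0 *disables*
criterion 2 for that territory: under either `>` or `≥` a literal 0 %
threshold degenerates (a single scattered pixel, or every territory, would
fire), contradicting the specificity the method attains; published
per-territory cut-off tables that contain zeros in the bulk columns are
therefore read as "criterion unused".  With zero stroke pixels all bulk
values are defined as 0 and every territory is negative.

## Diagnostic statistics and validation

Counting granularity is patient × territory (five outcomes per patient).
From pooled TP/FP/TN/FN counts: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), PPV, NPV, PLR = sens/(1−spec), NLR = (1−sens)/spec, Youden
index Y = sensitivity + specificity − 1.  At specificity 1 the PLR is
undefined; the default reports NaN, and a compatibility mode reports 0.0
(the convention some tabulations print for a fold without false
positives) — the cross-validation report uses that mode so aggregate rows
stay finite.

Cut-offs are tuned per territory by exhaustive grid search (default 0–100 %
in 5 % steps for both criteria) maximising the Youden index of the pooled
training decisions; counts are pooled over training patients rather than
averaged per patient, which is robust when a fold holds few positives.
Ties break toward the largest area cut-off, then the largest bulk cut-off —
the most conservative optimum.  A territory with no positive (or no
negative) training case has an undefined Youden index and falls back to the
grid maximum with a logged warning.

Outer cross-validation splits the cohort into seeded near-equal subgroups
(uniform shuffle, contiguous chunks; 91 cases in 10 folds give one group
of 10 and nine of 9).  Each round tunes cut-offs on the other folds —
held-out cases are never read during tuning, enforced by an identifier
audit — and evaluates on the held-out fold.  Aggregates are the mean and
*population* SD (divisor n) over fold statistics.  Independent validation
scores cut-offs tuned on the full training set against an
identifier-disjoint holdout.

The statsmodels-style surface: `TerritoryRecognitionModel(cases)` with
`.fit()` → results carrying the tuned cut-offs, training diagnostics, ROC
traces and a `summary()` table; `.cross_validate()` returns the full
validation report.

## Synthetic phantoms

`PhantomSpec` defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| grid | 96³ voxels, 2 mm isotropic | head-sized field of view at a tractable size |
| brain | axis-aligned ellipsoid, semi-axes 70/85/65 mm, ±5 % per-case jitter | gross head geometry; anatomy is irrelevant to the mathematics |
| background / brain / stroke levels | 20 / 180 / 300 a.u. | the three histogram regimes of exemplary clinical DWI |
| noise | additive Gaussian, SD 10 a.u. | the Gaussian-histogram assumption the segmentation relies on; a Rician magnitude option exists |
| partial-volume rim | 6 % shell, quadratic ramp brain→background | skull/CSF/partial-volume continuum that fills the histogram dip in real data; without it the dip minimum degenerates to the background tail and the reflected cut-off lands above the stroke level |
| lesion | single ellipsoidal blob, grown to `lesion_fraction` of brain volume, clipped to its territory wedge, always left-sided | compact single-territory infarcts; the healthy right hemisphere feeds the reference |
| lesion fraction | 0.05 median, log-normal across a cohort, clipped to [0.01, 0.6 × wedge capacity] | clinical stroke burden is a few percent and strongly right-skewed |

Territories are fixed longitude/latitude wedges in the projection's own
spherical frame (constants in `strokemap.territories`), bilateral,
pairwise disjoint, covering ≈ 89 % of the brain surface; ACA
anterior-superior, supMCA/infMCA lateral, PCA posterior, PICA the inferior
cap.  Atlas-building cases use widespread lesions (40–60 % of their
wedge's capacity).

What the phantoms do **not** emulate: realistic cortical folding and deep
grey/white contrast, partial-volume effects inside the brain, Rician noise
floors at low SNR (unless enabled), multi-territory or watershed infarcts,
and inter-subject registration error.  Phantom cohorts are cleaner than
clinical data in all these respects, so recovery results on phantoms are
an upper bound: the package's cross-validated sensitivity/specificity on
the default 60–91-case phantom cohorts exceed 0.90, above the ~0.81/0.87
regime attainable on clinical cohorts, as expected.  Passing phantom tests
demonstrates the correctness of the machinery, not clinical performance.

## Numerical choices and degenerate inputs

* Histogram smoothing pads with zero counts outside the range (a
  replicating border would triple a clipped-intensity spike at bin 0).
* All extremum ties take the lowest-intensity bin; cut-off grid ties take
  the most conservative pair; sigma-level ties take the smaller k.
* Reference SDs use divisor n; identical inputs give SD exactly 0.
* A unimodal histogram, an empty brain mask, a zero-variance KS sample, a
  position exactly at the projection centre, a territory with no atlas
  case, and contingency tables with a zero margin all raise typed errors
  rather than returning silent defaults.
* A voxel exactly at the projection centre has no direction; phantom grids
  avoid it by construction (even grid, half-voxel offset), and the wedge
  generator excludes zero-radius voxels.
* Lesion growth is deterministic: the target count of smallest normalised
  ellipsoidal distances from the seat point, ties included.

## Problem sizes

Default test and demonstration sizes — a 60-case cohort at 96³ voxels for
parameter recovery, 8–21 reduced-resolution (48³) phantoms for reference
and flagging properties, and the 125-case (14 atlas / 91 CV / 20 holdout)
study in the acceptance script — were chosen so the whole suite runs in
well under a minute per module on one CPU while keeping every cohort large
enough for the statistics to be meaningful.
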