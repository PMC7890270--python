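# Methods

## The phantom: a stated world

The synthetic animal is built from geometric primitives on an isotropic
voxel grid (default 0.2 mm; real scanners acquire at ~50 μm, but every
area and volume is computed from the voxel size, so resolution trades
runtime against partial-volume realism, not correctness):

- **Body**: ellipsoid, default 90 mm long with 14 × 11 mm semi-axes —
  roughly 29 cm³, i.e. a ~30 g mouse at typical composition.
- **Vertebral column**: a dorsal rod with 13 bead-shaped vertebrae along
  the central 80 % of the body. Bone voxels are the `bone_fraction`
  (default 5 %) of body voxels nearest the bead-modulated spine axis.
  Lumbar levels are counted caudally: L5 is the 4th and L4 the 5th
  vertebra from the caudal end; their slice indices are exported so no
  landmark detection is needed downstream.
- **Dorsal muscles**: paired elliptical prisms flanking the spine over the
  L4–L5 span.
- **Fat**: the `fat_fraction` (of soft-tissue volume) is realized *to the
  voxel* as a visceral ellipsoid at L4 plus a subcutaneous shell taken as
  the outermost unassigned voxels by normalized ellipsoid radius.
- **Liver** (ellipsoid with three cranio-caudal cylindrical vessels) and
  **spleen** (small left-lateral ellipsoid) sit inside the lean
  compartment. The spleen always has lipid fraction 0 — that is its role
  as internal density control.

**Attenuation.** Pure-tissue HU defaults are air −1000, fat −100, lean
+50, bone +800 (standard CT ranges; no primary values exist for the
scanner in question, so they are parameters, not facts). A tissue with
lipid fraction `f` attenuates at the linear mixture
`(1−f)·lean + f·fat`; an optional *marbled* mode instead sets discrete
voxels to pure fat with probability `f`, to stress partial-volume
behaviour. Gaussian noise (default SD 15 HU) is added from a seeded
generator; identical (spec, seed) pairs are bit-identical. Grey values are
the inverse image of HU under the affine calibration (default slope 1,
intercept −1000, i.e. offset-HU storage).

**Ground truth.** `truth.mass` is computed from the final masks as
`0.95·V_fat + 1.05·V_lean + 1.92·V_bone`, the same compartment densities
the weight estimator uses — so weight recovery tests the segmentation, not
the arithmetic.

**Cohorts.** `generate_cohort` assigns animals round-robin to groups of a
`CohortDesign`. The default four-group design (control, NAFL, early NASH,
fibrosing NASH) moves muscle lipid fraction from 2 % to 30 % and liver
lipid from 2 % to 32 % along the disease spectrum, with insulinaemia and
glycaemia rising and grip strength collapsing only in the fibrosing group
— the qualitative structure of the longitudinal mouse experiments this
emulates. Steatosis grade is derived from the drawn liver lipid fraction
(thresholds 5/15/28 %), inflammation and ballooning from group-level
categorical probabilities, so the histological label is consistent with
the imaging ground truth. These distributions are the stated world; they
are not tuned to any test outcome.

## Densitometry

- **Tissue classification** uses half-open HU windows, defaults
  fat [−300, −30), lean [−30, 300), bone ≥ 300. Published grey-value
  windows for a particular scanner (e.g. lean 30–97) are scanner-native;
  the config accepts thresholds in either unit with an explicit
  calibration, converted on load.
- **Slice metrics**: area = windowed in-ROI pixel count × pixel area;
  density = mean HU of those pixels. L4 and L5 are averaged in HU *first*,
  then normalized by the single per-animal spleen value. An ROI emptied by
  the window flags the record instead of reporting a silent zero.
- **Virtual biopsy**: an axis-aligned cylinder (height = 2 × radius),
  target volume 1.3 cm³ auto-scaled to ≤ 25 % of liver volume. Placement
  is deterministic: FFT convolution finds all centres whose cylinder lies
  entirely in vessel-free liver; among them the centre with maximal
  Euclidean distance to the nearest vessel wins (lexicographic
  tie-break); if nothing fits, the volume shrinks by 20 % steps down to
  5 % of target before raising a placement error.
- **Spleen normalization** works on offset HU (`HU + 1000`, air = 0), so
  ratios are positive, unitless and invariant under affine recalibration —
  the reason to normalize by an internal control at all. With the default
  tissue values, muscle ratios span ≈ 0.86 (pure fat) to ≈ 1.0 (lean);
  an observed 0.4–1.0 span on a real scanner implies a different effective
  scale, which the `offset` parameter absorbs.

## Diagnostics

Positive class is NASH and the marker is *lower-is-positive* (density
below cutoff ⇒ NASH); scores are negated internally. AUROC is trapezoidal
over unique thresholds, which equals the Mann–Whitney statistic with ½
credit for ties (cross-checked against brute-force pair counting and
scikit-learn). The Youden-optimal cutoff is reported as the midpoint
between the adjacent observed scores straddling the optimum (reproducible
and invariant under monotone transforms of the score); ties in J go to
the higher sensitivity. Sensitivity/specificity carry exact
Clopper–Pearson 95 % intervals (beta-quantile inversion). Density strata
default to low [0.4, 0.6), mild [0.6, 0.8), high [0.8, 1.0]; empty bins
report missing, out-of-range values go to a logged bucket. The logistic
adjustment (muscle density, HOMA-IR, visceral fat area) is a
maximum-likelihood fit with Wald p-values — matching standard SPSS-style
output — and raises an explicit error on separation or non-convergence
rather than returning runaway coefficients. No multiplicity correction is
applied within the model. A percentile-bootstrap AUROC CI is provided as
a clearly labelled convenience; no particular reference method is implied.

## Physiology

HOMA-IR = glycaemia (mmol/L) × insulinaemia (mU/L) / 22.5. Grip strength
is the mean of the two highest absolute-force values with trials from the
initial session and the retest *pooled* — the summary is reported once
per test day, and pooling is the reproducible reading of that convention.
The SAF label rule is exhaustively verified over all 48 admissible score
triples.

## What a green test establishes — and what it does not

The phantom validates *measurement logic*: windowing, area/volume
bookkeeping, averaging order, normalization, placement constraints,
statistical machinery. Its tissues are homogeneous primitives with
Gaussian noise; it has no reconstruction physics (beam hardening, rings,
scatter), no organ-shape realism, no motion, and lipid mixing is exactly
linear by construction. Correlations measured on phantom cohorts (e.g.
true mass vs CT weight r ≈ 1.0) are therefore *upper bounds* of the
corresponding animal-study values (r = 0.99, r = −0.83), not
reproductions of them; the real-cohort AUROC (0.96), cutoff (0.805) and
likelihood ratio (37) require the original animals and are replaced here
by property-based substitutes (perfect-ranking limits, invariances,
coverage and parameter-recovery simulations).

## Numerical choices

- Fat/bone voxel selection uses exact-count `argpartition`, so requested
  fractions are hit to one voxel and equality tests are meaningful.
- Volumes are float32; HU means are computed in float64 by numpy
  reduction. Closed-form equality tests use 1e-4 HU tolerance for float32
  rounding.
- The noise generator is numpy's seeded PCG64 — platform-stable, so
  bit-identical volumes across machines.
- Degenerate inputs fail loudly: empty masks, single-class labels,
  constant vectors, overlapping windows, non-positive spleen densities
  and unfittable anatomy all raise typed errors.

## Suite scaling

Tests run on miniature phantoms (32–45 mm bodies at 0.3–0.4 mm voxels);
`scripts/acceptance.py` runs the same computations at full default
resolution (≈ 11–20 M voxels per animal, ~1 minute for both targets).
Since all metrics derive from the voxel size, the reduction changes
runtime only.
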