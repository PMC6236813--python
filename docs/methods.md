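# Methods

## Problem and model

In an MRI-only prostate radiotherapy workflow the planning CT is replaced
by a synthetic CT (sCT) computed from MRI. The implanted gold fiducial
markers (three cylinders, 5.0 mm long, 1.0 mm diameter, implanted 2-3 cm
apart) must then be identified in T2-weighted MRI, where calcifications and
bleeds produce indistinguishable signal voids. `fidqa` implements an
independent confirmation of that identification: the C-arm kV radiograph
(CkV) acquired at implantation shows the true marker positions; if the
marker constellation identified in MRI (rendered into an
anterior-posterior DRR of the sCT) rigidly matches the constellation in the
CkV image, the identification is confirmed.

The pipeline, per patient:

1. **Presentation.** The CkV image is acquired posterior-anterior and
   presented anterior-posterior by left-right mirroring; the reader
   reproduces this and records the C-arm angle from the DICOM header,
   warning when it exceeds a tolerance (default 2 deg) since a tilted
   projection distorts the marker constellation.
2. **Anatomic scaling.** The CkV DICOM carries no pixel spacing. One
   horizontal bony-landmark distance (over the pubic symphysis) is measured
   in both images; the scale factor is `f = d_ckv_px / d_drr_px` and the CkV
   raster is resampled by `1/f` onto the DRR grid (bicubic spline, Gaussian
   anti-alias prefilter of width `(f-1)/2` px when downscaling, anchored at
   pixel (0,0) so a feature at pixel `p` lands exactly at `p/f`). The
   direction of the factor is a package convention: C-arm detectors sample
   the (magnified) anatomy several times finer than a ~0.4 mm DRR grid, so
   `f` is ~3.5-4.4 and the CkV is shrunk.
3. **Detection.** A rectangular ROI around the marker cluster is applied to
   both images (for the CkV after a translational pre-alignment from the
   landmark midpoints, standing in for the manual overlay a user would do).
   The DRR is binarised at a fixed threshold (default: halfway between ROI
   minimum and maximum -- the burned-in markers are the brightest objects by
   construction); the CkV ROI is normalised to [0,1], inverted and
   binarised with Otsu's threshold. Components are labelled with
   8-connected neighbourhoods, filtered by pixel-area bounds derived from
   the physical marker sizes, and reduced to unweighted binary centroids,
   reported sub-pixel and in mm.
4. **Registration.** The two three-point clouds are coupled by exhaustive
   search over all pairings after centroid alignment, then a proper rigid
   transform (rotation + translation, det = +1, no scale or reflection) is
   fitted in closed form (Kabsch/Procrustes via SVD) and applied to the CkV
   cloud. A full ICP loop (nearest-neighbour coupling alternated with the
   closed-form fit, objective non-increasing, tolerance 1e-9 mm^2, at most
   50 iterations) is available for unlabelled clouds; with fixed
   correspondences it reduces to the closed form after one iteration, which
   is the default path for three labelled markers.
5. **Report and decision.** Per marker: dX = |left-right|, dY =
   |inferior-superior|, dTotal = Euclidean distance, plus mean/SD/median/
   min/max summaries. A marker with dTotal strictly greater than 5 mm is
   flagged and the narrative directs the user to re-evaluate the MRI
   identification near it. The 5 mm default is the clinical action level
   derived from mean + 2 SD of observed displacements (1.7 + 2 x 1.4 =
   4.5 mm, rounded up); a displacement of exactly 5 mm passes.

Cohorts (e.g. an sCT-based workflow vs a CT-based one, whose displacements
measure pure marker migration) are compared with a two-sided independent
Mann-Whitney U test at a 5% significance level.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `qa_threshold_mm` | 5.0 | mm | action level, strict inequality |
| `angle_tolerance_deg` | 2.0 | deg | C-arm angle warning threshold |
| `size_bounds` | from marker sizes | px | component-area discrimination |
| `drr_threshold` | ROI mid-level | intensity | fixed DRR binarisation |
| `expected_n` | 3 | - | markers per patient |
| ICP `tol`, `max_iter` | 1e-9, 50 | mm^2, - | converges in <= 2 iterations here |

Detection size bounds default to `[A_cyl/3, 3*A_disc]` where `A_cyl` is the
projected 5 x 1 mm cylinder area and `A_disc` the area of the 4 mm round
burned-in marker, both in pixels at the DRR spacing.

## Statistical details

**Mann-Whitney U.** Midranks handle ties. The exact two-sided p-value
enumerates all `C(n+m, n)` assignments of the pooled ranks and counts
assignments whose U is at least as far from the null mean `nm/2` as
observed (the null distribution is symmetric, so this matches
double-and-cap in the tie-free case, verified against `scipy`). Exact mode
is automatic when `min(n, m) <= 8` *and* the enumeration stays below 2e5
assignments; otherwise the tie- and continuity-corrected normal
approximation is used and recorded in the result's `method` field.

**Pooling.** Cohort comparisons pool either every per-marker dTotal
(`markers`) or per-patient means (`patients`). The three markers of one
patient share a single rigid fit and are negatively correlated; simulation
shows the per-marker pooling inflates the type-I rate of the test (about
15% at nominal 5% under the default phantom conditions), while per-patient
pooling is correctly calibrated (5.3% over 1000 replicates). Calibration
claims in the test-suite therefore use `patients`; both modes are exposed.

**Migration model and calibration.** Migration vectors are i.i.d. isotropic
Gaussian per component with SD `sigma`; magnitudes are Rayleigh with mean
`sigma*sqrt(pi/2)` (`sigma_for_true_mean` inverts this). The rigid fit of
`n` corresponded points estimates 3 parameters from `2n` perturbed
coordinates, so for small i.i.d. perturbations `E[RSS] = (2n-3) sigma^2`:
residuals shrink by `sqrt((2n-3)/(2n))` in the RMS sense (`1/sqrt(2)` for
n = 3). `sigma_for_measured_mean` therefore inflates a target
*post-registration* mean by `sqrt(2n/(2n-3))` before the Rayleigh
inversion. The residuals are not exactly isotropic per marker, so the
calibration is approximate; simulation over random implant geometries puts
the residual bias near -3%, well inside the statistical tolerance of every
check that uses it. Two physical blind spots of the rigid model are
reproduced and tested rather than hidden: a displacement common to all
markers is indistinguishable from organ motion and registered away, and a
single migrating marker is underestimated because the fit spreads its
displacement over the cloud (ratio depends on the migration direction
relative to the constellation: radial displacements lose only the
translational 1/n share, tangential ones also feed the rotation).

## The synthetic phantom

The generator emulates the study conditions end to end: a 512 x 512 DRR at
0.4 mm/px (the in-plane sampling of the marker-bearing sCT images that
clinical DRRs inherit), markers as bright 4 mm discs the way a planning
system burns identified positions into the sCT, over a smooth mid-intensity
backdrop with two dark vertical bars standing in for the pubic-bone /
obturator-foramen interfaces; and a 1280 x 1280 CkV of the same scene
magnified by `f` (default 4.0; patient sampling uses U(3.5, 4.4)), markers
as dark 5 x 1 mm vertical rectangles, per-marker migration, a
depth-dependent lateral shift `depth * tan(angle)` modelling C-arm angle
error (depths are a free parameter, default spread +/-10 mm, since no
clinical depth distribution is available), additive Gaussian noise (default
SD 0.02 of the unit intensity range), an unknown frame translation (default
U(-5, 5) mm per axis) and optional rotation, stored PA (mirrored) without
pixel spacing. Shapes are rendered with exact or 5x5-supersampled sub-pixel
coverage so the recorded ground-truth centres are exact. Optional
calcification-mimic distractors render with marker-like polarity but an
area outside the size bounds (default 10 mm discs); a "confusable" mode
instead displaces one *DRR* marker radially by 10 mm, emulating a
calcification mistaken for the marker during MRI identification.

What the phantom does **not** emulate: real pelvic anatomy and bone
texture, scatter/beam-hardening and detector physics, overlapping markers
(excluded clinically; a lateral view would resolve them), out-of-plane
rotation of the prostate, and operator variability in landmark picking
(tests inject sub-pixel jitter explicitly instead). Passing tests therefore
demonstrate the correctness and calibration of the algorithmic pipeline
under controlled geometry, not detection robustness on clinical image
quality.

## Numerical choices

- **Otsu** is computed on the exact per-level histogram for integer-valued
  samples (making it identical to exhaustive between-class-variance search)
  and on a 256-bin histogram otherwise; ties break toward the lowest
  threshold; constant samples raise a degenerate-histogram error.
- **Connectivity**: "8-connected" is interpreted as the neighbourhood rule
  of the labelling; minimum object size is governed separately by the area
  bounds (an alternative reading -- minimum component size 8 px -- is
  available by setting `min_area=8`).
- **Centroids** are unweighted binary centroids: deterministic under any
  monotone intensity normalisation.
- **Rigid fit** uses SVD with the determinant correction (reflections
  refused); coincident or < 2 points raise an underdetermined error.
- **Resampling** maps output pixel `o` to input `f*o` exactly (no centre
  offset), so ground-truth coordinates transform by pure division; output
  rasters above a configurable maximum (default 8192 px) are refused.
- Boundary rule of the QA decision is strict (`>`), so exactly 5.0 mm
  passes. Summaries use the n-1 SD; a single-value sample reports SD (and
  mean + 2 SD) as NaN rather than 0.

## Validation problem sizes

The test-suite and acceptance script validate with: 100 noise-free and 100
noisy (SD 0.05) phantom patients for detection accuracy (bounds 0.5 px and
1 px); magnifications {2.0, 3.5, 4.4} for scale recovery within 1%; 1000
random rigid transforms recovered to < 1e-9 mm; full image pipelines over
31- and 16-patient cohorts with migration calibrated to a 1.2 mm measured
mean; and 1000 geometry-level replicates for the 5% type-I calibration of
the cohort comparison (image rendering omitted there; the rigid-fit
residual distribution is what the test exercises).

## Limitations

A single AP projection cannot verify marker depth; 3-D confirmation would
need a lateral view. The rigid 2-D model cannot separate common-mode
migration from prostate motion and underestimates single-marker migration.
The anatomic scale factor assumes the bony landmark and the markers lie at
comparable magnification; a radiopaque ruler would remove that assumption.
Exact Mann-Whitney enumeration is limited to small samples by design.
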