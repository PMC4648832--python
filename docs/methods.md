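# Methods

## Coordinate conventions

World coordinates are right-handed and in millimetres throughout. The `z`
axis is the specimen cutting axis, perpendicular to the nominal histology
planes; candidate ex vivo CT planes are `z = z0 + k·Δz` with Δz = 1.0 mm by
default (typical ex vivo CT slice spacing). Continuous `z` is the canonical
representation; slice indices are derived. Rigid transforms are stored as a
proper rotation matrix plus translation and serialized as 4×4 homogeneous
row-major matrices. Histology pixel coordinates (µm, image row increasing
downward) are converted at the I/O boundary to mm with y increasing upward;
nothing downstream knows about pixels. These axis conventions are package
choices — the procedure itself is convention-agnostic.

## Rigid point registration

Both the 3-D landmark registration and the 2-D in-plane fit solve the
orthogonal Procrustes problem without scaling in closed form: subtract
centroids, SVD (3-D) or arctangent (2-D) of the cross-covariance, correct
the determinant sign to exclude reflections. This is the exact global
optimum of the least-squares problem; there is no iterative tolerance. All
landmarks carry equal weight, and correspondence comes from labels (the
emulated workflow identifies landmarks manually).

Three pairs are the enforced minimum in both dimensions — in 2-D two pairs
would determine a proper rigid motion, but a three-marker minimum reflects
how the in-plane fits are actually used (the residual of a two-point fit
carries almost no information). Near-collinear source sets (second
principal extent ≤ 1e-6 mm) are rejected as degenerate rather than
silently returning an arbitrary rotation.

A 2-D fit can optionally consider the mirrored solution
(`allow_reflection`), because a histology section can be mounted on the
slide face-down; the better of the proper and reflected fits is returned
with a flag. Reflection is never chosen silently.

## Slice-correspondence search

For a fixed histology slice, `rms_curve` scans candidate planes: at each
`z` the line fiducials are intersected with the plane, matched to the
slice's marker pattern by label, and the residual RMS of the least-squares
2-D rigid fit is recorded. Planes sharing fewer than three labels with the
slice are dropped. Anatomical landmarks may join the search as zero-extent
point fiducials that participate only within ±0.5 mm (half a plane
spacing) of their own height — they sharpen the dip near the true plane
and drop out elsewhere, mimicking how a landmark is visible on only one or
two consecutive CT slices.

The dip is localized by fitting `rms(z) ≈ a − b·exp(−(z−μ)²/c²)` with
bounded nonlinear least squares (scipy `least_squares`, trust-region
reflective). Initialization: `a` at the curve maximum, `b` at the observed
depth, `μ` at the discrete argmin, `c` at half the fitted z-range; bounds
keep `b ≥ 1e-6` and `c ≥ Δz/2`. The fitted minimum value `a − b` can
undershoot zero on noisy curves and is clamped to 0 when reported as the
residual estimate. A fit whose depth is pinned at its lower bound (flat
curve) is flagged non-converged and the match falls back to the discrete
argmin, with ties broken toward the smallest z and a warning.

**Local fitting window.** `find_corresponding_plane` restricts the dip fit
to ±4 grid steps around the discrete argmin (the whole curve when it is
shorter). The Gaussian is a model of the dip only: away from the matching
plane the residual grows roughly linearly with plane offset, so fitting
the full, asymmetrically truncated V-shaped curve biases μ by up to a
plane spacing; the local fit removes that model-mismatch bias while still
using enough points (9) to constrain 4 parameters. The window is counted
in grid steps so its physical width scales with the plane spacing.

The center parameter μ is part of the model by construction — a dip with
its minimum pinned at `z = 0` could never track an arbitrary cutting
plane.

## Error model

* **PET → in vivo CT**: a constant, configurable `pet_ct_error_mm`
  (default 1.0 mm, a typical hardware alignment accuracy of a combined
  PET-CT scanner). It is a property of the scanner, not of a specimen, so
  it enters the overall quadrature once rather than per sample.
* **in vivo CT → ex vivo CT**: leave-one-out over the landmark pairs. Each
  landmark is held out, the registration refitted on the rest, and the
  held-out source's post-transform distance to its target recorded; the
  mean over landmarks is the step error. Unlike the residual RMS of the
  full fit (FRE), which is optimistic because every point pulled the fit
  toward itself, the held-out distance approximates target registration
  error (TRE). On synthetic data with isotropic per-coordinate noise σ the
  mean LOO error brackets σ√3 with a modest leverage inflation, and it
  exceeds the same-data FRE on average.
* **ex vivo CT → histology**: the residual in-plane RMS at the matched
  plane. The fiducials are too few and too extended for a leave-one-out
  here; note this term does not detect a wrongly matched plane.

Independent components combine as the square root of the sum of squares.
Column summaries use the sample standard deviation (n−1): recomputing the
bundled study table's printed SD row from its printed column cells matches
at two decimals with the n−1 denominator (0.66 and 0.63) and not with the
population denominator (0.64 and 0.61).

`build_report` has two modes. **reproduce** computes on inputs as printed
(two decimals) and rounds derived values the same way (totals to 2 dp,
overall to 1 dp) — the only way the published table's cells are exactly
recoverable, since they were derived from rounded entries. **research**
keeps full precision. Two caveats on the bundled table: its printed column
means (2.66 and 0.86) and the ex-vivo→histology SD (0.41) were evidently
computed from unrounded source values and differ in the last digit from
what the printed cells give (2.67, 0.87, 0.39); and the spread quoted
alongside the overall 3.0 mm figure is not derivable from the table by
any per-sample or column-wise quadrature, so research mode reports the
per-sample quadrature SD in a note instead of asserting it.

## Synthetic phantoms

`histofuse.phantom` generates the geometry the pipeline was designed for,
with defaults matching the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_spines` | 4 | implanted line fiducials |
| `spine_length_range` | 20–30 mm | segment lengths |
| `target_pairwise_angle` | 30° | mutual spine angles (±10° accepted) |
| `n_landmarks` | 13 | anatomical landmarks |
| `specimen_extent` | 60×60×50 mm | bounding box |
| `ct_plane_spacing` | 1.0 mm | candidate plane grid |
| `landmark_noise_sd` | 0 | 3-D localization noise, per coordinate |
| `inplane_noise_sd` | 0 | 2-D marker noise, per coordinate |
| `slice_tilt_max` | 2° | max cut-plane tilt |

Spine directions sit on a cone of half-angle target/2 about the cutting
axis at evenly spread, jittered azimuths; geometry is rejection-sampled
(≤1000 tries) until all pairwise angles are within ±10° of the target and
all segments lie in the box. A `target_pairwise_angle` of 0 produces an
exactly parallel bundle — the degenerate control. The ground-truth
in vivo→ex vivo motion is small (rotation ≤ 20°, translation ≤ 20 mm),
reflecting careful specimen positioning for the ex vivo scan. Cutting a
slice tilts the plane about a random in-plane axis through the specimen
centre (tilt ~ U(0, max)), expresses the spine intersections in the tilted
plane's own 2-D frame, applies a random mounting pose (rotation and ≤10 mm
translation), and adds in-plane noise. Bandsaw slice thicknesses are drawn
from a truncated-at-zero normal with mean 5.28 and SD 2.42 mm (the
distributional form is a modeling choice; only the two moments are known).

All randomness flows from one master seed through named substreams
(geometry / landmark noise / slice pose / thickness), so each stage is
independently reproducible.

**What the phantoms do not emulate:** voxelized image content and
intensity-based registration, tissue deformation, fixation shrinkage
(limited to a few percent in cartilage-rich specimens, and absorbed into
landmark noise here), marker detection errors beyond isotropic Gaussian
noise, and non-axial CT resampling. Passing phantom tests therefore
demonstrates the geometric estimators and their noise response, not
robustness to deformation or segmentation failure.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use 200 phantom replicates for slice recovery (angled
and parallel), 200 replicates per noise level for the leave-one-out
behaviour, and 500 replicates for dip-centre recovery — sizes at which the
asserted proportions are stable across seeds to a couple of percentage
points. The whole suite runs in well under a minute.

## Known limitations

* Only axial candidate planes are searched; a strongly tilted cut is
  matched to the nearest axial plane, contributing a bias of order
  (pattern radius)·tan(tilt).
* The residual-RMS error estimate for the histology step is blind to a
  wrongly matched plane (a local minimum of the curve at the wrong z).
* No outlier handling in the point fits: a mislabeled landmark corrupts
  the transform rather than being down-weighted.
* Line fiducials are idealized as zero-diameter segments; the ~0.5 mm
  physical diameter of real spines adds localization noise that must be
  captured in the noise SDs.
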