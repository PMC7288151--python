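# Methods

## Triangulation model

The instrument images the intersection of a thin laser sheet with an
opaque surface. In the triangulation plane, a height offset Δz of the
surface relative to the reference plane displaces the imaged spot in the
camera plane by Δx. The exact oblique relation implemented in
`geometry.delta_z_general` follows from similar triangles on the chief ray
through the lens centre plus the thin-lens equation 1/l + 1/d = 1/f:

Δz = Δx sinθ cosα (l−f) / [ f sin(α+β) ± Δx sin(α+β+θ)(1−f/l) ],

`+` for a convexity (surface above the reference plane), `−` for a
concavity. The sign branch is an explicit parameter, never inferred from
data. A unit test validates the formula against an independent numerical
ray-trace oracle (thin-lens imaging of the displaced spot, chief ray
intersected with the tilted camera plane) over 100 random geometries.

In the orthogonal configuration α = β = 45°, θ = 90° the Δx term in the
denominator carries sin(180°) = 0 and the relation reduces *exactly* to

Δz = cos45° · (l−f)/f · Δx = √2 (l−f)/(2f) · Δx.

Note the √2: a height change Δz moves the illuminated spot by Δz/cos45°
along the incident ray, all of which is transverse to the viewing axis
when α+β = 90°. `delta_z_linear` implements this slope, and the test
suite asserts that the general mapping and the linear law agree to 1e−12
relative over a grid of displacements and lens parameters — an identity
that pins both implementations to the same geometry.

Angles are accepted in degrees, f and l in millimetres, all other lengths
in micrometres; everything is converted to micrometres internally to avoid
silent unit mixing. f and l have no defaults — they are instrument
configuration — and the linear slope can alternatively be supplied
directly as a single calibrated scale factor
(`CalibrationModel.from_linear_slope`).

## Contour extraction

Frames are smoothed with a self-guided guided filter (box-filter
formulation; local linear model q = aI + b in a (2r+1)² window),
implemented in-package on `scipy.ndimage.uniform_filter`. Defaults:
radius 4 px and regularization (1% of the dynamic range)², small enough
to preserve a 10–20 px wide stripe while flattening speckle grain. The
filter maps constant images to themselves and its output is clipped to
the input range.

The stripe position of each row is the column of the maximum intensity;
when several columns tie (common at 8-bit depth), the position is the
arithmetic mean of all tied columns. Rows whose maximum falls below a
threshold (default 5% of the dynamic range) are marked invalid — the
handling of signal-free rows is this package's choice. Column positions
are 1-based in all public interfaces. An optional intensity-weighted
centroid would refine this to sub-pixel precision but is deliberately not
the default: the integer-argmax rule is the instrument's documented
behaviour, and all downstream statistics are designed around it.

Offsets are signed: positive = rightward shift = convexity. The FWHM
estimator locates the half level at baseline + (peak − baseline)/2 with
the baseline taken as the profile minimum, and interpolates the two
crossings linearly between samples.

## Calibration

A calibration stack images a flat surface raised in `step_um` increments
(defaults 301 frames × 2.5 μm, the instrument protocol). Each frame is
reduced to one column position — the median over valid rows by default
(mean by flag); the median is robust to residual speckle outliers, and
the instrument protocol does not prescribe a summary. Offsets are taken
against the first frame. The fit is an ordinary least-squares polynomial
(default degree 5; degree 1 supported for the purely linear regime),
computed in a rescaled domain for conditioning and converted back to
ordinary coefficients; R² = 1 − SS_res/SS_tot. If the fitted polynomial
is not strictly increasing over the data range a warning is recorded on
the model and inversion is restricted to the largest increasing
subinterval from the bottom of the range.

Inversion uses bracketed Brent root-finding (xtol 1e−9 μm) rather than
series reversion — robust for any monotone polynomial. The inverse is
only defined on the calibrated range; callers may pass an
`extrapolation_pad_um` to extend the bracket slightly beyond it (below).

The z-resolution bound is `step × steps_to_guaranteed_shift`: speckle can
leave the stripe stationary over single 2.5 μm steps, but a ≥1 px shift
is guaranteed within 4 steps, bounding the height resolution at 10 μm.

## Reconstruction and metrology

Frame k of a scan contributes points (x = k·scan_step, y = row·lateral
scale, z = calibration⁻¹(offset)) for every valid row; scattered points
are interpolated onto a regular grid with linear barycentric
interpolation (`scipy.interpolate.griddata`), exact on planes, with cells
outside the convex hull masked. The scan origin is frame 0 at x = 0 and
the lateral scale (μm per row) is required configuration — it mixes
objective magnification and pixel pitch and cannot be derived from the
triangulation parameters alone.

**Boundary censoring pad.** Peak extraction quantizes the stripe position
at one pixel and speckle dithers it by a few more. For surfaces at the
very bottom (or top) of the calibrated range, a strict inversion domain
would drop only the rows whose offsets fall outside the range — a
one-sided censoring that measurably biased a zero-height plateau upward
(by ~1.5–3.5 μm at speckle contrast 0.15). `stack_to_pointcloud`
therefore pads the inversion bracket by the height equivalent of 4 px of
offset (4/|c1|) on both sides by default, covering the observed
offset-noise tail symmetrically. Rows outside even the padded range are
dropped.

Step heights are summary(upper plateau) − summary(lower plateau) over
physical rectangles of the heightmap; the default summary is the median.

**Groove depth.** Gate-line grooves run along the scan axis, so every
frame images the same indenture. The indenture is located once, on the
frame-averaged offset profile within a user-given row window (the
extremal row); the groove floor is the set of rows whose averaged offset
lies beyond half of the extremal value. Per frame the indenture offset is
the median over the floor rows, and the per-frame offsets are averaged
across the scan, rounded to the nearest integer pixel (mirroring the
instrument's reported integer offsets; a no-rounding flag exists), and
converted to depth via the calibration inverse of the magnitude. A raw
per-frame extremum — the obvious alternative — rides the most extreme
speckle excursion among the window's rows and overestimated a 70 μm
groove by ~15% in simulation; the floor median removes that
extreme-value bias while keeping the protocol-shaped "per-frame offset, then
average over frames" structure.

**Curvature.** A selected contour arc is mapped to physical (y, z)
points and fitted with a circle in two stages: an algebraic (Kåsa)
least-squares fit — linear, deterministic, used as the starting point —
refined by a geometric fit minimizing Σ(dᵢ − R)² with
`scipy.optimize.least_squares`. Whether the instrument's own fit was
algebraic or geometric is unknown; both are exposed, geometric is the
default since it is the unbiased estimator for noisy arcs. Collinear
input raises (infinite radius). Arc selection is manual (a row range), as
it is on the instrument. Curvature is 1/R, reported per millimetre.

## Synthetic scenes

The renderer emulates what the pipeline consumes, not the physics of
sheet formation. Per row i (y = i·lateral scale) the stripe centre sits
at `reference_column + pixels_per_um · z(x, y)`; the cross-section is
Gaussian (σ default 6 px, consistent with the ~50 μm sheet thickness at
the default height scale of ≈3.4 μm/px); intensity is
background + peak·exp(...), multiplied by a clipped multiplicative
Gaussian speckle field (1 + contrast·N(0,1), clipped at 0) and quantized
to the camera bit depth (default 12). Speckle contrast defaults to 0.15.
The forward height→pixel map is linear by default, consistent with the
orthogonal configuration; calibration tests exercise the degree-5 fit on
it. Defaults mirror the instrument: 0.29 px/μm forward slope, lateral
scale 5000/896 μm/px, full frame 1280 × 1936 (tests and examples use
reduced frames with preset features placed at fractions of the field
height).

Presets encode the published test samples: `stair_10_20` (plateaus 0/10/
30 μm — two stacked feeler gauges), `grooves_70` (three 70 μm deep,
200 μm wide gate lines), `cylinder_edge` (circular arc of radius 2605 μm,
apex 300 μm), `hair_bump` (circular cross-section, peak 140 μm), `flat`.

What the renderer does **not** model: coherent (physically correlated)
speckle, defocus and sheet divergence, occlusion and shadowing at steep
walls, surface reflectance variation, camera read noise and hot pixels.
Passing tests therefore demonstrate the correctness of the *algorithms*
under realistic quantization and multiplicative noise, not the
instrument's full error budget on real samples.

## Problem sizes and numerical choices

The calibration recovery test runs the full 301-frame protocol at
320 × 512 px frames; the stair scan uses 100 frames at 256 × 384; the
gate-line scan 182 frames at 320 × 384 — frame sizes are reduced from the
full 1280 × 1936 sensor as the features under test occupy a fraction of
the field, which keeps the suite fast without changing any protocol
parameter (frame counts, step sizes, noise levels are the study
conditions). Reduced-size multi-seed calibration checks fit degree 1
(the generator's truth is linear; the quintic's first coefficient is a
derivative at the range edge and needs the full 750 μm range to be
stable). Tie-breaking in peak extraction is exact averaging; degenerate
inputs (all-invalid frames, collinear points, out-of-range inversions,
non-monotone fits) raise `ValueError` or record warnings as documented on
each function.

## Known limitations

- Published gate-line depths (72, 72, 71 μm at offsets 21, 21, 20 px) are
  not reproducible from the published quintic coefficients, whose
  inversion gives ≈74.7 μm at 21 px; the unrounded instrument
  coefficients are unavailable. The package asserts the self-consistent
  substitutes (forward evaluation and round-trip inversion) instead.
- The nonlinear part of the published quintic reaches ~6% of the linear
  term near 530 μm; "the linear term dominates" holds strictly (<2%)
  only below ~200 μm, where the published measurements live.
- No sub-pixel Gaussian peak regression, multi-stripe handling, or
  field-dependent (per-row) calibration maps.
- Heightmaps assume a single-valued surface z(x, y); overhangs and
  re-entrant features are outside the model.
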