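"""Curvature of a curved shell edge from a single stripe profile.

One frame of a cylinder-edge scene is contour-extracted, the curved arc is
converted to physical (y, z) coordinates through the calibration, and a
circle is fitted in two stages (algebraic seed, geometric refinement).
"""

import sheettopo as st

LATERAL = 5000.0 / 896.0
rows = 560
field = rows * LATERAL

scene = st.preset_scene("cylinder_edge", field_height_um=field, seed=41,
                        speckle_contrast=0.15)
frame = st.render_frame(scene, 0.0, (rows, 320))
profile = st.extract_contour(st.smooth_image(frame))
calibration = st.CalibrationModel.from_linear_slope(
    scene.pixels_per_um, 0.0, (0.0, 750.0))

half = int(1050 / LATERAL)  # rows covering the curved section
arc = st.select_arc(profile, (rows // 2 - half, rows // 2 + half),
                    LATERAL, calibration, scene.reference_column)
fit = st.fit_circle(arc)

print(f"arc: {fit.n_points} points spanning "
      f"{arc[:, 0].max() - arc[:, 0].min():.0f} um along the stripe")
print(f"fitted radius : {fit.radius:.0f} um (nominal 2605 um)")
print(f"rms residual  : {fit.rms_residual:.1f} um")
print(f"curvature     : {st.curvature_of(fit):.2f} per mm")
print("-> the fitted circle's reciprocal radius is the edge curvature; "
      "the rms residual reflects the ~1 px speckle jitter of the contour")
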