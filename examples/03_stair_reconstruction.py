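"""3D reconstruction of stacked feeler gauges and step-height metrology.

Simulates a scan across two certified shims (10 and 20 um) stacked in a
stair, reconstructs the surface as a point cloud and gridded heightmap, and
measures both step heights with their relative errors.
"""

import sheettopo as st

LATERAL = 5000.0 / 896.0  # um per pixel along the stripe
rows = 200
field = rows * LATERAL

scene = st.preset_scene("stair_10_20", field_height_um=field, seed=23,
                        speckle_contrast=0.15)
frames = st.render_stack(scene, n_frames=60, scan_step_um=10.0,
                         image_shape=(rows, 320))
print(f"rendered {len(frames)} frames, field {field:.0f} um across the stripe")

calibration = st.CalibrationModel.from_linear_slope(
    scene.pixels_per_um, 0.0, (0.0, 750.0))
stack = st.ScanStack(frames, 10.0, LATERAL, calibration,
                     reference_column=scene.reference_column)
points = st.stack_to_pointcloud(stack)
surface = st.grid_surface(points, 10.0, LATERAL)
print(f"point cloud: {points.shape[0]} points; "
      f"grid: {surface.z.shape[1]} x {surface.z.shape[0]} cells")

b1, b2, m = field / 3, 2 * field / 3, 50.0
x0, x1 = 20.0, 59 * 10.0 - 20.0
h_thin = st.measure_step_height(surface, (x0, x1, b1 + m, b2 - m),
                                (x0, x1, m, b1 - m))
h_thick = st.measure_step_height(surface, (x0, x1, b2 + m, field - m),
                                 (x0, x1, b1 + m, b2 - m))
print(f"10 um gauge: measured {h_thin:.2f} um "
      f"({st.relative_error(h_thin, 10.0):.2f}% error)")
print(f"20 um gauge: measured {h_thick:.2f} um "
      f"({st.relative_error(h_thick, 20.0):.2f}% error)")
print("-> each plateau is the median of thousands of speckle-dithered "
      "height samples, so sub-pixel step heights are recovered from an "
      "integer-pixel contour")
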