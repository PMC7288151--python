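"""Gate-line groove depth on a simulated solar-cell panel.

Grooves running along the scan axis indent the stripe leftward in every
frame; the averaged pixel offset of the indenture, converted through the
calibration, gives the groove depth.
"""

import sheettopo as st
from sheettopo.reconstruction import extract_stack_contours

LATERAL = 5000.0 / 896.0
rows = 240
field = rows * LATERAL

scene = st.preset_scene("grooves_70", field_height_um=field, seed=31,
                        speckle_contrast=0.15)
frames = st.render_stack(scene, n_frames=60, scan_step_um=50.0,
                         image_shape=(rows, 320))
profiles = extract_stack_contours(frames)
calibration = st.CalibrationModel.from_linear_slope(
    scene.pixels_per_um, 0.0, (0.0, 750.0))

print(f"{len(frames)} frames, three grooves of 70 um nominal depth")
for k, frac in enumerate((0.25, 0.5, 0.75), start=1):
    i0 = int((frac * field - 150) / LATERAL)
    i1 = int((frac * field + 150) / LATERAL)
    depth, offset = st.measure_groove_depth(
        profiles, scene.reference_column, calibration, (i0, i1))
    err = st.relative_error(depth, 70.0)
    print(f"groove {k}: mean offset {offset:+.0f} px -> "
          f"depth {depth:.1f} um ({err:.1f}% error)")
print("-> the negative sign marks a concavity (leftward stripe shift); "
      "averaging the indenture offset over all frames beats the +-1 px "
      "quantization of a single profile")
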