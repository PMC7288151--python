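"""Independent oracles used by the tests.

These deliberately avoid the library's code paths: the triangulation oracle
is a numerical 2D ray-trace through a thin lens, and the contour oracle is a
literal per-pixel scan.
"""

from __future__ import annotations

import math

import numpy as np


def raytrace_delta_x(
    delta_z_um: float,
    alpha_deg: float,
    beta_deg: float,
    theta_deg: float,
    focal_length_mm: float,
    object_distance_mm: float,
) -> float:
    """Camera-plane displacement (um) for a surface height offset, by ray trace.

    Construction in the triangulation plane (x horizontal, z up, reference
    surface at z = 0, illuminated reference point A at the origin):

    * the incident ray travels along (sin a, -cos a) through A; raising the
      surface to z = dz moves the bright spot along this fixed ray to B;
    * the imaging lens centre O sits at distance l from A along the viewing
      direction (sin b, cos b); the image A' of A lies at distance
      d = l f / (l - f) beyond O on the same axis;
    * B is imaged through the thin lens (axial/transverse decomposition,
      Newtonian magnification) to B'; the chief ray O -> B' is extended to
      the camera plane, a line through A' tilted so that it makes the angle
      theta with the axis A A';
    * the displacement is the distance from A' to that intersection,
      measured along the camera plane.

    Positive ``delta_z_um`` = surface above the reference plane.
    """
    a = math.radians(alpha_deg)
    b = math.radians(beta_deg)
    t = math.radians(theta_deg)
    f = focal_length_mm * 1e3
    l = object_distance_mm * 1e3
    dz = float(delta_z_um)

    u = np.array([math.sin(b), math.cos(b)])  # A -> lens centre
    p = np.array([math.cos(b), -math.sin(b)])  # transverse unit, p . u = 0
    lens = l * u
    d = l * f / (l - f)
    a_img = lens + d * u

    spot = np.array([-dz * math.tan(a), dz])  # B on the incident ray

    axis = -u  # from lens toward the object
    axial = (spot - lens) @ axis
    trans = (spot - lens) @ p
    if axial <= f:
        raise ValueError("object point inside focal distance; no real image")
    d_b = axial * f / (axial - f)
    b_img = lens + d_b * u + (-d_b / axial) * trans * p

    # camera line: points a_img + s * c, with c at angle theta to the axis
    c = math.cos(t) * u + math.sin(t) * p
    # chief ray: points lens + r * (b_img - lens)
    chief = b_img - lens
    mat = np.column_stack([c, -chief])
    rhs = lens - a_img
    s, _ = np.linalg.solve(mat, rhs)
    return abs(float(s))


def brute_force_contour(image: np.ndarray, min_intensity: float):
    """Literal per-pixel scan: per-row maximum with tie averaging (1-based).

    Returns (positions, valid) like the library's contour extraction.
    """
    h, w = image.shape
    positions = np.full(h, np.nan)
    valid = np.zeros(h, dtype=bool)
    for i in range(h):
        best = image[i, 0]
        tied = [1]
        for j in range(1, w):
            v = image[i, j]
            if v > best:
                best = v
                tied = [j + 1]
            elif v == best:
                tied.append(j + 1)
        if best >= min_intensity:
            positions[i] = sum(tied) / len(tied)
            valid[i] = True
    return positions, valid
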