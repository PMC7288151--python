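"""Circle fitting and curvature of contour arcs.

A selected arc of a stripe contour is mapped into physical (y, z)
coordinates — y from the row index via the lateral scale, z from the
calibrated inversion of the pixel offset — and a circle is fitted in two
stages: an algebraic least-squares fit (linear in the circle equation)
provides a deterministic starting point, refined geometrically by
minimizing the sum of squared point-to-circle distances.  Curvature is the
reciprocal radius, reported per millimetre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .calibration import CalibrationModel, invert_offset
from .profiles import ContourProfile, contour_offsets

__all__ = ["CircleFit", "select_arc", "fit_circle", "curvature_of"]


@dataclass(frozen=True)
class CircleFit:
    """Fitted circle in the (y, z) plane, lengths in um."""

    center_y: float
    center_z: float
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.rms_residual < 0 or self.n_points < 3:
            raise ValueError("invalid fit diagnostics")


def select_arc(
    profile: ContourProfile,
    row_range: tuple[int, int],
    lateral_scale_um_per_px: float,
    calibration: CalibrationModel,
    reference_column: float,
) -> np.ndarray:
    """(n, 2) array of (y, z) um points for rows in ``row_range``.

    y = row * lateral scale; z is the calibrated height of the row's pixel
    offset.  Rows that are invalid or whose offset cannot be inverted are
    skipped.

    Raises
    ------
    ValueError
        If fewer than 3 usable rows remain.
    """
    i0, i1 = row_range
    if not 0 <= i0 < i1 <= profile.n_rows:
        raise ValueError(f"row range [{i0}, {i1}) outside profile of {profile.n_rows} rows")
    offsets = contour_offsets(profile, reference_column)
    lo, hi = calibration.valid_z_range
    pad = 0.01 * (hi - lo)
    pts = []
    for i in range(i0, i1):
        if not profile.valid[i]:
            continue
        try:
            z = invert_offset(calibration, offsets[i], extrapolation_pad_um=pad)
        except ValueError:
            continue
        pts.append((i * lateral_scale_um_per_px, z))
    if len(pts) < 3:
        raise ValueError(f"only {len(pts)} usable rows in [{i0}, {i1}); need >= 3")
    return np.asarray(pts, dtype=float)


def _algebraic_fit(pts: np.ndarray) -> tuple[float, float, float]:
    # Kasa fit: minimize residuals of y^2 + z^2 + D y + E z + F = 0
    y, z = pts[:, 0], pts[:, 1]
    a = np.column_stack([y, z, np.ones_like(y)])
    b = -(y**2 + z**2)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; circle radius is infinite")
    d, e, f = sol
    cy, cz = -d / 2.0, -e / 2.0
    r2 = cy**2 + cz**2 - f
    if r2 <= 0:
        raise ValueError("degenerate algebraic circle fit")
    return float(cy), float(cz), float(np.sqrt(r2))


def fit_circle(points: np.ndarray, method: str = "geometric") -> CircleFit:
    """Least-squares circle through (y, z) points.

    ``method='algebraic'`` stops after the linear (Kasa) stage;
    ``'geometric'`` (default) refines centre and radius by minimizing
    sum((distance_i - R)^2).  For three exact points both are exact.

    Raises
    ------
    ValueError
        For fewer than 3 points or collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) array of (y, z) points")
    # explicit collinearity guard (lstsq rank can stay 3 on nearly collinear data)
    centred = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals[1] <= 1e-12 * max(svals[0], 1.0):
        raise ValueError("points are collinear; circle radius is infinite")
    cy, cz, r = _algebraic_fit(pts)
    if method not in ("algebraic", "geometric"):
        raise ValueError(f"unknown method '{method}'")
    if method == "geometric":

        def residuals(c):
            d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
            return d - d.mean()

        sol = least_squares(residuals, x0=[cy, cz], method="lm", xtol=1e-14, ftol=1e-14)
        cy, cz = float(sol.x[0]), float(sol.x[1])
        r = float(np.hypot(pts[:, 0] - cy, pts[:, 1] - cz).mean())
    dist = np.hypot(pts[:, 0] - cy, pts[:, 1] - cz)
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return CircleFit(
        center_y=cy, center_z=cz, radius=r, rms_residual=rms, n_points=pts.shape[0]
    )


def curvature_of(fit: "CircleFit | float") -> float:
    """Curvature 1/R in 1/mm for a fitted circle (or a radius in um)."""
    radius_um = fit.radius if isinstance(fit, CircleFit) else float(fit)
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    return 1000.0 / radius_um
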