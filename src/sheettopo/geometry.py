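"""Laser-triangulation geometry.

A thin light-sheet strikes the sample at angle ``alpha`` from the surface
normal; elastically scattered light leaves at angle ``beta`` toward an imaging
lens (focal length ``f``, object distance ``l``) and lands on a camera whose
plane makes angle ``theta`` with the object-to-image axis.  A height change
``dz`` of the surface shifts the imaged stripe laterally by ``dx`` in the
camera plane; this module implements the exact oblique mapping between the
two, and the orthogonal simplification (alpha = beta = 45 deg, theta = 90 deg)
in which the mapping is linear.

All lengths are micrometres internally; focal length and object distance are
accepted in millimetres at the interface, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "SurfaceSide",
    "OpticalGeometry",
    "image_distance",
    "delta_z_general",
    "delta_z_linear",
    "delta_x_from_pixels",
]

_MM_TO_UM = 1000.0


class SurfaceSide(str, Enum):
    """Which side of the reference plane the actual surface lies on.

    Selects the sign branch of the oblique mapping: a convexity (surface
    above the reference plane) takes the ``+`` branch, a concavity the
    ``-`` branch.  The branch is always explicit; it is never inferred
    from the data.
    """

    ABOVE = "above"
    BELOW = "below"


def image_distance(focal_length_mm: float, object_distance_mm: float) -> float:
    """Image distance d (mm) from the thin-lens equation 1/l + 1/d = 1/f.

    Raises
    ------
    ValueError
        If ``object_distance_mm <= focal_length_mm`` (no real image).
    """
    f, l = float(focal_length_mm), float(object_distance_mm)
    if f <= 0:
        raise ValueError(f"focal length must be positive, got {f}")
    if l <= f:
        raise ValueError(
            f"object distance ({l} mm) must exceed focal length ({f} mm) "
            "for a real image to form"
        )
    return l * f / (l - f)


@dataclass(frozen=True)
class OpticalGeometry:
    """Fixed triangulation parameters of the instrument.

    Parameters
    ----------
    alpha_deg, beta_deg
        Angles between the incident / scattered ray and the surface normal.
    theta_deg
        Angle between the object-to-image axis and the camera plane.
    focal_length_mm, object_distance_mm
        Thin-lens parameters of the imaging path; the image distance is
        derived from them and is available as :attr:`image_distance_mm`.
    pixel_size_um
        Physical pixel pitch of the camera.
    """

    alpha_deg: float
    beta_deg: float
    theta_deg: float
    focal_length_mm: float
    object_distance_mm: float
    pixel_size_um: float
    image_distance_mm: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.alpha_deg < 90:
            raise ValueError(f"alpha must be in (0, 90) deg, got {self.alpha_deg}")
        if not 0 < self.beta_deg < 90:
            raise ValueError(f"beta must be in (0, 90) deg, got {self.beta_deg}")
        if not 0 < self.theta_deg <= 90:
            raise ValueError(f"theta must be in (0, 90] deg, got {self.theta_deg}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_um}")
        d = image_distance(self.focal_length_mm, self.object_distance_mm)
        object.__setattr__(self, "image_distance_mm", d)


def delta_z_general(
    delta_x_um: float, geom: OpticalGeometry, surface_side: SurfaceSide | str
) -> float:
    """Surface height offset dz (um) for a camera-plane displacement dx (um).

    Exact oblique-configuration mapping::

        dz = dx sin(theta) cos(alpha) (l - f)
             -------------------------------------------------
             f sin(alpha+beta) +/- dx sin(alpha+beta+theta) (1 - f/l)

    with ``+`` for a surface above the reference plane (convexity) and ``-``
    below (concavity).

    Raises
    ------
    ValueError
        If the denominator is not positive for the requested branch, i.e.
        ``delta_x_um`` lies outside the geometric validity range.
    """
    side = SurfaceSide(surface_side)
    dx = float(delta_x_um)
    if dx < 0:
        raise ValueError(f"delta_x must be non-negative, got {dx}")
    a = math.radians(geom.alpha_deg)
    b = math.radians(geom.beta_deg)
    t = math.radians(geom.theta_deg)
    f = geom.focal_length_mm * _MM_TO_UM
    l = geom.object_distance_mm * _MM_TO_UM
    sign = 1.0 if side is SurfaceSide.ABOVE else -1.0
    num = dx * math.sin(t) * math.cos(a) * (l - f)
    den = f * math.sin(a + b) + sign * dx * math.sin(a + b + t) * (1.0 - f / l)
    if den <= 0:
        raise ValueError(
            f"delta_x = {dx} um is outside the validity range of the "
            f"'{side.value}' branch (denominator {den:.6g} <= 0)"
        )
    return num / den


def delta_z_linear(
    delta_x_um: float, focal_length_mm: float, object_distance_mm: float
) -> float:
    """Height offset dz (um) in the orthogonal configuration.

    With alpha = beta = 45 deg and theta = 90 deg the oblique mapping loses
    its dx dependence in the denominator and becomes linear::

        dz = cos(45 deg) * (l - f) / f * dx = sqrt(2) (l - f) / (2 f) * dx

    This is the exact reduction of :func:`delta_z_general`; the two agree to
    machine precision in that configuration.
    """
    # validates l > f > 0
    image_distance(focal_length_mm, object_distance_mm)
    f = focal_length_mm * _MM_TO_UM
    l = object_distance_mm * _MM_TO_UM
    return float(delta_x_um) * math.sqrt(2.0) * (l - f) / (2.0 * f)


def linear_scale_um_per_px(
    focal_length_mm: float, object_distance_mm: float, pixel_size_um: float
) -> float:
    """Height change (um) per one-pixel stripe shift in the orthogonal setup."""
    return delta_z_linear(pixel_size_um, focal_length_mm, object_distance_mm)


def delta_x_from_pixels(delta_n_pixel: float, pixel_size_um: float) -> float:
    """Convert a stripe displacement in pixels to a physical length (um)."""
    if pixel_size_um <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel_size_um}")
    return float(delta_n_pixel) * float(pixel_size_um)
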