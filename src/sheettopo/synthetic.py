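"""Synthetic light-sheet scene renderer.

Forward model of the instrument: a bright, roughly vertical stripe whose
per-row column position encodes the local surface height through the
triangulation mapping.  Ground-truth surfaces z(x, y) are parametric
functions in physical micrometres; the renderer places the stripe centre of
row i (y = i * lateral scale) at

    column = reference_column + pixels_per_um * z(x, y)

gives it a Gaussian cross-section, multiplies by a clipped multiplicative
speckle field and quantizes to the camera bit depth.  Every render is
deterministic given the scene seed.

Presets mirror the published test samples: stacked 10/20 um feeler gauges,
~70 um solar-cell gate-line grooves, a cylinder edge of radius 2605 um and a
~140 um hair lying across the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .profiles import LightSheetImage

__all__ = [
    "SceneSpec",
    "render_frame",
    "render_stack",
    "render_calibration_stack",
    "preset_scene",
    "PRESET_NAMES",
]

# instrument defaults: 896 px across a 5 mm field; calibration slope 0.29 px/um
DEFAULT_LATERAL_SCALE = 5000.0 / 896.0
DEFAULT_PIXELS_PER_UM = 0.29
DEFAULT_SHAPE = (1280, 1936)


@dataclass
class SceneSpec:
    """Parametric ground truth plus stripe/noise/camera parameters.

    ``surface_fn(x_um, y_um)`` returns the surface height z in um; ``y_um``
    is a vector (one entry per image row).  ``pixels_per_um`` is the forward
    calibration slope; ``sheet_sigma_px`` the Gaussian stripe half-width in
    columns (default ~6 px, consistent with a sheet thickness of about 50 um
    at the default height scale); ``speckle_contrast`` the relative standard
    deviation of the multiplicative noise field.
    """

    surface_fn: Callable[[float, np.ndarray], np.ndarray]
    sheet_sigma_px: float = 6.0
    peak_intensity: float = 3000.0
    background: float = 60.0
    speckle_contrast: float = 0.15
    pixels_per_um: float = DEFAULT_PIXELS_PER_UM
    reference_column: float = 120.0  # 1-based column of zero height
    lateral_scale_um_per_px: float = DEFAULT_LATERAL_SCALE
    bit_depth: int = 12
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.sheet_sigma_px <= 0:
            raise ValueError("sheet_sigma_px must be positive")
        if not 0.0 <= self.speckle_contrast < 1.0:
            raise ValueError("speckle_contrast must lie in [0, 1)")
        if not self.peak_intensity > self.background >= 0:
            raise ValueError("need peak_intensity > background >= 0")
        if self.lateral_scale_um_per_px <= 0:
            raise ValueError("lateral_scale_um_per_px must be positive")

    def with_(self, **kwargs) -> "SceneSpec":
        """Copy of the scene with selected fields replaced."""
        return replace(self, **kwargs)

    def stripe_centers(self, x_um: float, n_rows: int) -> np.ndarray:
        """Ground-truth stripe centre column (1-based) per row at scan position x."""
        y = np.arange(n_rows) * self.lateral_scale_um_per_px
        z = np.asarray(self.surface_fn(float(x_um), y), dtype=float)
        return self.reference_column + self.pixels_per_um * z


def render_frame(
    scene: SceneSpec,
    x_position_um: float = 0.0,
    image_shape: tuple[int, int] = DEFAULT_SHAPE,
    rng: np.random.Generator | None = None,
    frame_index: int = 0,
) -> LightSheetImage:
    """Render one frame at scan position ``x_position_um``.

    Raises
    ------
    ValueError
        If the stripe centre falls outside the image columns for any row
        (the programmed height is outside the camera's view).
    """
    h, w = image_shape
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    centers = scene.stripe_centers(x_position_um, h)
    if np.any(centers < 1) or np.any(centers > w):
        raise ValueError(
            "stripe centre outside image columns for at least one row: "
            f"range [{centers.min():.1f}, {centers.max():.1f}] vs width {w}"
        )
    cols = np.arange(1, w + 1, dtype=float)
    signal = scene.peak_intensity * np.exp(
        -((cols[None, :] - centers[:, None]) ** 2) / (2.0 * scene.sheet_sigma_px**2)
    )
    img = scene.background + signal
    if scene.speckle_contrast > 0:
        speckle = 1.0 + scene.speckle_contrast * rng.standard_normal(size=(h, w))
        img = img * np.clip(speckle, 0.0, None)
    img = np.clip(np.rint(img), 0, 2**scene.bit_depth - 1).astype(np.uint16)
    return LightSheetImage(
        intensities=img,
        bit_depth=scene.bit_depth,
        frame_index=frame_index,
        stage_position_um=float(x_position_um),
    )


def render_stack(
    scene: SceneSpec,
    n_frames: int,
    scan_step_um: float,
    image_shape: tuple[int, int] = DEFAULT_SHAPE,
) -> list[LightSheetImage]:
    """Render an ordered scan: frame k at x = k * scan_step_um."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(scene.seed)
    return [
        render_frame(scene, k * scan_step_um, image_shape, rng=rng, frame_index=k)
        for k in range(n_frames)
    ]


def render_calibration_stack(
    scene: SceneSpec,
    n_steps: int = 301,
    step_um: float = 2.5,
    image_shape: tuple[int, int] = DEFAULT_SHAPE,
) -> list[LightSheetImage]:
    """Calibration protocol: a flat surface raised by ``step_um`` per frame.

    Frame k images a flat plane at height k * step_um regardless of the
    scene's own surface function (defaults: 301 frames, 2.5 um steps).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(scene.seed)
    frames = []
    for k in range(n_steps):
        height = k * float(step_um)
        flat = scene.with_(surface_fn=_flat(height))
        frames.append(
            render_frame(flat, 0.0, image_shape, rng=rng, frame_index=k)
        )
    return frames


# ---------------------------------------------------------------------------
# preset ground-truth surfaces


def _flat(height: float = 0.0):
    def fn(x: float, y: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(y, dtype=float), float(height))

    return fn


def _stair(field_height_um: float, h1: float = 10.0, h2: float = 20.0):
    # two gauges stacked in a stair: plateaus at 0, h1 and h1 + h2 along y
    b1, b2 = field_height_um / 3.0, 2.0 * field_height_um / 3.0

    def fn(x: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return np.where(y < b1, 0.0, np.where(y < b2, h1, h1 + h2))

    return fn


def _grooves(field_height_um: float, depth: float = 70.0, width: float = 200.0):
    # three gate-line grooves running along the scan axis
    centers = np.array([0.25, 0.5, 0.75]) * field_height_um

    def fn(x: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        z = np.zeros_like(y)
        for c in centers:
            z = np.where(np.abs(y - c) < width / 2.0, -depth, z)
        return z

    return fn


def _cylinder_edge(field_height_um: float, radius: float = 2605.0, apex: float = 300.0):
    # circular arc bulge: apex height `apex`, circle centre below the surface
    y0 = field_height_um / 2.0
    zc = apex - radius  # centre height; z(y) = zc + sqrt(R^2 - (y - y0)^2)

    def fn(x: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        inside = radius**2 - (y - y0) ** 2
        z = zc + np.sqrt(np.clip(inside, 0.0, None))
        return np.clip(z, 0.0, None)

    return fn


def _hair_bump(field_height_um: float, diameter: float = 140.0):
    # a hair of circular cross-section lying across the field at mid-height
    r = diameter / 2.0
    y0 = field_height_um / 2.0

    def fn(x: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        inside = r**2 - (y - y0) ** 2
        return np.where(inside > 0, r + np.sqrt(np.clip(inside, 0.0, None)), 0.0)

    return fn


#: ground truth documented per preset (um)
PRESET_GROUND_TRUTH = {
    "flat": {"height": 0.0},
    "stair_10_20": {"plateaus": (0.0, 10.0, 30.0), "gauges": (10.0, 20.0)},
    "grooves_70": {"depth": 70.0, "n_grooves": 3, "width_um": 200.0},
    "cylinder_edge": {"radius_um": 2605.0, "apex_um": 300.0},
    "hair_bump": {"peak_height_um": 140.0},
}

PRESET_NAMES = tuple(PRESET_GROUND_TRUTH)


def preset_scene(
    name: str,
    field_height_um: float | None = None,
    **overrides,
) -> SceneSpec:
    """Fully parameterized scene for a named preset.

    ``field_height_um`` is the physical height of the imaged field (rows x
    lateral scale); preset features are placed at fixed fractions of it so
    the same preset renders correctly at reduced image sizes.  Extra keyword
    arguments override :class:`SceneSpec` fields.

    Raises
    ------
    ValueError
        For an unknown preset name.
    """
    if name not in PRESET_GROUND_TRUTH:
        raise ValueError(f"unknown preset '{name}'; choose from {PRESET_NAMES}")
    lateral = overrides.get("lateral_scale_um_per_px", DEFAULT_LATERAL_SCALE)
    if field_height_um is None:
        field_height_um = DEFAULT_SHAPE[0] * lateral
    builders = {
        "flat": lambda: _flat(0.0),
        "stair_10_20": lambda: _stair(field_height_um),
        "grooves_70": lambda: _grooves(field_height_um),
        "cylinder_edge": lambda: _cylinder_edge(field_height_um),
        "hair_bump": lambda: _hair_bump(field_height_um),
    }
    return SceneSpec(surface_fn=builders[name](), name=name, **overrides)
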