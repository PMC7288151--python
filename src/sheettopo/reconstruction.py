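"""3D surface reconstruction and dimensional metrology.

Per-frame stripe contours are converted to heights through the calibration
model and stitched along the scan axis into a point cloud (x = scan
position, y = row * lateral scale, z = height), then interpolated onto a
regular grid.  Metrology helpers measure step heights between plateau
regions, groove depths from averaged pixel offsets, and relative errors
against reference values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.interpolate import griddata

from .calibration import CalibrationModel, invert_offset
from .profiles import (
    ContourProfile,
    LightSheetImage,
    contour_offsets,
    extract_contour,
    smooth_image,
)

__all__ = [
    "ScanStack",
    "HeightMap",
    "extract_stack_contours",
    "stack_to_pointcloud",
    "grid_surface",
    "measure_step_height",
    "measure_groove_depth",
    "relative_error",
]


@dataclass
class ScanStack:
    """An ordered light-sheet scan plus the scales needed to reconstruct it.

    ``scan_step_um`` separates consecutive frames along x; ``lateral_scale``
    converts image rows to um along y; ``calibration`` maps pixel offsets to
    heights; ``reference_column`` is the stripe column of the zero-height
    reference plane (taken from the calibration metadata when omitted).
    """

    frames: Sequence["LightSheetImage | np.ndarray"]
    scan_step_um: float
    lateral_scale_um_per_px: float
    calibration: CalibrationModel
    reference_column: float | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a scan needs at least 2 frames")
        if self.scan_step_um <= 0 or self.lateral_scale_um_per_px <= 0:
            raise ValueError("scan_step_um and lateral_scale_um_per_px must be positive")
        if self.reference_column is None:
            ref = self.calibration.metadata.get("reference_column")
            if ref is None:
                raise ValueError(
                    "reference_column not given and absent from calibration metadata"
                )
            self.reference_column = float(ref)


@dataclass
class HeightMap:
    """Surface heights z(x, y) on a regular grid (um everywhere).

    ``z`` is (ny, nx); ``x`` and ``y`` are the 1D grid coordinates; masked
    cells (outside the interpolation hull or otherwise undefined) are False
    in ``mask`` and NaN in ``z``.
    """

    z: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.shape != (self.y.size, self.x.size) or self.mask.shape != self.z.shape:
            raise ValueError("inconsistent grid shapes")

    @property
    def x_spacing(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 0.0

    @property
    def y_spacing(self) -> float:
        return float(self.y[1] - self.y[0]) if self.y.size > 1 else 0.0

    def region_values(self, region: tuple[float, float, float, float]) -> np.ndarray:
        """Valid z values inside a physical rectangle (x0, x1, y0, y1) um."""
        x0, x1, y0, y1 = region
        ix = (self.x >= min(x0, x1)) & (self.x <= max(x0, x1))
        iy = (self.y >= min(y0, y1)) & (self.y <= max(y0, y1))
        sub = self.z[np.ix_(iy, ix)]
        ok = self.mask[np.ix_(iy, ix)]
        return sub[ok]


def extract_stack_contours(
    frames: Sequence["LightSheetImage | np.ndarray"],
    smooth: bool = True,
    min_intensity: float | None = None,
) -> list[ContourProfile]:
    """Smooth and contour-extract every frame of a scan."""
    profiles = []
    for k, frame in enumerate(frames):
        img = smooth_image(frame) if smooth else frame
        prof = extract_contour(img, min_intensity=min_intensity)
        prof.frame_index = k
        profiles.append(prof)
    return profiles


def stack_to_pointcloud(
    stack: ScanStack,
    smooth: bool = True,
    min_intensity: float | None = None,
    extrapolation_pad_um: float | None = None,
) -> np.ndarray:
    """(N, 3) array of (x, y, z) um points from a scan.

    Frame k contributes points at x = k * scan_step for each valid row i at
    y = i * lateral scale, with z obtained by inverting the calibration at
    that row's pixel offset.  Rows whose offset cannot be inverted (outside
    the calibrated offset range even after the pad) are dropped.  The default
    pad is the height equivalent of 4 pixels of offset (4 / |c1|): peak
    extraction quantizes at one pixel and speckle dithers it by a few more,
    so points at the boundary of the calibrated range would otherwise be
    censored one-sidedly, biasing plateau statistics.

    Raises
    ------
    ValueError
        If no point at all can be reconstructed.
    """
    cal = stack.calibration
    if extrapolation_pad_um is None:
        slope = abs(cal.linear_slope)
        lo, hi = cal.valid_z_range
        extrapolation_pad_um = 4.0 / slope if slope > 0 else 0.01 * (hi - lo)
    profiles = extract_stack_contours(stack.frames, smooth=smooth, min_intensity=min_intensity)
    points = []
    for k, prof in enumerate(profiles):
        x = k * stack.scan_step_um
        offsets = contour_offsets(prof, stack.reference_column)
        for i in np.nonzero(prof.valid)[0]:
            try:
                z = invert_offset(cal, offsets[i], extrapolation_pad_um=extrapolation_pad_um)
            except ValueError:
                continue
            points.append((x, i * stack.lateral_scale_um_per_px, z))
    if not points:
        raise ValueError("no reconstructable points in the scan")
    return np.asarray(points, dtype=float)


def grid_surface(
    points: np.ndarray,
    x_spacing_um: float,
    y_spacing_um: float,
) -> HeightMap:
    """Linear scattered-data interpolation of a point cloud onto a grid.

    Cells outside the convex hull of the points are masked.  Linear
    barycentric interpolation is exact for planar surfaces and reproduces
    input points that fall on grid nodes.

    Raises
    ------
    ValueError
        For fewer than 3 points or a degenerate (collinear) geometry.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need an (N >= 3, 3) point array")
    if x_spacing_um <= 0 or y_spacing_um <= 0:
        raise ValueError("grid spacings must be positive")
    xy, z = pts[:, :2], pts[:, 2]
    # collinearity check via the rank of centred coordinates
    if np.linalg.matrix_rank(xy - xy.mean(axis=0), tol=1e-9 * max(np.ptp(xy), 1.0)) < 2:
        raise ValueError("points are collinear in (x, y); cannot triangulate a surface")
    gx = np.arange(xy[:, 0].min(), xy[:, 0].max() + x_spacing_um / 2, x_spacing_um)
    gy = np.arange(xy[:, 1].min(), xy[:, 1].max() + y_spacing_um / 2, y_spacing_um)
    mx, my = np.meshgrid(gx, gy)
    gz = griddata(xy, z, (mx, my), method="linear")
    mask = np.isfinite(gz)
    return HeightMap(z=gz, x=gx, y=gy, mask=mask)


def measure_step_height(
    surface: HeightMap,
    region_hi: tuple[float, float, float, float],
    region_lo: tuple[float, float, float, float],
    summary: str = "median",
    min_cells: int = 10,
) -> float:
    """Step height (um) between two plateau rectangles (x0, x1, y0, y1).

    Returns summary(region_hi) - summary(region_lo); the median (default) is
    robust to residual speckle outliers.

    Raises
    ------
    ValueError
        If either region holds fewer than ``min_cells`` valid cells.
    """
    if summary not in ("median", "mean"):
        raise ValueError(f"unknown summary '{summary}' (use 'median' or 'mean')")
    stat = np.median if summary == "median" else np.mean
    vals = []
    for label, region in (("region_hi", region_hi), ("region_lo", region_lo)):
        v = surface.region_values(region)
        if v.size < min_cells:
            raise ValueError(
                f"{label} contains only {v.size} valid cells (need >= {min_cells})"
            )
        vals.append(float(stat(v)))
    return vals[0] - vals[1]


def groove_frame_offset(
    profile: ContourProfile,
    reference_column: float,
    row_window: tuple[int, int],
) -> float:
    """Extremal signed pixel offset of one groove in one frame.

    The indenture is located as the offset of largest magnitude within the
    given row window (grooves shift the stripe toward negative offsets).

    Raises
    ------
    ValueError
        If the window holds no valid row.
    """
    i0, i1 = row_window
    offsets = contour_offsets(profile, reference_column)[i0:i1]
    offsets = offsets[np.isfinite(offsets)]
    if offsets.size == 0:
        raise ValueError(f"no valid rows in window [{i0}, {i1})")
    return float(offsets[np.argmax(np.abs(offsets))])


def measure_groove_depth(
    profiles: Sequence[ContourProfile],
    reference_column: float,
    calibration: CalibrationModel,
    row_window: tuple[int, int],
    round_offsets: bool = True,
) -> tuple[float, float]:
    """Groove depth (um) from per-frame pixel offsets averaged over a scan.

    The groove runs along the scan axis, so every frame images the same
    indenture.  Its location is fixed once from the frame-averaged offset
    profile inside ``row_window`` (the extremal row); the groove floor is
    the set of rows whose averaged offset lies beyond half of the extremal
    value.  Per frame, the indenture offset is the median over the floor
    rows — a raw per-frame extremum would ride the most extreme speckle
    excursion and systematically overestimate the depth.  The per-frame
    offsets are averaged across all frames, rounded to the nearest integer
    pixel (as in the instrument protocol; disable with
    ``round_offsets=False``), and the magnitude is converted to a depth via
    the calibration inverse.

    Returns ``(depth_um, mean_offset_px)`` where ``mean_offset_px`` is the
    (possibly rounded) averaged signed offset.

    Raises
    ------
    ValueError
        If no frame shows a detectable indenture.
    """
    i0, i1 = row_window
    rows = []
    for prof in profiles:
        off = contour_offsets(prof, reference_column)[i0:i1]
        rows.append(off)
    stack = np.asarray(rows, dtype=float)  # (n_frames, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_profile = np.nanmean(stack, axis=0)
    if not np.isfinite(mean_profile).any():
        raise ValueError("no indenture detected in any frame")
    extremal = mean_profile[np.nanargmax(np.abs(mean_profile))]
    if extremal == 0:
        raise ValueError("no indenture detected: offsets are all zero")
    floor = (mean_profile / extremal) > 0.5  # same sign, beyond half depth
    per_frame = []
    for off in stack:
        vals = off[floor & np.isfinite(off)]
        if vals.size:
            per_frame.append(float(np.median(vals)))
    if not per_frame:
        raise ValueError("no indenture detected in any frame")
    mean_offset = float(np.mean(per_frame))
    if round_offsets:
        mean_offset = float(np.rint(mean_offset))
    depth = invert_offset(calibration, abs(mean_offset))
    return depth, mean_offset


def relative_error(measured_um: float, reference_um: float) -> float:
    """Relative error in percent: 100 |measured - reference| / reference.

    Raises
    ------
    ValueError
        If the reference value is zero.
    """
    if reference_um == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * abs(measured_um - reference_um) / abs(reference_um)
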