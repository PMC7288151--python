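"""Pixel-offset-versus-height calibration.

A calibration stack images a flat surface raised in known increments (the
instrument protocol: 301 frames at 2.5 um steps).  The stripe column shift
dn (pixels) against height dz (um) is fitted with a low-order polynomial
(default degree 5, of which the linear term dominates in the orthogonal
configuration); the fitted model is inverted by bracketed root-finding to
convert measured pixel offsets back into heights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq

from .profiles import ContourProfile, LightSheetImage, extract_contour, smooth_image, summarize_profile

__all__ = [
    "CalibrationModel",
    "build_calibration",
    "predict_offset",
    "invert_offset",
    "z_resolution_bound",
    "calibrate_stack",
]


@dataclass
class CalibrationModel:
    """Polynomial mapping dz (um) -> dn (pixels) with fit diagnostics.

    ``coefficients`` are lowest-order first (c0..c_degree).  ``valid_z_range``
    is the height interval covered by the calibration data; inversion is only
    defined there (plus a caller-supplied pad).  If the fitted polynomial is
    not strictly increasing over the range, ``monotone_warning`` is set and
    inversion is restricted to the largest increasing subinterval starting at
    the bottom of the range.
    """

    coefficients: np.ndarray
    r_squared: float
    valid_z_range: tuple[float, float]
    metadata: dict = dc_field(default_factory=dict)
    monotone_warning: bool = dc_field(default=False)
    _inversion_range: tuple[float, float] = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1 or not 1 <= self.coefficients.size <= 6:
            raise ValueError("coefficients must be a 1D array of length 2..6 (degree <= 5)")
        if not 0.0 <= self.r_squared <= 1.0:
            if not np.isnan(self.r_squared):
                raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")
        lo, hi = self.valid_z_range
        if not hi > lo:
            raise ValueError("valid_z_range must be an increasing interval")
        if self._inversion_range is None:
            self._check_monotone()

    def _check_monotone(self) -> None:
        lo, hi = self.valid_z_range
        z = np.linspace(lo, hi, 2048)
        dp = Polynomial(self.coefficients).deriv()(z)
        if np.all(dp > 0):
            self._inversion_range = (lo, hi)
            return
        self.monotone_warning = True
        bad = np.nonzero(dp <= 0)[0]
        stop = max(int(bad[0]), 1)
        self._inversion_range = (lo, float(z[stop - 1]))
        warnings.warn(
            "fitted calibration polynomial is not strictly increasing over "
            f"[{lo:g}, {hi:g}] um; inversion restricted to "
            f"[{self._inversion_range[0]:g}, {self._inversion_range[1]:g}] um",
            stacklevel=3,
        )

    @property
    def degree(self) -> int:
        return self.coefficients.size - 1

    @property
    def linear_slope(self) -> float:
        """First-order coefficient c1, in pixels per um."""
        return float(self.coefficients[1]) if self.coefficients.size > 1 else 0.0

    @property
    def inversion_range(self) -> tuple[float, float]:
        return self._inversion_range

    def predict(self, delta_z_um: float | np.ndarray) -> float | np.ndarray:
        return predict_offset(self, delta_z_um)

    def invert(self, delta_n_px: float, extrapolation_pad_um: float = 0.0) -> float:
        return invert_offset(self, delta_n_px, extrapolation_pad_um=extrapolation_pad_um)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coefficients": list(map(float, self.coefficients)),
            "r_squared": float(self.r_squared),
            "valid_z_range": [float(v) for v in self.valid_z_range],
            "monotone_warning": bool(self.monotone_warning),
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            r_squared=float(d["r_squared"]),
            valid_z_range=tuple(d["valid_z_range"]),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_linear_slope(
        cls,
        slope_px_per_um: float,
        intercept_px: float = 0.0,
        valid_z_range: tuple[float, float] = (0.0, 750.0),
    ) -> "CalibrationModel":
        """Model from a single calibrated scale factor (pure linear regime)."""
        return cls(
            coefficients=np.array([intercept_px, slope_px_per_um]),
            r_squared=1.0,
            valid_z_range=valid_z_range,
        )


def build_calibration(
    offsets: Iterable[tuple[float, float]] | np.ndarray,
    degree: int = 5,
) -> CalibrationModel:
    """Least-squares polynomial fit of (dz um, dn px) calibration points.

    Fitting is done in a rescaled domain for conditioning and converted back
    to ordinary coefficients.  R^2 is the coefficient of determination
    1 - SS_res/SS_tot.

    Raises
    ------
    ValueError
        If fewer than ``degree + 2`` points are given or the dz values are
        not strictly increasing.
    """
    pts = np.asarray(list(offsets) if not isinstance(offsets, np.ndarray) else offsets, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("offsets must be a sequence of (delta_z_um, delta_n_px) pairs")
    if not 1 <= degree <= 5:
        raise ValueError(f"degree must be in 1..5, got {degree}")
    z, n = pts[:, 0], pts[:, 1]
    if pts.shape[0] < degree + 2:
        raise ValueError(
            f"need at least degree + 2 = {degree + 2} points, got {pts.shape[0]}"
        )
    if not np.all(np.diff(z) > 0):
        raise ValueError("delta_z values must be strictly increasing")
    fit = Polynomial.fit(z, n, deg=degree)
    coeffs = fit.convert().coef
    coeffs = np.pad(coeffs, (0, degree + 1 - coeffs.size))
    pred = fit(z)
    ss_res = float(np.sum((n - pred) ** 2))
    ss_tot = float(np.sum((n - n.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(
        coefficients=coeffs,
        r_squared=min(max(r2, 0.0), 1.0),
        valid_z_range=(float(z.min()), float(z.max())),
        metadata={"n_points": int(pts.shape[0]), "degree": int(degree)},
    )


def predict_offset(model: CalibrationModel, delta_z_um: float | np.ndarray):
    """Forward evaluation dn(dz) of the calibration polynomial (pixels).

    Raises
    ------
    ValueError
        If ``delta_z_um`` lies outside the model's valid height range.
    """
    z = np.asarray(delta_z_um, dtype=float)
    lo, hi = model.valid_z_range
    span = hi - lo
    tol = 1e-9 * max(span, 1.0)
    if np.any(z < lo - tol) or np.any(z > hi + tol):
        raise ValueError(
            f"delta_z outside the calibrated range [{lo:g}, {hi:g}] um"
        )
    out = Polynomial(model.coefficients)(z)
    return float(out) if np.isscalar(delta_z_um) else out


def invert_offset(
    model: CalibrationModel,
    delta_n_px: float,
    extrapolation_pad_um: float = 0.0,
) -> float:
    """Height dz (um) whose predicted offset equals ``delta_n_px``.

    Solved by bracketed root-finding (Brent) over the model's monotone
    inversion range, optionally padded by ``extrapolation_pad_um`` at both
    ends to absorb noise on the fitted intercept near the range boundaries.

    Raises
    ------
    ValueError
        If ``delta_n_px`` is outside the attainable offset range.
    """
    lo, hi = model.inversion_range
    lo -= extrapolation_pad_um
    hi += extrapolation_pad_um
    poly = Polynomial(model.coefficients)
    dn = float(delta_n_px)
    f_lo, f_hi = poly(lo) - dn, poly(hi) - dn
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"offset {dn:g} px is outside the attainable range "
            f"[{poly(lo):.4g}, {poly(hi):.4g}] px of the calibration"
        )
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    return float(brentq(lambda z: poly(z) - dn, lo, hi, xtol=1e-9, rtol=1e-14))


def z_resolution_bound(step_um: float, steps_to_guaranteed_shift: int) -> float:
    """Worst-case height resolution of the instrument (um).

    Speckle can leave the stripe stationary for single calibration steps;
    if a shift of at least one pixel is guaranteed only after
    ``steps_to_guaranteed_shift`` increments of ``step_um``, the resolution
    bound is their product (e.g. 4 steps of 2.5 um -> 10 um).
    """
    if step_um <= 0:
        raise ValueError(f"step must be positive, got {step_um}")
    if steps_to_guaranteed_shift < 1:
        raise ValueError("steps_to_guaranteed_shift must be >= 1")
    return float(step_um) * int(steps_to_guaranteed_shift)


def stack_frame_offsets(
    frames: Sequence["LightSheetImage | np.ndarray"],
    smooth: bool = True,
    min_intensity: float | None = None,
    summary: str = "median",
) -> tuple[float, np.ndarray]:
    """Per-frame stripe offsets of a calibration stack (pixels).

    Each frame is reduced to one column position (``summary`` over valid
    rows); offsets are taken against the first frame's position, mirroring
    the protocol of subtracting the first recorded contour line.

    Returns ``(reference_column, offsets)`` with ``offsets[0] == 0``.
    """
    positions = []
    for k, frame in enumerate(frames):
        img = smooth_image(frame) if smooth else frame
        prof = extract_contour(img, min_intensity=min_intensity)
        positions.append(summarize_profile(prof, summary=summary))
    reference = positions[0]
    return reference, np.asarray(positions) - reference


def calibrate_stack(
    frames: Sequence["LightSheetImage | np.ndarray"],
    step_um: float = 2.5,
    degree: int = 5,
    smooth: bool = True,
    min_intensity: float | None = None,
    summary: str = "median",
) -> CalibrationModel:
    """End-to-end calibration from a stack of flat-surface frames.

    Frame ``k`` is assumed to image the flat reference surface raised by
    ``k * step_um``; contours are extracted, summarized and fitted with
    :func:`build_calibration`.
    """
    if step_um <= 0:
        raise ValueError(f"step must be positive, got {step_um}")
    reference, offsets = stack_frame_offsets(
        frames, smooth=smooth, min_intensity=min_intensity, summary=summary
    )
    z = np.arange(len(offsets)) * float(step_um)
    model = build_calibration(np.column_stack([z, offsets]), degree=degree)
    model.metadata.update(
        {"step_um": float(step_um), "n_frames": len(offsets), "reference_column": reference}
    )
    return model
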