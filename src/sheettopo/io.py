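"""Readers and writers for the pipeline's plain-file formats.

Frames are TIFF or PNG; stacks are directories read in lexicographic order
unless a ``manifest.csv`` (columns: filename, stage_position_um) fixes the
order; contours and heightmaps are CSV; heightmaps additionally 32-bit
float TIFF (um units) with the validity mask as a second TIFF; point clouds
are whitespace XYZ and ASCII PLY.  Run configuration is flat YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .profiles import ContourProfile, LightSheetImage
from .reconstruction import HeightMap

__all__ = [
    "read_image",
    "read_stack",
    "write_stack",
    "contours_to_csv",
    "contours_from_csv",
    "write_heightmap",
    "write_pointcloud_xyz",
    "write_pointcloud_ply",
    "load_config",
]

_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    m = int(arr.max()) if arr.size else 0
    return 12 if m <= 4095 else 16


def read_image(path: str | Path, frame_index: int = 0,
               stage_position_um: float | None = None) -> LightSheetImage:
    """Read one grayscale frame (TIFF via tifffile, PNG via imageio)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB read of a grayscale image
        arr = arr[..., 0]
    return LightSheetImage(
        intensities=arr,
        bit_depth=_infer_bit_depth(arr),
        frame_index=frame_index,
        stage_position_um=stage_position_um,
    )


def read_stack(directory: str | Path) -> list[LightSheetImage]:
    """Read an ordered stack from a directory.

    If ``manifest.csv`` exists (columns ``filename`` and optionally
    ``stage_position_um``) it fixes the frame order; otherwise files are
    taken in lexicographic order.
    """
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if manifest.exists():
        table = pd.read_csv(manifest)
        names = list(table["filename"])
        positions = (
            list(table["stage_position_um"])
            if "stage_position_um" in table
            else [None] * len(names)
        )
    else:
        names = sorted(
            p.name for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        positions = [None] * len(names)
    if not names:
        raise ValueError(f"no frames found in {directory}")
    return [
        read_image(directory / name, frame_index=k, stage_position_um=pos)
        for k, (name, pos) in enumerate(zip(names, positions))
    ]


def write_stack(
    frames: Sequence[LightSheetImage], directory: str | Path, prefix: str = "frame"
) -> list[Path]:
    """Write frames as numbered TIFFs plus a manifest.csv with stage positions."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths, rows = [], []
    for k, frame in enumerate(frames):
        name = f"{prefix}_{k:05d}.tif"
        tifffile.imwrite(directory / name, np.asarray(frame.intensities, dtype=np.uint16))
        rows.append({"filename": name, "stage_position_um": frame.stage_position_um})
        paths.append(directory / name)
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return paths


def contours_to_csv(profiles: Sequence[ContourProfile], path: str | Path) -> None:
    """Write contours as CSV (frame, row, column_position, valid)."""
    rows = []
    for prof in profiles:
        for i in range(prof.n_rows):
            rows.append(
                {
                    "frame": prof.frame_index,
                    "row": i,
                    "column_position": prof.column_position[i],
                    "valid": bool(prof.valid[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def contours_from_csv(path: str | Path) -> list[ContourProfile]:
    table = pd.read_csv(path)
    profiles = []
    for frame, group in table.groupby("frame", sort=True):
        group = group.sort_values("row")
        profiles.append(
            ContourProfile(
                column_position=group["column_position"].to_numpy(dtype=float),
                valid=group["valid"].to_numpy(dtype=bool),
                frame_index=int(frame),
            )
        )
    return profiles


def write_heightmap(surface: HeightMap, stem: str | Path) -> dict[str, Path]:
    """Write ``<stem>.tif`` (float32 um), ``<stem>_mask.tif`` and ``<stem>.csv``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    out = {
        "tiff": stem.with_suffix(".tif"),
        "mask": stem.parent / f"{stem.name}_mask.tif",
        "csv": stem.with_suffix(".csv"),
    }
    tifffile.imwrite(out["tiff"], surface.z.astype(np.float32))
    tifffile.imwrite(out["mask"], surface.mask.astype(np.uint8))
    iy, ix = np.nonzero(surface.mask)
    pd.DataFrame(
        {"x_um": surface.x[ix], "y_um": surface.y[iy], "z_um": surface.z[iy, ix]}
    ).to_csv(out["csv"], index=False)
    return out


def write_pointcloud_xyz(points: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.6f")


def write_pointcloud_ply(points: np.ndarray, path: str | Path) -> None:
    """Minimal ASCII PLY with vertex positions only."""
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {pts.shape[0]}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n"
        )
        for x, y, z in pts:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def load_config(path: str | Path) -> dict:
    """Flat key-value run configuration from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a flat YAML mapping")
    return cfg


def write_provenance(directory: str | Path, payload: dict) -> Path:
    """Drop a provenance log (config echo, version, seed) next to outputs."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "provenance.json"
    path.write_text(json.dumps({"sheettopo_version": __version__, **payload}, indent=2, default=str) + "\n")
    return path
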