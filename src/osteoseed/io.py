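"""File output: legacy VTK, CSV tables, images, manifests.

VTK files use the legacy ASCII STRUCTURED_POINTS format (readable by
ParaView and VisIt) so voxel occupancies and section fields can be
inspected visually; tabular outputs go through pandas CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def write_vtk_structured_points(path, spacing, origin, cell_data: dict,
                                title: str = "osteoseed field") -> None:
    """Write cell-centred 2D/3D scalar fields as legacy ASCII VTK.

    ``cell_data`` maps names to arrays of one common shape; 2D arrays
    are written as a one-cell-thick volume.
    """
    arrays = {k: np.asarray(v) for k, v in cell_data.items()}
    if not arrays:
        raise ValueError("no fields to write")
    shape = next(iter(arrays.values())).shape
    if any(a.shape != shape for a in arrays.values()):
        raise ValueError("all fields must share one shape")
    if len(shape) == 2:
        arrays = {k: a[:, :, None] for k, a in arrays.items()}
        shape = shape + (1,)
    nx, ny, nz = shape
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
    origin = np.broadcast_to(np.asarray(origin, float), (3,))
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}",
        f"SPACING {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}",
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, arr in arrays.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        flat = arr.transpose(2, 1, 0).ravel()  # VTK is x-fastest
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_points(path, points, scalars: dict | None = None,
                     title: str = "osteoseed particles") -> None:
    """Write a point cloud (N, 2 or 3) with per-point scalar fields."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[1] == 2:
        pts = np.hstack([pts, np.zeros((len(pts), 1))])
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pts)} float",
    ]
    lines.extend(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in pts)
    if scalars:
        lines.append(f"POINT_DATA {len(pts)}")
        for name, vals in scalars.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{float(v):.9g}" for v in np.asarray(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def save_image(path, image) -> None:
    """Save an 8-bit grayscale image (PNG/TIFF by extension)."""
    import imageio.v3 as iio

    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("expected a uint8 image")
    iio.imwrite(path, arr)


def load_image(path) -> np.ndarray:
    """Load an image as 8-bit grayscale (averaging channels if RGB)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def overlay_classes(labels) -> np.ndarray:
    """RGB visual QC overlay: scaffold white, bone orange, other black."""
    from .quant import BONE_PX, SCAFFOLD_PX

    lab = np.asarray(labels)
    rgb = np.zeros(lab.shape + (3,), np.uint8)
    rgb[lab == SCAFFOLD_PX] = (255, 255, 255)
    rgb[lab == BONE_PX] = (230, 140, 30)
    return rgb


def write_manifest(path, manifest: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(manifest, indent=2, default=default)
                          + "\n")
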