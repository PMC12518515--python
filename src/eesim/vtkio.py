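"""Legacy-ASCII VTK structured-points export for inspection in ParaView."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_structured_points"]


def write_structured_points(
    path: str | Path,
    arrays: dict[str, np.ndarray],
    voxel_size: float,
    origin: np.ndarray,
) -> Path:
    """Write one or more voxel-grid scalar fields to a legacy VTK file.

    All arrays must share one (nx, ny, nz) shape; values are written in the
    x-fastest order the format expects.
    """
    path = Path(path)
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError(f"arrays disagree on shape: {shapes}")
    nx, ny, nz = shapes.pop()
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\neesim grid\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {voxel_size} {voxel_size} {voxel_size}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in arrays.items():
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            flat = np.transpose(arr, (2, 1, 0)).ravel()
            np.savetxt(fh, flat[None] if flat.ndim == 1 else flat, fmt="%g")
    return path
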