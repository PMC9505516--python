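"""Minimal legacy-ASCII VTK rectilinear-grid writer for field exports.

Writes cell data (potential, field magnitude, envelope, RE/IRE masks) on
the solver's structured grid so results can be inspected in ParaView.
Only the small subset of the legacy VTK format needed here is emitted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .grid import Grid

__all__ = ["write_vtk"]


def write_vtk(path: str | Path, grid: Grid, cell_data: Mapping[str, np.ndarray],
              title: str = "skingetsim field export") -> None:
    """Write cell-centred arrays (shape nx, ny, nz) as legacy VTK."""
    nx, ny, nz = grid.shape
    for name, arr in cell_data.items():
        if arr.shape != (nx, ny, nz):
            raise ValueError(f"array {name!r} does not match the grid")
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"X_COORDINATES {nx + 1} double",
        " ".join(f"{v:.9g}" for v in grid.x_edges),
        f"Y_COORDINATES {ny + 1} double",
        " ".join(f"{v:.9g}" for v in grid.y_edges),
        f"Z_COORDINATES {nz + 1} double",
        " ".join(f"{v:.9g}" for v in grid.z_edges),
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, arr in cell_data.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x fastest, then y, then z
        flat = np.transpose(arr.astype(float), (2, 1, 0)).ravel()
        lines.extend(
            " ".join(f"{v:.6g}" for v in flat[i:i + 9])
            for i in range(0, flat.size, 9)
        )
    Path(path).write_text("\n".join(lines) + "\n")
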