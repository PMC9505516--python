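"""Structured voxel grid over the layered skin domain.

Cell-centred finite-volume grid: uniform spacing in x and y, graded in z so
that every layer interface coincides with a grid line and each layer —
including the 20 µm stratum corneum — is resolved by at least two voxels.
The origin is at the electrode-array centroid on the skin surface; z is
positive downward (depth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .skin import LayerStack
from .protocols import ElectrodeArray
from .units import MM

__all__ = ["Grid", "GridSpec", "PRESETS", "build_grid", "surface_contacts",
           "plate_contacts", "Contact"]


@dataclass(frozen=True)
class GridSpec:
    """Resolution specification: lateral cell counts and per-layer z cells."""

    nx: int
    ny: int
    layer_nz: tuple[int, ...]
    lateral_extent: float = 30.0 * MM

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3 or any(n < 1 for n in self.layer_nz):
            raise ValueError("resolution spec must be positive")
        if self.lateral_extent <= 0:
            raise ValueError("lateral extent must be positive")


#: resolution presets; `default` is the preset the protocol-comparison
#: metrics are evaluated at, `coarse` is for quick runs, `tiny` for smoke
#: tests only (too coarse for quantitative volume comparisons)
PRESETS: dict[str, GridSpec] = {
    "tiny": GridSpec(21, 21, (2, 1, 1, 1, 2, 2, 3, 4), lateral_extent=24e-3),
    "coarse": GridSpec(33, 33, (2, 2, 2, 2, 4, 4, 6, 8)),
    "default": GridSpec(51, 51, (2, 3, 3, 2, 5, 6, 9, 11)),
    "fine": GridSpec(69, 69, (3, 4, 4, 3, 7, 8, 12, 14)),
}


@dataclass(frozen=True, eq=False)
class Grid:
    """Cell-centred structured grid.

    ``x_edges``/``y_edges``/``z_edges`` are the cell boundary coordinates;
    centres and spacings are derived.  ``layer_of_k`` maps each z-slab of
    cells to its layer index in ``stack`` (layers are z-slabs, so the
    voxel→layer map depends on z only).
    """

    stack: LayerStack
    x_edges: np.ndarray
    y_edges: np.ndarray
    z_edges: np.ndarray
    layer_of_k: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.x_edges) - 1, len(self.y_edges) - 1,
                len(self.z_edges) - 1)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def dx(self) -> float:
        return float(self.x_edges[1] - self.x_edges[0])

    @property
    def dy(self) -> float:
        return float(self.y_edges[1] - self.y_edges[0])

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    def cell_volumes(self) -> np.ndarray:
        """Voxel volumes, shape (nx, ny, nz)."""
        nx, ny, nz = self.shape
        return np.broadcast_to(
            self.dx * self.dy * self.dz[None, None, :], (nx, ny, nz)
        ).copy()

    def domain_volume(self) -> float:
        ex = self.x_edges[-1] - self.x_edges[0]
        ey = self.y_edges[-1] - self.y_edges[0]
        return float(ex * ey * (self.z_edges[-1] - self.z_edges[0]))


def build_grid(
    stack: LayerStack,
    resolution: GridSpec | str = "default",
    lateral_extent: float | None = None,
) -> Grid:
    """Build a graded grid over ``stack``.

    ``resolution`` is a :class:`GridSpec` or a preset name.  The z grid
    lines include every layer interface and the stratum-corneum-like top
    layer keeps ≥ 2 voxels.
    """
    spec = PRESETS[resolution] if isinstance(resolution, str) else resolution
    if len(spec.layer_nz) != len(stack):
        raise ValueError(
            f"layer_nz has {len(spec.layer_nz)} entries for {len(stack)} layers"
        )
    if spec.layer_nz[0] < 2:
        raise ValueError("the top layer must be resolved by at least 2 voxels")
    ext = spec.lateral_extent if lateral_extent is None else lateral_extent
    x_edges = np.linspace(-ext / 2, ext / 2, spec.nx + 1)
    y_edges = np.linspace(-ext / 2, ext / 2, spec.ny + 1)
    zi = stack.z_interfaces
    z_parts = [
        np.linspace(zi[j], zi[j + 1], spec.layer_nz[j] + 1)[:-1]
        for j in range(len(stack))
    ]
    z_edges = np.concatenate(z_parts + [[zi[-1]]])
    layer_of_k = np.repeat(np.arange(len(stack)), spec.layer_nz)
    return Grid(stack=stack, x_edges=x_edges, y_edges=y_edges,
                z_edges=z_edges, layer_of_k=layer_of_k)


@dataclass(frozen=True)
class Contact:
    """A Dirichlet contact patch on the top or bottom face of the domain:
    ``mask`` selects the face cells under the contact."""

    face: Literal["top", "bottom"]
    mask: np.ndarray


def surface_contacts(grid: Grid, array: ElectrodeArray) -> dict[int, Contact]:
    """Contact masks of every electrode of ``array`` on the skin surface.

    Each electrode is a disc-shaped Dirichlet patch on the top face; a face
    cell belongs to the contact when its centre lies inside the disc.
    Raises a geometry error when an electrode extends beyond the grid or
    covers no cell at this resolution.
    """
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    half_x = grid.x_edges[-1]
    half_y = grid.y_edges[-1]
    out: dict[int, Contact] = {}
    for e in array.electrodes:
        cx, cy = e.center
        if (abs(cx) + e.contact_radius > half_x
                or abs(cy) + e.contact_radius > half_y):
            raise ValueError(
                f"electrode {e.id} extends beyond the grid footprint; "
                "increase the lateral extent"
            )
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= e.contact_radius**2
        if not mask.any():
            raise ValueError(
                f"electrode {e.id} covers no grid cell; refine the lateral "
                "resolution"
            )
        out[e.id] = Contact("top", mask)
    return out


#: pseudo-electrode ids of full-face plate contacts (validation geometries)
TOP_PLATE = -1
BOTTOM_PLATE = -2


def plate_contacts(grid: Grid) -> dict[int, Contact]:
    """Full-face plate contacts on the top and bottom of the domain, for
    parallel-plate validation geometries."""
    nx, ny, _ = grid.shape
    full = np.ones((nx, ny), dtype=bool)
    return {TOP_PLATE: Contact("top", full), BOTTOM_PLATE: Contact("bottom", full)}
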