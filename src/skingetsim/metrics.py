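"""Electroporation volume metrics and field slices.

A voxel is irreversibly electroporated (IRE) when its field envelope
reaches the layer's IRE threshold, and reversibly electroporated (RE) when
the envelope lies between the (direction-dependent, for muscle) RE
threshold and the IRE threshold.  RE is reported *exclusive* of IRE by
default — the two quantities compete in protocol design: RE volume is the
useful gene-delivery region, IRE volume is collateral damage — with an
inclusive variant available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .grid import Grid
from .solver import ElectroporationState, FieldSolution, _layer_params

__all__ = [
    "VolumeMetrics",
    "ProtocolComparison",
    "classify_voxels",
    "classify_and_measure",
    "compare_protocols",
    "field_slice",
    "vertical_slice",
]


@dataclass(frozen=True)
class VolumeMetrics:
    """RE/IRE volumes (m³), maximal RE depth (m) and per-layer breakdown."""

    re_volume: float
    ire_volume: float
    re_depth: float
    per_layer: Mapping[str, tuple[float, float]]
    inclusive_re: bool = False

    def __post_init__(self) -> None:
        sums = np.array(list(self.per_layer.values())).sum(axis=0) \
            if self.per_layer else np.zeros(2)
        if not (np.isclose(sums[0], self.re_volume)
                and np.isclose(sums[1], self.ire_volume)):
            raise ValueError("per-layer volumes do not sum to totals")

    def to_dict(self) -> dict:
        return {
            "re_volume_mm3": self.re_volume * 1e9,
            "ire_volume_mm3": self.ire_volume * 1e9,
            "re_depth_mm": self.re_depth * 1e3,
            "inclusive_re": self.inclusive_re,
            "per_layer_mm3": {
                name: {"re": re * 1e9, "ire": ire * 1e9}
                for name, (re, ire) in self.per_layer.items()
            },
        }


def classify_voxels(
    grid: Grid, state: ElectroporationState
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (re, ire) voxel masks from the field envelope.

    IRE: e_env ≥ layer IRE threshold.  RE: effective RE threshold ≤ e_env
    < IRE threshold, where muscle's effective RE threshold is evaluated at
    the envelope's field direction.  RE here is exclusive of IRE.
    """
    if state.e_env.shape != grid.shape:
        raise ValueError("state does not match grid")
    p = _layer_params(grid)
    e = state.e_env
    e_low = np.broadcast_to(p.re_perp, e.shape).copy()
    if p.has_fiber.any():
        ks = np.nonzero(p.has_fiber)[0]
        cos2 = np.clip(
            np.einsum("xyzc,zc->xyz", state.env_dir[:, :, ks, :],
                      p.fiber[ks]) ** 2,
            0.0, 1.0,
        )
        inv2 = cos2 / p.re_par[ks] ** 2 + (1.0 - cos2) / p.re_perp[ks] ** 2
        e_low[:, :, ks] = 1.0 / np.sqrt(inv2)
    ire = e >= p.ire
    re = (e >= e_low) & ~ire
    return re, ire


def classify_and_measure(
    grid: Grid,
    state: ElectroporationState,
    *,
    inclusive_re: bool = False,
) -> VolumeMetrics:
    """Classify every voxel against its layer's thresholds and integrate.

    Volumes are sums of voxel volumes; ``re_depth`` is the largest
    voxel-centre depth among RE voxels.  With ``inclusive_re=True`` the RE
    volume counts every voxel above the RE threshold, including IRE ones.
    """
    re, ire = classify_voxels(grid, state)
    if inclusive_re:
        re = re | ire
    vol = grid.cell_volumes()
    zc = grid.z_centers
    per_layer: dict[str, tuple[float, float]] = {}
    for j, layer in enumerate(grid.stack):
        sl = grid.layer_of_k == j
        per_layer[layer.name] = (
            float(vol[:, :, sl][re[:, :, sl]].sum()),
            float(vol[:, :, sl][ire[:, :, sl]].sum()),
        )
    depth = float(zc[np.any(re, axis=(0, 1))].max()) if re.any() else 0.0
    return VolumeMetrics(
        re_volume=float(vol[re].sum()),
        ire_volume=float(vol[ire].sum()),
        re_depth=depth,
        per_layer=per_layer,
        inclusive_re=inclusive_re,
    )


@dataclass(frozen=True)
class ProtocolComparison:
    """Percentage differences of protocol ``a`` against baseline ``b``."""

    re_gain_pct: float
    ire_reduction_pct: float
    depth_gain_mm: float
    undefined_re_ratio: bool = False
    undefined_ire_ratio: bool = False

    def to_dict(self) -> dict:
        return {
            "re_gain_pct": self.re_gain_pct,
            "ire_reduction_pct": self.ire_reduction_pct,
            "depth_gain_mm": self.depth_gain_mm,
            "undefined_re_ratio": self.undefined_re_ratio,
            "undefined_ire_ratio": self.undefined_ire_ratio,
        }


def compare_protocols(a: VolumeMetrics, b: VolumeMetrics) -> ProtocolComparison:
    """Compare protocol ``a`` to baseline ``b``.

    Returns 100·(a.re − b.re)/b.re (how much larger a's reversibly
    electroporated volume is) and 100·(b.ire − a.ire)/b.ire (how much a
    reduces irreversible damage), plus the RE depth difference.  A zero
    baseline volume flags the ratio as undefined (NaN) instead of raising.
    """
    if a.inclusive_re != b.inclusive_re:
        raise ValueError("metrics use different RE definitions")
    und_re = b.re_volume == 0
    und_ire = b.ire_volume == 0
    return ProtocolComparison(
        re_gain_pct=(np.nan if und_re
                     else 100.0 * (a.re_volume - b.re_volume) / b.re_volume),
        ire_reduction_pct=(np.nan if und_ire
                           else 100.0 * (b.ire_volume - a.ire_volume) / b.ire_volume),
        depth_gain_mm=(a.re_depth - b.re_depth) * 1e3,
        undefined_re_ratio=und_re,
        undefined_ire_ratio=und_ire,
    )


def _magnitude_of(obj) -> np.ndarray:
    if isinstance(obj, ElectroporationState):
        return obj.e_env
    if isinstance(obj, FieldSolution):
        return obj.e_mag
    return np.asarray(obj)


def field_slice(grid: Grid, obj, depth: float, *, log: bool = False) -> np.ndarray:
    """Field-magnitude map on the horizontal plane at the given depth.

    ``obj`` may be an :class:`ElectroporationState` (envelope), a
    :class:`FieldSolution` (step field) or a raw (nx, ny, nz) array.
    Values are interpolated linearly between the two bracketing voxel-centre
    planes.  With ``log=True`` the natural logarithm is returned (zeros
    clipped to the smallest positive value present).
    """
    F = _magnitude_of(obj)
    if not 0.0 <= depth < grid.stack.total_depth:
        raise ValueError("depth outside the domain")
    zc = grid.z_centers
    k = int(np.clip(np.searchsorted(zc, depth), 1, len(zc) - 1))
    w = np.clip((depth - zc[k - 1]) / (zc[k] - zc[k - 1]), 0.0, 1.0)
    out = (1.0 - w) * F[:, :, k - 1] + w * F[:, :, k]
    return _maybe_log(out, log)


def vertical_slice(grid: Grid, obj, y: float = 0.0, *, log: bool = False) -> np.ndarray:
    """Field-magnitude map on the vertical plane at lateral position ``y``
    (default: the mid-plane between the electrodes), shape (nx, nz)."""
    F = _magnitude_of(obj)
    yc = grid.y_centers
    if not yc[0] <= y <= yc[-1]:
        raise ValueError("y outside the grid")
    j = int(np.clip(np.searchsorted(yc, y), 1, len(yc) - 1))
    w = np.clip((y - yc[j - 1]) / (yc[j] - yc[j - 1]), 0.0, 1.0)
    out = (1.0 - w) * F[:, j - 1, :] + w * F[:, j, :]
    return _maybe_log(out, log)


def _maybe_log(a: np.ndarray, log: bool) -> np.ndarray:
    if not log:
        return a
    pos = a[a > 0]
    floor = pos.min() if pos.size else 1.0
    return np.log(np.maximum(a, floor))
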