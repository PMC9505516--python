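"""Layered anisotropic skin model and the field-dependent conductivity law.

The tissue domain is a stack of plane-parallel layers (stratum corneum down
to muscle), each with a diagonal conductivity tensor, reversible- and
irreversible-electroporation field thresholds, and a maximal conductivity
increase reached once the local field exceeds the irreversible threshold.
Electroporation raises the conductivity: the scaling factor follows a
sigmoid of the local field magnitude, rising from 1 at the reversible (RE)
threshold to the layer's maximal factor at the irreversible (IRE)
threshold.  Muscle is the one layer whose RE threshold depends on the angle
between the field and the fiber axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .units import V_PER_CM, MM, UM

__all__ = [
    "SkinLayer",
    "LayerStack",
    "ConductivityLaw",
    "default_skin_stack",
    "sigma_of_field",
]


@dataclass(frozen=True)
class SkinLayer:
    """One plane-parallel tissue layer.

    Parameters
    ----------
    name
        Layer label (e.g. ``"stratum_corneum"``).
    thickness
        Layer thickness in metres, > 0.
    sigma0
        Baseline diagonal conductivity tensor ``(σx, σy, σz)`` in S/m.
    re_threshold
        Reversible-electroporation field threshold in V/m.  For muscle this
        is the *perpendicular* (field ⊥ fiber) threshold.
    ire_threshold
        Irreversible-electroporation field threshold in V/m.
    max_sigma_factor
        Maximal conductivity increase (≥ 1) reached at/above the IRE
        threshold; applied as an isotropic scaling of ``sigma0``.
    fiber_axis
        Optional unit vector of the muscle-fiber direction; only muscle
        sets it.
    re_threshold_parallel
        RE threshold for a field parallel to ``fiber_axis`` (V/m); must be
        ≤ ``re_threshold``.  Only meaningful together with ``fiber_axis``.
    """

    name: str
    thickness: float
    sigma0: tuple[float, float, float]
    re_threshold: float
    ire_threshold: float
    max_sigma_factor: float
    fiber_axis: tuple[float, float, float] | None = None
    re_threshold_parallel: float | None = None

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"{self.name}: thickness must be > 0")
        if any(s <= 0 for s in self.sigma0):
            raise ValueError(f"{self.name}: conductivities must be > 0")
        if self.re_threshold > self.ire_threshold:
            raise ValueError(f"{self.name}: RE threshold exceeds IRE threshold")
        if self.max_sigma_factor < 1:
            raise ValueError(f"{self.name}: max_sigma_factor must be ≥ 1")
        if self.re_threshold_parallel is not None:
            if self.re_threshold_parallel > self.re_threshold:
                raise ValueError(
                    f"{self.name}: parallel RE threshold exceeds perpendicular one"
                )
        if self.fiber_axis is not None:
            ax = np.asarray(self.fiber_axis, dtype=float)
            n = np.linalg.norm(ax)
            if not np.isclose(n, 1.0):
                raise ValueError(f"{self.name}: fiber_axis must be a unit vector")

    @property
    def is_isotropic(self) -> bool:
        sx, sy, sz = self.sigma0
        return sx == sy == sz

    def effective_re_threshold(self, cos2: float | np.ndarray = 0.0):
        """RE threshold for a field whose squared cosine with the fiber axis
        is ``cos2``.

        Interpolates elliptically between the parallel and perpendicular
        thresholds, ``E_th(θ)⁻² = (cosθ/E_par)² + (sinθ/E_perp)²``; layers
        without a fiber axis return the scalar RE threshold unchanged.
        """
        if self.re_threshold_parallel is None:
            return np.broadcast_to(
                np.asarray(self.re_threshold), np.shape(cos2)
            ).copy() if np.ndim(cos2) else self.re_threshold
        cos2 = np.clip(np.asarray(cos2, dtype=float), 0.0, 1.0)
        inv2 = cos2 / self.re_threshold_parallel**2 + (1.0 - cos2) / self.re_threshold**2
        out = 1.0 / np.sqrt(inv2)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "thickness": self.thickness,
            "sigma0": list(self.sigma0),
            "re_threshold": self.re_threshold,
            "ire_threshold": self.ire_threshold,
            "max_sigma_factor": self.max_sigma_factor,
        }
        if self.fiber_axis is not None:
            d["fiber_axis"] = list(self.fiber_axis)
        if self.re_threshold_parallel is not None:
            d["re_threshold_parallel"] = self.re_threshold_parallel
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SkinLayer":
        units = d.get("units", {})
        lf = {"m": 1.0, "mm": MM, "um": UM}[units.get("thickness", "m")]
        ff = {"V/m": 1.0, "V/cm": V_PER_CM}[units.get("field", "V/m")]
        return cls(
            name=d["name"],
            thickness=d["thickness"] * lf,
            sigma0=tuple(d["sigma0"]),
            re_threshold=d["re_threshold"] * ff,
            ire_threshold=d["ire_threshold"] * ff,
            max_sigma_factor=d["max_sigma_factor"],
            fiber_axis=tuple(d["fiber_axis"]) if "fiber_axis" in d else None,
            re_threshold_parallel=(
                d["re_threshold_parallel"] * ff
                if "re_threshold_parallel" in d
                else None
            ),
        )


@dataclass(frozen=True)
class LayerStack:
    """Ordered stack of skin layers, top (skin surface, z = 0) to bottom."""

    layers: tuple[SkinLayer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack must contain at least one layer")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")

    @property
    def z_interfaces(self) -> np.ndarray:
        """Depths of the layer boundaries: 0, d1, d1+d2, … (metres)."""
        return np.concatenate(
            [[0.0], np.cumsum([l.thickness for l in self.layers])]
        )

    @property
    def total_depth(self) -> float:
        return float(sum(l.thickness for l in self.layers))

    def layer_at_depth(self, z: float) -> SkinLayer:
        """Layer whose half-open interval [z_top, z_bottom) contains ``z``."""
        if not 0.0 <= z < self.total_depth:
            raise ValueError(
                f"depth {z!r} outside the domain [0, {self.total_depth})"
            )
        idx = int(np.searchsorted(self.z_interfaces, z, side="right") - 1)
        return self.layers[idx]

    def layer_index_at_depth(self, z: np.ndarray) -> np.ndarray:
        """Vectorised layer index lookup (voxel→layer map helper)."""
        z = np.asarray(z, dtype=float)
        if np.any(z < 0) or np.any(z >= self.total_depth):
            raise ValueError("depth outside the domain")
        return np.searchsorted(self.z_interfaces, z, side="right") - 1

    def __iter__(self) -> Iterable[SkinLayer]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, key):
        if isinstance(key, str):
            for l in self.layers:
                if l.name == key:
                    return l
            raise KeyError(key)
        return self.layers[key]

    def to_dict(self) -> dict:
        return {"layers": [l.to_dict() for l in self.layers]}

    @classmethod
    def from_dict(cls, d: dict) -> "LayerStack":
        return cls(tuple(SkinLayer.from_dict(ld) for ld in d["layers"]))


@dataclass(frozen=True)
class ConductivityLaw:
    """Sigmoid conductivity-increase law.

    The per-layer scaling factor is

        f(E) = 1 + (max_factor − 1) · g(t),   t = (E − E_re) / (E_ire − E_re)

    with ``g`` an endpoint-normalised logistic of steepness ``k``:
    g(t) = (L(t) − L(0)) / (L(1) − L(0)), L(t) = 1 / (1 + exp(−k(t − ½))),
    and ``t`` clamped to [0, 1].  Thus f = 1 exactly at and below the RE
    threshold, f = max_factor exactly at and above the IRE threshold, and
    f = (1 + max_factor)/2 at the midpoint.  ``k`` controls how sharply the
    transition is confined to the middle of the RE→IRE band.
    """

    steepness: float = 10.0

    def ramp(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        k = self.steepness
        lo = 1.0 / (1.0 + np.exp(k / 2.0))
        hi = 1.0 / (1.0 + np.exp(-k / 2.0))
        L = 1.0 / (1.0 + np.exp(-k * (t - 0.5)))
        out = (L - lo) / (hi - lo)
        return float(out) if out.ndim == 0 else out

    def factor(
        self,
        e_mag: np.ndarray | float,
        e_low: np.ndarray | float,
        e_high: np.ndarray | float,
        max_factor: np.ndarray | float,
    ) -> np.ndarray | float:
        """Conductivity scaling factor for field magnitude ``e_mag``."""
        e_mag = np.asarray(e_mag, dtype=float)
        if np.any(e_mag < 0):
            raise ValueError("field magnitude must be non-negative")
        t = (e_mag - e_low) / (np.asarray(e_high) - e_low)
        out = 1.0 + (np.asarray(max_factor) - 1.0) * self.ramp(t)
        return float(out) if out.ndim == 0 else out


def sigma_of_field(
    layer: SkinLayer,
    law: ConductivityLaw,
    e_mag: float,
    e_dir: Sequence[float] | None = None,
) -> np.ndarray:
    """Diagonal conductivity tensor of ``layer`` at field magnitude ``e_mag``.

    ``e_dir`` (a unit vector) is consulted only for layers with a fiber
    axis, where the effective RE threshold interpolates between the
    parallel and perpendicular values.
    """
    if e_mag < 0:
        raise ValueError("field magnitude must be non-negative")
    cos2 = 0.0
    if layer.fiber_axis is not None and e_dir is not None:
        ax = np.asarray(layer.fiber_axis, dtype=float)
        d = np.asarray(e_dir, dtype=float)
        n = np.linalg.norm(d)
        if n > 0:
            cos2 = float(np.dot(ax, d / n) ** 2)
    e_low = layer.effective_re_threshold(cos2)
    f = law.factor(e_mag, e_low, layer.ire_threshold, layer.max_sigma_factor)
    return np.asarray(layer.sigma0, dtype=float) * f


def default_skin_stack() -> LayerStack:
    """The eight-layer skin stack used throughout: thicknesses, anisotropic
    baseline conductivities, RE/IRE thresholds and maximal conductivity
    increases of the published skin model (thresholds converted from V/cm).

    Muscle carries both RE thresholds (200 V/cm perpendicular, 80 V/cm
    parallel to the fibers) and a fiber axis along the direction of its
    largest conductivity component (y).
    """
    L = SkinLayer
    return LayerStack((
        L("stratum_corneum", 20 * UM, (1.10e-2, 1.10e-2, 2.23e-4),
          400 * V_PER_CM, 1200 * V_PER_CM, 100.0),
        L("epidermis", 0.1 * MM, (5.82e-2, 5.82e-2, 6.36e-2),
          400 * V_PER_CM, 1200 * V_PER_CM, 3.5),
        L("papillary_dermis", 0.15 * MM, (7.19e-2, 7.19e-2, 7.19e-2),
          300 * V_PER_CM, 1200 * V_PER_CM, 3.5),
        L("upper_vessel_plexus", 80 * UM, (4.22e-1, 3.86e-1, 3.86e-1),
          300 * V_PER_CM, 1200 * V_PER_CM, 3.5),
        L("supply_layer", 1.0 * MM, (3.12e-1, 3.12e-1, 3.19e-1),
          300 * V_PER_CM, 1200 * V_PER_CM, 3.5),
        L("deeper_vessel_plexus", 1.0 * MM, (3.42e-1, 3.28e-1, 3.28e-1),
          300 * V_PER_CM, 1200 * V_PER_CM, 3.5),
        L("hypodermis", 5.0 * MM, (6.35e-2, 6.35e-2, 6.35e-2),
          300 * V_PER_CM, 1200 * V_PER_CM, 3.5),
        L("muscle", 20.0 * MM, (1.57e-2, 6.86e-2, 1.57e-2),
          200 * V_PER_CM, 800 * V_PER_CM, 2.5,
          fiber_axis=(0.0, 1.0, 0.0), re_threshold_parallel=80 * V_PER_CM),
    ))
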