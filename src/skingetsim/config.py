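"""Run configuration: every knob of a protocol-comparison experiment in one
validated, serialisable record.

Defaults are the study conditions: the eight-layer skin stack, 560 V per
activation step, sigmoid steepness 10, the ``default`` grid preset, damped
Picard iteration (damping 0.5, tolerance 1e-3 on |E|, max 50 iterations),
and the reversible-only RE volume definition.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import yaml

from .grid import PRESETS, GridSpec
from .skin import ConductivityLaw, LayerStack, default_skin_stack
from .units import MM

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration of a classical-vs-alternative comparison run."""

    amplitude: float = 560.0
    law_steepness: float = 10.0
    resolution: str = "default"
    lateral_extent_mm: float | None = None
    solver_tol: float = 1e-3
    solver_max_iter: int = 50
    solver_damping: float = 0.5
    inclusive_re: bool = False
    diagonal_mode: Literal["single", "paired"] = "paired"
    hex_contact_radius_mm: float | None = None
    seed: int = 0
    stack: dict | None = None          # serialized layer stack; None = default
    out_dir: str | None = None
    export_vtk: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.resolution not in PRESETS:
            raise ValueError(
                f"resolution must be one of {sorted(PRESETS)}"
            )
        if not 0 < self.solver_damping <= 1:
            raise ValueError("solver_damping must be in (0, 1]")
        if self.solver_tol <= 0 or self.solver_max_iter < 1:
            raise ValueError("bad solver tolerances")
        if self.diagonal_mode not in ("single", "paired"):
            raise ValueError("diagonal_mode must be 'single' or 'paired'")

    # -- derived objects -------------------------------------------------
    def layer_stack(self) -> LayerStack:
        return (LayerStack.from_dict(self.stack) if self.stack
                else default_skin_stack())

    def conductivity_law(self) -> ConductivityLaw:
        return ConductivityLaw(steepness=self.law_steepness)

    def grid_spec(self) -> GridSpec:
        spec = PRESETS[self.resolution]
        if self.lateral_extent_mm is not None:
            spec = GridSpec(spec.nx, spec.ny, spec.layer_nz,
                            self.lateral_extent_mm * MM)
        return spec

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
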