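import numpy as np
import pytest

from skingetsim import ConductivityLaw, LayerStack, SkinLayer, default_skin_stack
from skingetsim.grid import GridSpec, build_grid


@pytest.fixture(scope="session")
def full_stack() -> LayerStack:
    return default_skin_stack()


@pytest.fixture(scope="session")
def law() -> ConductivityLaw:
    return ConductivityLaw()


@pytest.fixture(scope="session")
def tiny_grid(full_stack):
    """A very coarse grid over the full layer stack for fast solver tests."""
    spec = GridSpec(21, 21, (2, 1, 1, 1, 2, 2, 3, 4), lateral_extent=24e-3)
    return build_grid(full_stack, spec)


def make_slab_stack(*layers):
    """Slab stacks for analytic validation: (name, thickness, sigma) with
    thresholds far above any applied field, so conductivity stays linear."""
    return LayerStack(tuple(
        SkinLayer(name, t, (s, s, s), 1e12, 2e12, 1.0)
        for name, t, s in layers
    ))
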