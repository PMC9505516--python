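"""Voxel classification, volume metrics, comparisons and slices."""

import numpy as np
import pytest

from skingetsim import (
    VolumeMetrics,
    classify_and_measure,
    compare_protocols,
    field_slice,
    vertical_slice,
)
from skingetsim.solver import ElectroporationState
from skingetsim.units import V_PER_CM


def synthetic_state(grid, assignments):
    """Envelope with prescribed values: assignments is a list of
    (layer_index, n_voxels, field_v_per_m)."""
    state = ElectroporationState.zeros(grid)
    for layer_idx, n, value in assignments:
        ks = np.nonzero(grid.layer_of_k == layer_idx)[0]
        placed = 0
        for k in ks:
            nx, ny, _ = grid.shape
            for i in range(nx):
                for j in range(ny):
                    if placed < n and state.e_env[i, j, k] == 0:
                        state.e_env[i, j, k] = value
                        state.env_dir[i, j, k] = (0, 0, 1)
                        placed += 1
        assert placed == n
    return state


class TestClassification:
    def test_zero_envelope_gives_zero_volumes(self, tiny_grid):
        state = ElectroporationState.zeros(tiny_grid)
        m = classify_and_measure(tiny_grid, state)
        assert m.re_volume == 0.0
        assert m.ire_volume == 0.0
        assert m.re_depth == 0.0

    def test_hand_counted_hypodermis_voxels(self, tiny_grid):
        # hypodermis thresholds: RE 300 V/cm, IRE 1200 V/cm
        hypo = next(i for i, l in enumerate(tiny_grid.stack)
                    if l.name == "hypodermis")
        state = synthetic_state(
            tiny_grid,
            [(hypo, 10, 500 * V_PER_CM)],
        )
        # place 3 IRE voxels on top of different cells
        ks = np.nonzero(tiny_grid.layer_of_k == hypo)[0]
        state.e_env[0, 0, ks[-1]] = 1500 * V_PER_CM
        state.e_env[1, 0, ks[-1]] = 1500 * V_PER_CM
        state.e_env[2, 0, ks[-1]] = 1500 * V_PER_CM
        m = classify_and_measure(tiny_grid, state)
        vol = tiny_grid.cell_volumes()
        voxel = float(vol[0, 0, ks[0]])
        assert m.re_volume == pytest.approx(10 * voxel)
        assert m.ire_volume == pytest.approx(3 * voxel)
        assert m.per_layer["hypodermis"] == pytest.approx((10 * voxel, 3 * voxel))

    def test_ire_voxels_also_exceed_re(self, tiny_grid):
        from skingetsim import classify_voxels

        state = ElectroporationState.zeros(tiny_grid)
        rng = np.random.default_rng(0)
        state.e_env = rng.uniform(0, 2e5, size=tiny_grid.shape)
        re, ire = classify_voxels(tiny_grid, state)
        assert not (re & ire).any()
        # inclusive definition: every IRE voxel is above its RE threshold
        m_incl = classify_and_measure(tiny_grid, state, inclusive_re=True)
        m_excl = classify_and_measure(tiny_grid, state)
        assert m_incl.re_volume == pytest.approx(
            m_excl.re_volume + m_excl.ire_volume)

    def test_per_layer_sums_to_totals(self, tiny_grid):
        state = ElectroporationState.zeros(tiny_grid)
        rng = np.random.default_rng(1)
        state.e_env = rng.uniform(0, 2e5, size=tiny_grid.shape)
        m = classify_and_measure(tiny_grid, state)
        re_sum = sum(v[0] for v in m.per_layer.values())
        ire_sum = sum(v[1] for v in m.per_layer.values())
        assert re_sum == pytest.approx(m.re_volume)
        assert ire_sum == pytest.approx(m.ire_volume)
        assert m.re_volume + m.ire_volume <= tiny_grid.domain_volume()

    def test_muscle_uses_directional_threshold(self, tiny_grid):
        muscle = next(i for i, l in enumerate(tiny_grid.stack)
                      if l.name == "muscle")
        ks = np.nonzero(tiny_grid.layer_of_k == muscle)[0]
        e = 100 * V_PER_CM  # between parallel (80) and perpendicular (200)
        state = ElectroporationState.zeros(tiny_grid)
        state.e_env[0, 0, ks[0]] = e
        state.env_dir[0, 0, ks[0]] = (0, 1, 0)  # parallel to fibers
        state.e_env[1, 0, ks[0]] = e
        state.env_dir[1, 0, ks[0]] = (1, 0, 0)  # perpendicular
        m = classify_and_measure(tiny_grid, state)
        voxel = float(tiny_grid.cell_volumes()[0, 0, ks[0]])
        assert m.re_volume == pytest.approx(voxel)  # only the parallel voxel

    def test_mismatched_state_rejected(self, tiny_grid, full_stack):
        from skingetsim.grid import GridSpec, build_grid

        other = build_grid(full_stack,
                           GridSpec(5, 5, (2, 1, 1, 1, 1, 1, 1, 1)))
        state = ElectroporationState.zeros(other)
        with pytest.raises(ValueError):
            classify_and_measure(tiny_grid, state)


class TestComparison:
    def make_metrics(self, re, ire, depth=1e-3):
        return VolumeMetrics(re_volume=re, ire_volume=ire, re_depth=depth,
                             per_layer={"all": (re, ire)})

    def test_identical_inputs_zero_percent(self):
        m = self.make_metrics(1.0e-9, 0.5e-9)
        c = compare_protocols(m, m)
        assert c.re_gain_pct == 0.0
        assert c.ire_reduction_pct == 0.0

    def test_eight_percent_gain_arithmetic(self):
        a = self.make_metrics(1.08e-9, 0.85e-9)
        b = self.make_metrics(1.00e-9, 1.00e-9)
        c = compare_protocols(a, b)
        assert c.re_gain_pct == pytest.approx(8.0)
        assert c.ire_reduction_pct == pytest.approx(15.0)

    def test_zero_baseline_flags_undefined(self):
        a = self.make_metrics(1.0e-9, 0.0)
        b = self.make_metrics(0.0, 0.0)
        c = compare_protocols(a, b)
        assert c.undefined_re_ratio and c.undefined_ire_ratio
        assert np.isnan(c.re_gain_pct)

    def test_mixed_definitions_rejected(self):
        a = self.make_metrics(1.0e-9, 0.0)
        b = VolumeMetrics(re_volume=1e-9, ire_volume=0.0, re_depth=0.0,
                          per_layer={"all": (1e-9, 0.0)}, inclusive_re=True)
        with pytest.raises(ValueError):
            compare_protocols(a, b)


class TestSlices:
    def test_uniform_envelope_slices_flat(self, tiny_grid):
        state = ElectroporationState.zeros(tiny_grid)
        state.e_env[:] = 123.0
        sl = field_slice(tiny_grid, state, 2e-3)
        assert sl.shape == tiny_grid.shape[:2]
        assert np.allclose(sl, 123.0)
        vs = vertical_slice(tiny_grid, state, 0.0)
        assert vs.shape == (tiny_grid.shape[0], tiny_grid.shape[2])
        assert np.allclose(vs, 123.0)

    def test_zero_state_gives_zero_map(self, tiny_grid):
        state = ElectroporationState.zeros(tiny_grid)
        assert not field_slice(tiny_grid, state, 2e-3).any()

    def test_out_of_domain_depth_rejected(self, tiny_grid):
        state = ElectroporationState.zeros(tiny_grid)
        with pytest.raises(ValueError):
            field_slice(tiny_grid, state, 1.0)

    def test_log_slice_monotone_transform(self, tiny_grid):
        state = ElectroporationState.zeros(tiny_grid)
        rng = np.random.default_rng(2)
        state.e_env = rng.uniform(1.0, 1e5, size=tiny_grid.shape)
        lin = field_slice(tiny_grid, state, 2e-3)
        logm = field_slice(tiny_grid, state, 2e-3, log=True)
        assert np.allclose(np.exp(logm), lin)

    def test_single_diagonal_slice_peaks_near_contacts(self, tiny_grid, law):
        from skingetsim import ProtocolStep, build_array
        from skingetsim.grid import surface_contacts
        from skingetsim.solver import solve_step

        array = build_array("hex6")
        contacts = surface_contacts(tiny_grid, array)
        step = ProtocolStep(frozenset([1]), frozenset([4]), 560.0)
        state = ElectroporationState.zeros(tiny_grid)
        sol = solve_step(tiny_grid, state, step, law, contacts)
        sl = field_slice(tiny_grid, sol, 0.5e-3)
        # the field maximum lies within one contact radius of an active
        # electrode's lateral position
        i, j = np.unravel_index(sl.argmax(), sl.shape)
        pos = np.array([tiny_grid.x_centers[i], tiny_grid.y_centers[j]])
        d = min(np.linalg.norm(pos - np.asarray(array[e].center))
                for e in (1, 4))
        assert d <= array[1].contact_radius + max(tiny_grid.dx, tiny_grid.dy)
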