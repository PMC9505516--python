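"""Field solver: analytic oracles, conservation, and sequential memory."""

import numpy as np
import pytest

from skingetsim import (
    ConductivityLaw,
    ProtocolStep,
    Protocol,
    PulseTrain,
    SolverError,
    build_array,
    generate_protocol,
)
from skingetsim.grid import (
    BOTTOM_PLATE,
    TOP_PLATE,
    GridSpec,
    build_grid,
    plate_contacts,
    surface_contacts,
)
from skingetsim.solver import ElectroporationState, run_protocol, solve_step

from conftest import make_slab_stack


def plate_step(amplitude):
    return ProtocolStep(frozenset([TOP_PLATE]), frozenset([BOTTOM_PLATE]),
                        amplitude)


class TestAnalyticOracles:
    def test_parallel_plate_uniform_field(self, law):
        # |E| = U/d everywhere in a homogeneous slab
        stack = make_slab_stack(("slab", 1e-2, 0.2))
        grid = build_grid(stack, GridSpec(8, 8, (10,), lateral_extent=1e-2))
        state = ElectroporationState.zeros(grid)
        sol = solve_step(grid, state, plate_step(10.0), law,
                         plate_contacts(grid))
        expected = 10.0 / 1e-2
        assert np.abs(sol.e_mag - expected).max() / expected < 1e-3
        assert sol.converged

    def test_parallel_plate_current(self, law):
        # I = sigma * A * U / d
        stack = make_slab_stack(("slab", 1e-2, 0.2))
        grid = build_grid(stack, GridSpec(6, 6, (8,), lateral_extent=1e-2))
        state = ElectroporationState.zeros(grid)
        sol = solve_step(grid, state, plate_step(10.0), law,
                         plate_contacts(grid))
        expected = 0.2 * 1e-4 * 10.0 / 1e-2
        assert sol.anode_current == pytest.approx(expected, rel=1e-6)

    def test_two_layer_slab_series_resistance(self, law):
        # E1 = U/(d1 + d2*s1/s2), E2 = E1*s1/s2 (1D voltage division)
        U, d1, d2, s1, s2 = 100.0, 2e-3, 8e-3, 0.1, 0.4
        stack = make_slab_stack(("a", d1, s1), ("b", d2, s2))
        grid = build_grid(stack, GridSpec(4, 4, (20, 40), lateral_extent=5e-3))
        state = ElectroporationState.zeros(grid)
        sol = solve_step(grid, state, plate_step(U), law, plate_contacts(grid))
        E1 = U / (d1 + d2 * s1 / s2)
        E2 = E1 * s1 / s2
        in1 = grid.layer_of_k == 0
        assert np.abs(sol.e_mag[:, :, in1] - E1).max() / E1 < 1e-2
        assert np.abs(sol.e_mag[:, :, ~in1] - E2).max() / E2 < 1e-2

    def test_eight_layer_slab_matches_resistor_network(self, full_stack, law):
        # independent oracle: 1D series-resistance voltage division across
        # all layers of the full stack (fields kept below all thresholds)
        U = 0.5
        spec = GridSpec(4, 4, (2, 2, 2, 2, 4, 4, 8, 10), lateral_extent=5e-3)
        grid = build_grid(full_stack, spec)
        state = ElectroporationState.zeros(grid)
        sol = solve_step(grid, state, plate_step(U), law, plate_contacts(grid))
        sz = np.array([l.sigma0[2] for l in full_stack])
        th = np.array([l.thickness for l in full_stack])
        r_total = np.sum(th / sz)
        e_layers = (U / r_total) / sz  # J/sigma_z per layer
        for j, e_expect in enumerate(e_layers):
            sl = grid.layer_of_k == j
            err = np.abs(sol.e_mag[:, :, sl] - e_expect).max() / e_expect
            assert err < 1e-2, full_stack[j].name


class TestConservationAndSymmetry:
    def test_current_conservation_hex_step(self, tiny_grid, law):
        array = build_array("hex6")
        protocol = generate_protocol(array, "alternative")
        contacts = surface_contacts(tiny_grid, array)
        state = ElectroporationState.zeros(tiny_grid)
        sol = solve_step(tiny_grid, state, protocol.steps[0], law, contacts)
        assert sol.current_imbalance() < 0.01

    def test_polarity_reversal_gives_identical_field(self, tiny_grid, law):
        array = build_array("hex6")
        contacts = surface_contacts(tiny_grid, array)
        step = ProtocolStep(frozenset([1]), frozenset([4]), 560.0)
        state_a = ElectroporationState.zeros(tiny_grid)
        sol_a = solve_step(tiny_grid, state_a, step, law, contacts)
        state_b = ElectroporationState.zeros(tiny_grid)
        sol_b = solve_step(tiny_grid, state_b, step.reversed(), law, contacts)
        assert np.allclose(sol_a.e_mag, sol_b.e_mag, rtol=1e-2, atol=1.0)

    def test_reused_reversal_matches_full_solve(self, tiny_grid, law):
        array = build_array("hex6")
        step = ProtocolStep(frozenset([2]), frozenset([5]), 560.0)
        train = PulseTrain(Ap=560.0, Tp=100e-6, NrP=4, PRR=5000.0)
        protocol = Protocol(steps=(step, step.reversed()), train=train,
                            name="alternative")
        st_fast, sols_fast = run_protocol(
            tiny_grid, protocol, law, array=array, reuse_reversed=True)
        st_full, sols_full = run_protocol(
            tiny_grid, protocol, law, array=array, reuse_reversed=False)
        assert sols_fast[1].reused and not sols_full[1].reused
        # agreement wherever the field is significant (the convergence
        # tolerance is relative to the peak field)
        scale = st_full.e_env.max()
        assert np.abs(st_fast.e_env - st_full.e_env).max() < 2e-2 * scale
        sig = st_full.e_env > 1e-2 * scale
        rel = np.abs(st_fast.e_env - st_full.e_env)[sig] / st_full.e_env[sig]
        assert rel.max() < 5e-2


class TestSequentialMemory:
    def test_envelope_monotone_over_protocol(self, tiny_grid, law):
        array = build_array("hex6")
        protocol = generate_protocol(array, "alternative")
        contacts = surface_contacts(tiny_grid, array)
        state = ElectroporationState.zeros(tiny_grid)
        prev = state.e_env.copy()
        for i, step in enumerate(protocol.steps[:6]):
            sol = solve_step(tiny_grid, state, step, law, contacts,
                             step_index=i)
            state.update_envelope(law, sol)
            assert (state.e_env >= prev - 1e-12).all()
            prev = state.e_env.copy()

    def test_repeated_step_is_absorbed(self, tiny_grid, law):
        # once the envelope has absorbed a step, re-running it changes the
        # electroporated volumes by (at most) the solver tolerance
        from skingetsim import classify_and_measure

        array = build_array("hex6")
        contacts = surface_contacts(tiny_grid, array)
        step = ProtocolStep(frozenset([1]), frozenset([4]), 560.0)
        state = ElectroporationState.zeros(tiny_grid)
        sol1 = solve_step(tiny_grid, state, step, law, contacts)
        state.update_envelope(law, sol1)
        m1 = classify_and_measure(tiny_grid, state)
        sol2 = solve_step(tiny_grid, state, step, law, contacts)
        state.update_envelope(law, sol2)
        m2 = classify_and_measure(tiny_grid, state)
        scale = sol1.e_mag.max()
        assert np.abs(sol2.e_mag - sol1.e_mag).max() < 2e-2 * scale
        assert m2.re_volume == pytest.approx(m1.re_volume, rel=0.03)
        assert m2.ire_volume == pytest.approx(m1.ire_volume, rel=0.03)

    def test_zero_amplitude_leaves_state_untouched(self, tiny_grid, law):
        array = build_array("hex6")
        train = PulseTrain(Ap=560.0, Tp=100e-6, NrP=4, PRR=5000.0)
        step = ProtocolStep(frozenset([1]), frozenset([4]), 0.0)
        protocol = Protocol(steps=(step, step.reversed()), train=train,
                            name="alternative")
        state, _ = run_protocol(tiny_grid, protocol, law, array=array)
        assert not state.e_env.any()
        assert (state.factor == 1.0).all()

    def test_step_order_insensitivity(self, tiny_grid, law):
        # stationary-sequential envelope: permuting the steps leaves the
        # electroporated volumes (nearly) unchanged
        from skingetsim import classify_and_measure

        array = build_array("hex6")
        train = PulseTrain(Ap=560.0, Tp=100e-6, NrP=4, PRR=5000.0)
        steps = [
            ProtocolStep(frozenset([1]), frozenset([2]), 560.0),
            ProtocolStep(frozenset([2]), frozenset([1]), 560.0),
            ProtocolStep(frozenset([1]), frozenset([4]), 560.0),
            ProtocolStep(frozenset([4]), frozenset([1]), 560.0),
        ]
        fwd = Protocol(steps=tuple(steps), train=train, name="alternative")
        rev = Protocol(steps=tuple(steps[::-1]), train=train,
                       name="alternative")
        st_f, _ = run_protocol(tiny_grid, fwd, law, array=array)
        st_r, _ = run_protocol(tiny_grid, rev, law, array=array)
        m_f = classify_and_measure(tiny_grid, st_f)
        m_r = classify_and_measure(tiny_grid, st_r)
        assert m_f.re_volume == pytest.approx(m_r.re_volume, rel=0.05)
        assert m_f.ire_volume == pytest.approx(m_r.ire_volume, rel=0.05)

    def test_voltage_monotonicity_of_envelope(self, tiny_grid, law):
        array = build_array("hex6")
        train = PulseTrain(Ap=560.0, Tp=100e-6, NrP=4, PRR=5000.0)

        def envelope(amp):
            step = ProtocolStep(frozenset([1]), frozenset([4]), amp)
            protocol = Protocol(steps=(step, step.reversed()), train=train,
                                name="alternative")
            state, _ = run_protocol(tiny_grid, protocol, law, array=array)
            return state.e_env

        lo = envelope(280.0)
        hi = envelope(560.0)
        # doubling the amplitude must not decrease the envelope anywhere
        # (small numerical slack for the Picard tolerance)
        assert (hi >= lo * (1 - 5e-2)).all()
        assert hi.max() > lo.max()


class TestErrors:
    def test_missing_contact_raises(self, tiny_grid, law):
        array = build_array("hex6")
        contacts = surface_contacts(tiny_grid, array)
        step = ProtocolStep(frozenset([99]), frozenset([1]), 100.0)
        state = ElectroporationState.zeros(tiny_grid)
        with pytest.raises(SolverError):
            solve_step(tiny_grid, state, step, law, contacts)

    def test_electrode_outside_grid_rejected(self, full_stack):
        small = build_grid(
            full_stack,
            GridSpec(5, 5, (2, 1, 1, 1, 1, 1, 1, 1), lateral_extent=4e-3),
        )
        with pytest.raises(ValueError):
            surface_contacts(small, build_array("hex6"))
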