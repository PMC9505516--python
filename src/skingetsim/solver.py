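"""Stationary nonlinear electric-field solver with sequential
electroporation memory.

Each activation step solves the current-conservation equation
∇·(σ(E) ∇φ) = 0 on the voxel grid with Dirichlet potentials on the active
electrode contacts and zero normal current on every other boundary.  The
conductivity depends on the local field through the sigmoid law, so within
a step the solution is iterated to a self-consistent fixed point (damped
Picard iteration).  Electroporation is modelled as persistent: across steps
the per-voxel *field envelope* — the maximum converged |E| seen so far —
determines the conductivity state, so a region permeabilised by one pulse
stays conductive for all later pulses.

Discretisation is cell-centred finite volume with harmonic averaging of
face conductivities, which keeps the normal current density continuous
across layer interfaces and reproduces the 1D series-resistance solution
exactly on layered slabs.  The linear systems are solved with
ILU-preconditioned BiCGSTAB on a symmetrically diagonal-scaled matrix,
warm-started between Picard iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import Contact, Grid, surface_contacts
from .protocols import ElectrodeArray, Protocol, ProtocolStep
from .skin import ConductivityLaw

__all__ = [
    "ElectroporationState",
    "FieldSolution",
    "SolverError",
    "solve_step",
    "run_protocol",
]

log = logging.getLogger(__name__)

_TINY = 1e-300


class SolverError(RuntimeError):
    pass


class _LayerParams:
    """Per-z-slab layer parameters broadcast to solver arrays."""

    def __init__(self, grid: Grid):
        stack = grid.stack
        k = grid.layer_of_k
        s0 = np.array([l.sigma0 for l in stack])  # (n_layers, 3)
        self.s0x = s0[k, 0]
        self.s0y = s0[k, 1]
        self.s0z = s0[k, 2]
        self.re_perp = np.array([l.re_threshold for l in stack])[k]
        self.ire = np.array([l.ire_threshold for l in stack])[k]
        self.max_factor = np.array([l.max_sigma_factor for l in stack])[k]
        re_par = np.array(
            [l.re_threshold_parallel if l.re_threshold_parallel is not None
             else np.nan for l in stack]
        )[k]
        self.re_par = re_par
        fib = np.array(
            [l.fiber_axis if l.fiber_axis is not None else (0.0, 0.0, 0.0)
             for l in stack]
        )[k]  # (nz, 3)
        self.fiber = fib
        self.has_fiber = ~np.isnan(re_par)


_params_cache: dict[int, _LayerParams] = {}


def _layer_params(grid: Grid) -> _LayerParams:
    p = _params_cache.get(id(grid))
    if p is None:
        p = _params_cache[id(grid)] = _LayerParams(grid)
    return p


def conductivity_factor(
    grid: Grid,
    law: ConductivityLaw,
    e_mag: np.ndarray,
    e_dir: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel conductivity scaling factor for field magnitudes ``e_mag``
    (shape nx,ny,nz) with optional field directions ``e_dir``
    (shape nx,ny,nz,3, unit or zero vectors) used for the direction-dependent
    muscle RE threshold."""
    p = _layer_params(grid)
    e_low = np.broadcast_to(p.re_perp, e_mag.shape).copy()
    if e_dir is not None and p.has_fiber.any():
        ks = np.nonzero(p.has_fiber)[0]
        cos2 = np.clip(
            np.einsum("xyzc,zc->xyz", e_dir[:, :, ks, :], p.fiber[ks]) ** 2,
            0.0, 1.0,
        )
        inv2 = (cos2 / p.re_par[ks] ** 2
                + (1.0 - cos2) / p.re_perp[ks] ** 2)
        e_low[:, :, ks] = 1.0 / np.sqrt(inv2)
    return law.factor(e_mag, e_low, p.ire, p.max_factor)


@dataclass(eq=False)
class ElectroporationState:
    """Per-voxel electroporation memory of a running protocol.

    ``e_env`` is the envelope — max over completed steps of the converged
    field magnitude; ``env_dir`` the field direction at which the envelope
    was attained (unit vectors, zero where no field has been seen);
    ``factor`` the current conductivity scaling, always in
    [1, max_sigma_factor].
    """

    grid: Grid
    e_env: np.ndarray
    env_dir: np.ndarray
    factor: np.ndarray

    @classmethod
    def zeros(cls, grid: Grid) -> "ElectroporationState":
        shape = grid.shape
        return cls(
            grid=grid,
            e_env=np.zeros(shape),
            env_dir=np.zeros(shape + (3,)),
            factor=np.ones(shape),
        )

    def conductivity(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Current per-voxel diagonal conductivity (σx, σy, σz) arrays."""
        p = _layer_params(self.grid)
        return p.s0x * self.factor, p.s0y * self.factor, p.s0z * self.factor

    def update_envelope(self, law: ConductivityLaw, sol: "FieldSolution") -> None:
        """Absorb a converged step into the envelope and refresh σ."""
        grow = sol.e_mag > self.e_env
        self.e_env = np.where(grow, sol.e_mag, self.e_env)
        mag = np.maximum(sol.e_mag, _TINY)
        unit = sol.E / mag[..., None]
        self.env_dir = np.where(grow[..., None], unit, self.env_dir)
        self.factor = conductivity_factor(self.grid, law, self.e_env, self.env_dir)


@dataclass(eq=False)
class FieldSolution:
    """Converged solution of one protocol step."""

    step_index: int
    phi: np.ndarray              # potential per cell (V)
    E: np.ndarray                # field vectors per cell (nx, ny, nz, 3), V/m
    e_mag: np.ndarray            # |E| per cell (V/m)
    currents: dict[int, float]   # electrode id -> injected current (A)
    converged: bool
    n_iterations: int
    reused: bool = False

    @property
    def anode_current(self) -> float:
        return sum(i for i in self.currents.values() if i > 0)

    @property
    def cathode_current(self) -> float:
        return -sum(i for i in self.currents.values() if i < 0)

    def current_imbalance(self) -> float:
        """|I_anode − I_cathode| / I_anode (0 for a zero-amplitude step)."""
        ia = self.anode_current
        if ia == 0:
            return 0.0
        return abs(ia - self.cathode_current) / ia


def _assemble(
    grid: Grid,
    sx: np.ndarray,
    sy: np.ndarray,
    sz: np.ndarray,
    active: Sequence[tuple[Contact, float]],
):
    """Assemble the FV system.  ``active`` lists (contact, potential) pairs.

    Returns (A csr, b, contact_terms) where contact_terms holds, per active
    contact, the flat cell indices, conductances, and applied potential —
    enough to evaluate electrode currents from a solution.
    """
    nx, ny, nz = grid.shape
    N = nx * ny * nz
    dx, dy, dz = grid.dx, grid.dy, grid.dz
    idx = np.arange(N).reshape(nx, ny, nz)
    diag = np.zeros(N)
    rows, cols, vals = [], [], []

    def faces(s, axis, d_self, area):
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[axis] = slice(0, -1)
        sl2[axis] = slice(1, None)
        s1, s2 = s[tuple(sl1)], s[tuple(sl2)]
        if axis == 2:
            r1 = 0.5 * dz[:-1][None, None, :] / s1
            r2 = 0.5 * dz[1:][None, None, :] / s2
            g = (dx * dy) / (r1 + r2)
        else:
            g = area / (0.5 * d_self / s1 + 0.5 * d_self / s2)
        i1 = idx[tuple(sl1)].ravel()
        i2 = idx[tuple(sl2)].ravel()
        gv = g.ravel()
        rows.append(i1); cols.append(i2); vals.append(-gv)
        rows.append(i2); cols.append(i1); vals.append(-gv)
        np.add.at(diag, i1, gv)
        np.add.at(diag, i2, gv)
        return g

    gx = faces(np.broadcast_to(sx, (nx, ny, nz)), 0, dx,
               dy * dz[None, None, :])
    gy = faces(np.broadcast_to(sy, (nx, ny, nz)), 1, dy,
               dx * dz[None, None, :])
    gz = faces(np.broadcast_to(sz, (nx, ny, nz)), 2, 0.0, None)

    b = np.zeros(N)
    contact_terms = []
    for contact, phi_d in active:
        mask = contact.mask
        if contact.face == "top":
            szf = np.broadcast_to(sz, (nx, ny, nz))[:, :, 0]
            g = szf * dx * dy / (0.5 * dz[0])
            cells = idx[:, :, 0][mask]
        else:
            szf = np.broadcast_to(sz, (nx, ny, nz))[:, :, -1]
            g = szf * dx * dy / (0.5 * dz[-1])
            cells = idx[:, :, -1][mask]
        gm = g[mask]
        diag[cells] += gm
        b[cells] += gm * phi_d
        contact_terms.append((contact, cells, gm, phi_d))

    A = sp.csr_matrix(
        (
            np.concatenate(vals + [diag]),
            (
                np.concatenate(rows + [np.arange(N)]),
                np.concatenate(cols + [np.arange(N)]),
            ),
        ),
        shape=(N, N),
    )
    return A, b, contact_terms, (gx, gy, gz)


def _field_from_fluxes(
    grid: Grid,
    phi: np.ndarray,
    gcond,
    sx: np.ndarray,
    sy: np.ndarray,
    sz: np.ndarray,
    contact_terms,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centred E from face current densities (J_n continuous across
    interfaces; E = J/σ per cell, exact for 1D layered solutions)."""
    nx, ny, nz = grid.shape
    dx, dy, dz = grid.dx, grid.dy, grid.dz
    gx, gy, gz = gcond

    # face current densities (positive along +axis)
    qx = np.zeros((nx + 1, ny, nz))
    qx[1:-1] = gx * (phi[:-1] - phi[1:]) / (dy * dz[None, None, :])
    qy = np.zeros((nx, ny + 1, nz))
    qy[:, 1:-1] = gy * (phi[:, :-1] - phi[:, 1:]) / (dx * dz[None, None, :])
    qz = np.zeros((nx, ny, nz + 1))
    qz[:, :, 1:-1] = gz * (phi[:, :, :-1] - phi[:, :, 1:]) / (dx * dy)

    phi_flat = phi.ravel()
    for contact, cells, gm, phi_d in contact_terms:
        jn = gm * (phi_d - phi_flat[cells]) / (dx * dy)
        if contact.face == "top":
            qz[:, :, 0][contact.mask] = jn   # current entering downward (+z)
        else:
            qz[:, :, -1][contact.mask] = -jn  # entering upward means −z flux

    sx3 = np.broadcast_to(sx, (nx, ny, nz))
    sy3 = np.broadcast_to(sy, (nx, ny, nz))
    sz3 = np.broadcast_to(sz, (nx, ny, nz))
    Ex = 0.5 * (qx[:-1] + qx[1:]) / sx3
    Ey = 0.5 * (qy[:, :-1] + qy[:, 1:]) / sy3
    Ez = 0.5 * (qz[:, :, :-1] + qz[:, :, 1:]) / sz3
    E = np.stack([Ex, Ey, Ez], axis=-1)
    return E, np.sqrt(Ex**2 + Ey**2 + Ez**2)


def _zline_preconditioner(A, gz, shape):
    """Block-Jacobi preconditioner with one tridiagonal block per vertical
    cell column.

    The grid's cells are far thinner than they are wide, so the face
    conductances couple each column of cells much more strongly in z than
    laterally (the stratum corneum contributes an extreme contrast on top).
    Solving the z-tridiagonal blocks exactly captures that stiff coupling;
    the remaining lateral problem is mild and CG handles it.  The blocks
    are SPD, so the preconditioner is valid for CG.
    """
    nx, ny, nz = shape
    m = nx * ny
    diag = A.diagonal().reshape(m, nz)
    c = -gz.reshape(m, nz - 1)  # symmetric off-diagonal within a column
    cp = np.empty_like(c)
    bp = diag.copy()
    for k in range(nz - 1):
        cp[:, k] = c[:, k] / bp[:, k]
        bp[:, k + 1] = diag[:, k + 1] - c[:, k] * cp[:, k]

    def solve(r):
        y = np.asarray(r, dtype=float).reshape(m, nz).copy()
        for k in range(1, nz):
            y[:, k] -= cp[:, k - 1] * y[:, k - 1]
        y /= bp
        for k in range(nz - 2, -1, -1):
            y[:, k] -= cp[:, k] * y[:, k + 1]
        return y.ravel()

    return spla.LinearOperator(A.shape, solve)


def _linear_solve(A, b, gz, shape, x0=None, rtol=1e-9, maxiter=3000):
    if not np.any(b):
        return np.zeros_like(b), 0
    M = _zline_preconditioner(A, gz, shape)
    x, info = spla.cg(A, b, x0=x0, M=M, rtol=rtol, atol=0.0, maxiter=maxiter)
    if info != 0:
        x, info = spla.cg(A, b, x0=x, M=M, rtol=rtol, atol=0.0,
                          maxiter=2 * maxiter)
    return x, info


def solve_step(
    grid: Grid,
    state: ElectroporationState,
    step: ProtocolStep,
    law: ConductivityLaw,
    contacts: Mapping[int, Contact],
    *,
    tol: float = 1e-3,
    max_iter: int = 50,
    damping: float = 0.5,
    step_index: int = 0,
) -> FieldSolution:
    """Solve one activation step to a self-consistent conductivity.

    Dirichlet φ = amplitude on anode contacts and φ = 0 on cathode
    contacts; all other boundaries insulating.  Within the step σ responds
    to the larger of the stored envelope and the current field magnitude
    (damped Picard fixed point on the conductivity factor); the iteration
    stops when the max relative change of |E| drops below ``tol``.
    Non-convergence at ``max_iter`` is flagged on the returned solution,
    not raised.
    """
    try:
        active = (
            [(contacts[i], step.amplitude) for i in sorted(step.anodes)]
            + [(contacts[i], 0.0) for i in sorted(step.cathodes)]
        )
    except KeyError as e:
        raise SolverError(f"no contact patch for electrode {e.args[0]}") from None
    if not active:
        raise SolverError("step activates no electrodes")
    p = _layer_params(grid)
    factor = state.factor.copy()
    phi_flat = None
    emag_prev = None
    converged = False
    n_it = 0
    beta = damping
    r_prev = np.inf
    for it in range(max_iter):
        n_it = it + 1
        sx, sy, sz = p.s0x * factor, p.s0y * factor, p.s0z * factor
        A, b, terms, gcond = _assemble(grid, sx, sy, sz, active)
        phi_flat, info = _linear_solve(A, b, gcond[2], grid.shape, x0=phi_flat)
        if info != 0:
            log.warning("step %d: linear solver stagnated (info=%s)",
                        step_index, info)
        phi = phi_flat.reshape(grid.shape)
        E, emag = _field_from_fluxes(grid, phi, gcond, sx, sy, sz, terms)
        scale = emag.max()
        if emag_prev is not None:
            r = np.abs(emag - emag_prev).max() / scale if scale > 0 else 0.0
            if scale == 0.0 or r <= tol:
                converged = True
                break
            # a stalling residual signals a Picard limit cycle in cells on
            # the steep part of the sigmoid; shrink the mixing parameter
            if r > 0.9 * r_prev:
                beta = max(0.5 * beta, 0.05)
            r_prev = r
        emag_prev = emag
        e_eff = np.maximum(state.e_env, emag)
        grow = emag > state.e_env
        unit = E / np.maximum(emag, _TINY)[..., None]
        dirs = np.where(grow[..., None], unit, state.env_dir)
        f_new = conductivity_factor(grid, law, e_eff, dirs)
        factor = factor + beta * (f_new - factor)
    if not converged:
        log.warning("step %d: Picard iteration did not converge in %d "
                    "iterations", step_index, max_iter)

    currents: dict[int, float] = {}
    ids = sorted(step.anodes) + sorted(step.cathodes)
    for eid, (_, cells, gm, phi_d) in zip(ids, terms):
        currents[eid] = float(np.sum(gm * (phi_d - phi_flat[cells])))
    return FieldSolution(
        step_index=step_index,
        phi=phi,
        E=E,
        e_mag=emag,
        currents=currents,
        converged=converged,
        n_iterations=n_it,
    )


def _mirror_solution(prev: FieldSolution, step: ProtocolStep,
                     step_index: int) -> FieldSolution:
    """Exact solution of a polarity-reversed step: for any fixed σ field,
    φ' = U − φ satisfies the same equation with anodes and cathodes
    swapped, so |E| is identical and the envelope cannot change."""
    return FieldSolution(
        step_index=step_index,
        phi=step.amplitude - prev.phi,
        E=-prev.E,
        e_mag=prev.e_mag,
        currents={eid: -i for eid, i in prev.currents.items()},
        converged=prev.converged,
        n_iterations=0,
        reused=True,
    )


def run_protocol(
    grid: Grid,
    protocol: Protocol,
    law: ConductivityLaw,
    array: ElectrodeArray | None = None,
    contacts: Mapping[int, Contact] | None = None,
    *,
    tol: float = 1e-3,
    max_iter: int = 50,
    damping: float = 0.5,
    reuse_reversed: bool = True,
    keep_solutions: bool = True,
) -> tuple[ElectroporationState, list[FieldSolution]]:
    """Run all steps of ``protocol`` in order, sequentially updating the
    electroporation state.

    After each step the envelope absorbs the converged field magnitude,
    e_env ← max(e_env, |E|), and the conductivity is recomputed from the
    updated envelope — the "electroporation memory" that persists across
    steps.  A step that exactly reverses the polarity of the immediately
    preceding one is reproduced analytically (φ' = U − φ) rather than
    re-solved; set ``reuse_reversed=False`` to force the full solve.
    """
    if contacts is None:
        if array is None:
            raise SolverError("either an electrode array or explicit "
                              "contacts are required")
        contacts = surface_contacts(grid, array)
    state = ElectroporationState.zeros(grid)
    solutions: list[FieldSolution] = []
    prev_step: ProtocolStep | None = None
    prev_sol: FieldSolution | None = None
    for i, step in enumerate(protocol.steps):
        if (
            reuse_reversed
            and prev_step is not None
            and prev_sol is not None
            and prev_sol.converged
            and step.is_reversal_of(prev_step)
        ):
            sol = _mirror_solution(prev_sol, step, i)
        else:
            sol = solve_step(
                grid, state, step, law, contacts,
                tol=tol, max_iter=max_iter, damping=damping, step_index=i,
            )
        state.update_envelope(law, sol)
        log.info(
            "step %2d/%d: %s iters=%d I=%.3g A imbalance=%.2e%s",
            i + 1, len(protocol.steps),
            "reused" if sol.reused else "solved",
            sol.n_iterations, sol.anode_current, sol.current_imbalance(),
            "" if sol.converged else "  NOT CONVERGED",
        )
        prev_step, prev_sol = step, sol
        if keep_solutions:
            solutions.append(sol)
        else:
            solutions = [sol]
    return state, solutions
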