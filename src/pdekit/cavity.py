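"""Steady lid-driven cavity in primitive variables.

Incompressible Navier-Stokes on the unit square, lid moving at constant
velocity, solved with Picard linearization of the advection term (dropped
entirely in the zero-Reynolds Stokes limit) and the mesh-free
pressure-correction loop nested inside each Picard step.  Works with either
the DC-PSE or the finite-difference operator backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .dcpse import OperatorBundle, build_operator_bundle
from .expr import ArrayExpr, Derivative, EquationSet, assemble, get_field
from .geometry import BoxDomain, ParticleSet, grid_particles
from .solvers import PressureCorrectionConfig, SolveReport, pressure_correction

__all__ = [
    "CavityConfig",
    "build_cavity_particles",
    "solve_cavity",
    "centerline_profiles",
    "locate_vortex_center",
]


@dataclass
class CavityConfig:
    re: float = 0.0
    n: int = 41
    backend: str = "dcpse"
    tol_picard: float = 1e-6
    max_picard: int = 30
    pc: PressureCorrectionConfig = dc_field(default_factory=PressureCorrectionConfig)
    lid_velocity: tuple = (1.0, 0.0)
    conv_order: int = 2
    rc_factor: float = 3.1

    def __post_init__(self):
        if self.re < 0:
            raise ValueError("Re must be >= 0")
        if self.n < 17:
            raise ValueError("need n >= 17 particles per axis")


def build_cavity_particles(cfg: CavityConfig) -> ParticleSet:
    box = BoxDomain((0.0, 0.0), (1.0, 1.0))
    ps = grid_particles(box, cfg.n)
    ps.add_property("v", rank="vector")
    ps.add_property("Pi", rank="scalar")
    return ps


def _boundary_velocity(ps: ParticleSet, lid_velocity) -> np.ndarray:
    """No-slip walls; the whole top face y=1 (corners included) takes the lid value."""
    vb = np.zeros((ps.N, ps.d))
    top = ps.boundary_idx[np.isclose(ps.positions[ps.boundary_idx, 1], 1.0)]
    vb[top] = np.asarray(lid_velocity, dtype=float)
    return vb


def momentum_assembler(ps: ParticleSet, ops: OperatorBundle, re: float, v_frozen: np.ndarray, vb: np.ndarray):
    """Momentum EquationSet factory at frozen advection coefficients.

    Bulk rows: (v_k . grad) v_a - (1/Re) lap v_a = -d_a Pi   (advection
    dropped for Re = 0, where the system is -lap v_a = -d_a Pi).
    Boundary rows: Dirichlet velocity.
    """
    Dx = [Derivative(op) for op in ops.dx]
    Dxx = [Derivative(op) for op in ops.dxx]
    visc = 1.0 if re == 0 else 1.0 / re

    def build(v_prev: np.ndarray, Pi: np.ndarray) -> EquationSet:
        ps.properties["Pi"][:] = Pi
        Pi_f = get_field(ps, "Pi")
        v_h = get_field(ps, "v")
        system = EquationSet(unknowns=[("v", 0), ("v", 1)])
        for a in range(2):
            lap = Dxx[0](v_h[a]) + Dxx[1](v_h[a])
            if re == 0:
                lhs = -lap
            else:
                adv = ArrayExpr(ps, v_frozen[:, 0]) * Dx[0](v_h[a]) + ArrayExpr(
                    ps, v_frozen[:, 1]
                ) * Dx[1](v_h[a])
                lhs = adv - visc * lap
            rhs = -Dx[a](Pi_f)
            system.add(lhs, rhs, ps.bulk_idx, ("v", a))
            system.add(v_h[a], ArrayExpr(ps, vb[:, a]), ps.boundary_idx, ("v", a))
        return system

    return build


def solve_cavity(cfg: CavityConfig, ps: ParticleSet | None = None):
    """Outer Picard loop with pressure correction nested in each step.

    Returns ``(v, Pi, report)``; ``report.extras`` records the Picard
    increments and per-step divergence histories.
    """
    if ps is None:
        ps = build_cavity_particles(cfg)
    ops = build_operator_bundle(
        ps, backend=cfg.backend, conv_order=cfg.conv_order, rc_factor=cfg.rc_factor
    )
    vb = _boundary_velocity(ps, cfg.lid_velocity)

    v = np.zeros((ps.N, 2))
    Pi = np.zeros(ps.N)
    increments = []
    div_histories = []
    report = SolveReport()
    stokes = cfg.re == 0
    for k in range(cfg.max_picard):
        momentum = momentum_assembler(ps, ops, cfg.re, v, vb)
        v_new, Pi, pc_rep = pressure_correction(momentum, ps, ops, cfg.pc, v0=v, Pi0=Pi)
        dv = float(np.max(np.abs(v_new - v)))
        increments.append(dv)
        div_histories.append(pc_rep.div_history)
        v = v_new
        if not pc_rep.converged:
            break
        if dv <= cfg.tol_picard or (stokes and k >= 1):
            report.converged = True
            break
    report.outer_iters = len(increments)
    report.div_history = div_histories[-1] if div_histories else []
    report.extras = {
        "picard_increments": increments,
        "pc_div_histories": div_histories,
        "pc_converged": bool(pc_rep.converged),
    }
    report.converged = report.converged and pc_rep.converged
    ps.properties["v"][:] = v
    ps.properties["Pi"][:] = Pi
    return v, Pi, report


def centerline_profiles(v: np.ndarray, ps: ParticleSet):
    """Sample u_x along the vertical line x=0.5 and u_y along y=0.5.

    Uses the particles nearest the centerlines (exactly on them for odd
    lattice sizes), ordered by the free coordinate.  Returns two (coord,
    value) arrays.
    """
    x, y = ps.positions[:, 0], ps.positions[:, 1]
    half = ps.h_nominal / 2
    cx, cy = 0.5, 0.5
    on_v = np.flatnonzero(np.abs(x - cx) <= half * (1 + 1e-9))
    on_h = np.flatnonzero(np.abs(y - cy) <= half * (1 + 1e-9))
    on_v = on_v[np.argsort(y[on_v])]
    on_h = on_h[np.argsort(x[on_h])]
    return (
        np.column_stack([y[on_v], v[on_v, 0]]),
        np.column_stack([x[on_h], v[on_h, 1]]),
    )


def locate_vortex_center(v: np.ndarray, ps: ParticleSet, ops: OperatorBundle | None = None) -> tuple:
    """Center of the primary vortex, refined to sub-spacing accuracy.

    The raw global minimum of |v| is ambiguous in a cavity (the stagnant
    corner regions are as slow as the vortex core), so the search is gated
    to the core of the primary vortex — particles where the streamfunction
    psi (from lap(psi) = -curl(v), psi = 0 on the boundary) is above half
    its extremum — and the |v|-minimizing particle there is refined by the
    stationary point of a local quadratic fit of |v|^2.  A degenerate field
    (psi identically ~0, e.g. uniform v) falls back to the smallest-index
    bulk particle.
    """
    if ops is None:
        ops = build_operator_bundle(ps)
    from .solvers import solve_linear

    curl = ops.dx[0].matrix @ v[:, 1] - ops.dx[1].matrix @ v[:, 0]
    ps.add_property("_psi")
    psi_h = get_field(ps, "_psi")
    Dxx, Dyy = Derivative(ops.dxx[0]), Derivative(ops.dxx[1])
    system = EquationSet(unknowns=[("_psi", None)])
    system.add(Dxx(psi_h) + Dyy(psi_h), ArrayExpr(ps, -curl), ps.bulk_idx, ("_psi", None))
    system.add(psi_h, 0.0, ps.boundary_idx, ("_psi", None))
    A, b, _ = assemble(system)
    psi = solve_linear(A, b)
    del ps.properties["_psi"]

    bulk = ps.bulk_idx
    if np.max(np.abs(psi[bulk])) < 1e-12:
        return tuple(ps.positions[bulk[0]])
    # core region of the primary vortex: |psi| above half its extremum; this
    # excludes the slow stagnant corner regions that also minimize |v|
    core = bulk[np.abs(psi[bulk]) >= 0.5 * np.max(np.abs(psi[bulk]))]
    speed2 = np.sum(v[core] ** 2, axis=1)
    seed = core[int(np.argmin(speed2))]
    x0 = ps.positions[seed]
    h = ps.h_nominal
    d2 = np.sum((ps.positions - x0) ** 2, axis=1)
    nb = np.flatnonzero(d2 < (2.5 * h) ** 2)
    if nb.size < 6:
        return tuple(x0)
    dx = (ps.positions[nb] - x0) / h
    A2 = np.column_stack(
        [np.ones(nb.size), dx[:, 0], dx[:, 1], dx[:, 0] ** 2, dx[:, 0] * dx[:, 1], dx[:, 1] ** 2]
    )
    coef, *_ = np.linalg.lstsq(A2, np.sum(v[nb] ** 2, axis=1), rcond=None)
    _, c1, c2, c20, c11, c02 = coef
    H = np.array([[2 * c20, c11], [c11, 2 * c02]])
    g = np.array([c1, c2])
    try:
        shift = np.linalg.solve(H, -g)
    except np.linalg.LinAlgError:
        return tuple(x0)
    if np.any(np.linalg.eigvalsh(H) <= 0) or np.linalg.norm(shift) > 1.5:
        return tuple(x0)
    return tuple(x0 + shift * h)
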