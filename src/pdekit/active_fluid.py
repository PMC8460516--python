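"""Lagrangian mesh-free simulator for 2-d viscous active polar fluids.

State: a unit polarity vector field p advected and rotated by the flow it
itself drives.  Each time step (i) evaluates the molecular field and the
polarity-dependent (velocity-independent) part of the stress, (ii) solves
the forced Stokes problem for (v, Pi) with the pressure-correction loop,
(iii) advances p by RK4 (flow kinematics frozen over the step, molecular
field refreshed per substage), renormalizes and re-anchors it, and
(iv) advects the bulk particles with explicit Euler, after which neighbor
lists and derivative operators are rebuilt on the moved cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .dcpse import OperatorBundle, apply_op, build_operator_bundle
from .expr import Derivative, EquationSet, get_field
from .geometry import BoxDomain, ParticleSet, grid_particles
from .solvers import PressureCorrectionConfig, pressure_correction

__all__ = [
    "ActiveParams",
    "ActiveState",
    "init_polarity",
    "make_benchmark_state",
    "stress_fields",
    "molecular_field",
    "strain_vorticity",
    "passive_active_force",
    "active_stokes_solve",
    "polarity_rhs",
    "step",
    "run_benchmark",
    "shepard_interpolate",
    "spatial_convergence",
    "temporal_convergence",
    "BENCHMARK_BOX",
]

#: benchmark domain [0, 10]^2
BENCHMARK_BOX = BoxDomain((0.0, 0.0), (10.0, 10.0))


@dataclass(frozen=True)
class ActiveParams:
    """Material and discretization parameters (benchmark defaults)."""

    eta: float = 1.0
    nu: float = -0.5
    gamma: float = 0.1
    zeta: float = 0.07
    lam: float = 0.1
    dmu: float = -1.0
    Ks: float = 1.0
    Kb: float = 1.0
    dt: float = 2e-7

    def __post_init__(self):
        if not (self.eta > 0 and self.gamma > 0 and self.dt > 0):
            raise ValueError("eta, gamma and dt must be positive")


@dataclass
class ActiveState:
    ps: ParticleSet
    p: np.ndarray          # (N, 2) polarity
    v: np.ndarray          # (N, 2) velocity
    Pi: np.ndarray         # (N,) pressure
    p_anchor: np.ndarray   # boundary anchoring values (N, 2), fixed at t=0
    t: float = 0.0


def init_polarity(ps: ParticleSet, Lx: float, Ly: float) -> np.ndarray:
    """Benchmark initial polarity: p = (sin A, cos A),
    A = 2*pi*(cos((2x - Lx)/Lx) - sin((2y - Ly)/Ly))."""
    x, y = ps.positions[:, 0], ps.positions[:, 1]
    A = 2.0 * np.pi * (np.cos((2 * x - Lx) / Lx) - np.sin((2 * y - Ly) / Ly))
    return np.stack([np.sin(A), np.cos(A)], axis=-1)


def make_benchmark_state(n: int, box: BoxDomain = BENCHMARK_BOX) -> ActiveState:
    ps = grid_particles(box, n)
    ps.add_property("v", rank="vector")
    ps.add_property("Pi", rank="scalar")
    ps.add_property("g", rank="vector")
    p = init_polarity(ps, box.extent[0], box.extent[1])
    return ActiveState(ps=ps, p=p, v=np.zeros((ps.N, 2)), Pi=np.zeros(ps.N),
                       p_anchor=p.copy())


def molecular_field(p: np.ndarray, ops: OperatorBundle, Ks: float, Kb: float,
                    project: bool = True) -> np.ndarray:
    """Molecular field h from splay/bend elasticity.

    Elastic part h_e = Ks*grad(div p) - Kb*perp_grad(curl p); for Ks = Kb = K
    this reduces to K*lap(p).  When ``project`` is set, the component parallel
    to p is removed (the unit-norm Lagrange multiplier realized as
    perpendicular projection), so p . h = 0 pointwise.
    """
    px, py = p[:, 0], p[:, 1]
    dxx = lambda f: apply_op(ops.dxx[0], f)
    dyy = lambda f: apply_op(ops.dxx[1], f)
    dxy = lambda f: apply_op(ops.dmixed[(0, 1)], f)
    he = np.empty_like(p)
    he[:, 0] = Ks * (dxx(px) + dxy(py)) - Kb * (dxy(py) - dyy(px))
    he[:, 1] = Ks * (dxy(px) + dyy(py)) + Kb * (dxx(py) - dxy(px))
    if not project:
        return he
    norm2 = np.sum(p * p, axis=1)
    norm2 = np.where(norm2 > 0, norm2, 1.0)
    par = np.sum(p * he, axis=1) / norm2
    return he - par[:, None] * p


def strain_vorticity(v: np.ndarray, ops: OperatorBundle):
    """Strain rate u_ab = (d_a v_b + d_b v_a)/2 and vorticity
    w_ab = (d_b v_a - d_a v_b)/2."""
    d = v.shape[1]
    grad = np.stack([ops.gradient(v[:, b]) for b in range(d)], axis=1)
    # grad[n, a, b] = d_b v_a
    u = 0.5 * (grad + grad.transpose(0, 2, 1))
    w = 0.5 * (grad - grad.transpose(0, 2, 1))
    # u[n, a, b] = (d_b v_a + d_a v_b)/2 ; w[n, a, b] = (d_b v_a - d_a v_b)/2
    return u, w


def stress_fields(p: np.ndarray, h: np.ndarray, params: ActiveParams) -> np.ndarray:
    """Velocity-independent stress sigma~_ab (N, 2, 2):
    active + orientational-coupling symmetric part + antisymmetric part."""
    q = params.zeta * params.dmu
    nu = params.nu
    px, py = p[:, 0], p[:, 1]
    hx, hy = h[:, 0], h[:, 1]
    p2 = px * px + py * py
    ph = px * hx + py * hy
    sig = np.empty((p.shape[0], 2, 2))
    sig[:, 0, 0] = -q * (px * px - 0.5 * p2) + 0.5 * nu * (2 * px * hx - ph)
    sig[:, 1, 1] = -q * (py * py - 0.5 * p2) + 0.5 * nu * (2 * py * hy - ph)
    sym_xy = -q * px * py + 0.5 * nu * (px * hy + py * hx)
    anti = 0.5 * (px * hy - hx * py)
    sig[:, 0, 1] = sym_xy + anti
    sig[:, 1, 0] = sym_xy - anti
    return sig


def passive_active_force(p: np.ndarray, h: np.ndarray, params: ActiveParams,
                         ops: OperatorBundle) -> np.ndarray:
    """Body force g_a = d_b sigma~_ab driving the Stokes solve."""
    sig = stress_fields(p, h, params)
    g = np.empty_like(p)
    for a in range(2):
        g[:, a] = apply_op(ops.dx[0], sig[:, a, 0]) + apply_op(ops.dx[1], sig[:, a, 1])
    return g


def _stokes_momentum(ps: ParticleSet, ops: OperatorBundle, eta: float, g: np.ndarray):
    """Momentum system eta*lap(v_a) = d_a(Pi) - g_a on bulk, v = 0 on boundary."""
    Dx = [Derivative(op) for op in ops.dx]
    Dxx = [Derivative(op) for op in ops.dxx]
    d = ps.d

    def build(v_prev, Pi):
        ps.properties["Pi"][:] = Pi
        ps.properties["g"][:] = g
        Pi_f = get_field(ps, "Pi")
        g_f = get_field(ps, "g")
        v_h = get_field(ps, "v")
        system = EquationSet(unknowns=[("v", a) for a in range(d)])
        for a in range(d):
            lap = Dxx[0](v_h[a])
            for k in range(1, d):
                lap = lap + Dxx[k](v_h[a])
            system.add(eta * lap, Dx[a](Pi_f) - g_f[a], ps.bulk_idx, ("v", a))
            system.add(v_h[a], 0.0, ps.boundary_idx, ("v", a))
        return system

    return build


def active_stokes_solve(state: ActiveState, params: ActiveParams, ops: OperatorBundle,
                        pc_cfg: PressureCorrectionConfig, g: np.ndarray | None = None):
    """Solve the forced Stokes problem for (v, Pi) at the current polarity."""
    if g is None:
        h = molecular_field(state.p, ops, params.Ks, params.Kb)
        g = passive_active_force(state.p, h, params, ops)
    momentum = _stokes_momentum(state.ps, ops, params.eta, g)
    v, Pi, report = pressure_correction(
        momentum, state.ps, ops, pc_cfg, v0=state.v, Pi0=state.Pi
    )
    return v, Pi, report


def polarity_rhs(p: np.ndarray, h: np.ndarray, v: np.ndarray, u: np.ndarray,
                 w: np.ndarray, params: ActiveParams) -> np.ndarray:
    """dp_a/dt = h_a/gamma - nu*u_ab p_b + lam*dmu*p_a + w_ab p_b
    (advection absorbed by particle motion in the Lagrangian frame)."""
    up = np.einsum("nab,nb->na", u, p)
    wp = np.einsum("nab,nb->na", w, p)
    return h / params.gamma - params.nu * up + params.lam * params.dmu * p + wp


def step(state: ActiveState, params: ActiveParams,
         pc_cfg: PressureCorrectionConfig | None = None,
         conv_order: int = 2, rc_factor: float = 3.1,
         ops: OperatorBundle | None = None) -> ActiveState:
    """Advance the state by one time step of size ``params.dt``.

    Operators are built on the current particle positions (they must be
    rebuilt after every advection, which this function guarantees by
    building them fresh unless a bundle for *these* positions is supplied).
    """
    pc_cfg = pc_cfg or PressureCorrectionConfig(eps=1e-3)
    ps = state.ps
    if ops is None:
        ops = build_operator_bundle(ps, conv_order=conv_order, rc_factor=rc_factor, mixed=True)

    h = molecular_field(state.p, ops, params.Ks, params.Kb)
    g = passive_active_force(state.p, h, params, ops)
    v, Pi, report = active_stokes_solve(state, params, ops, pc_cfg, g=g)
    u, w = strain_vorticity(v, ops)

    # RK4 on p; v, u, w frozen at step start, h refreshed per substage
    dt = params.dt

    def rhs(p_sub):
        h_sub = molecular_field(p_sub, ops, params.Ks, params.Kb)
        return polarity_rhs(p_sub, h_sub, v, u, w, params)

    p0 = state.p
    k1 = rhs(p0)
    k2 = rhs(p0 + 0.5 * dt * k1)
    k3 = rhs(p0 + 0.5 * dt * k2)
    k4 = rhs(p0 + dt * k3)
    p_new = p0 + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    norm = np.linalg.norm(p_new, axis=1)
    if np.any(norm == 0):
        raise FloatingPointError("polarity collapsed to zero during RK4 stage")
    p_new /= norm[:, None]
    p_new[ps.boundary_idx] = state.p_anchor[ps.boundary_idx]

    new_ps = ps.copy()
    new_ps.positions[ps.bulk_idx] += dt * v[ps.bulk_idx]
    new_ps.lattice_shape = None  # particles moved; downstream must not assume a lattice
    return ActiveState(ps=new_ps, p=p_new, v=v, Pi=Pi, p_anchor=state.p_anchor,
                       t=state.t + dt)


def run_benchmark(n: int, steps: int, params: ActiveParams | None = None,
                  pc_cfg: PressureCorrectionConfig | None = None,
                  callback=None) -> ActiveState:
    """Run the benchmark configuration for ``steps`` time steps."""
    params = params or ActiveParams()
    pc_cfg = pc_cfg or PressureCorrectionConfig(eps=1e-3)
    state = make_benchmark_state(n)
    for k in range(steps):
        state = step(state, params, pc_cfg)
        if callback is not None:
            callback(k, state)
    return state


# ---------------------------------------------------------------------------
# convergence harnesses
# ---------------------------------------------------------------------------

def shepard_interpolate(src_pos: np.ndarray, src_vals: np.ndarray,
                        dst_pos: np.ndarray, k: int = 4, power: int = 2) -> np.ndarray:
    """Inverse-distance (Shepard) interpolation with k nearest neighbors."""
    tree = cKDTree(src_pos)
    dist, idx = tree.query(dst_pos, k=k)
    dist = np.maximum(dist, 1e-14)
    wts = 1.0 / dist**power
    wts /= wts.sum(axis=1, keepdims=True)
    vals = src_vals[idx]  # (M, k, ...) gather
    return np.einsum("mk,mk...->m...", wts, vals)


def _error_norms(diff: np.ndarray):
    mag = np.linalg.norm(diff, axis=-1) if diff.ndim > 1 else np.abs(diff)
    return float(np.sqrt(np.mean(mag**2))), float(np.max(mag))


def spatial_convergence(resolutions, n_ref: int, steps: int,
                        params: ActiveParams | None = None,
                        pc_cfg: PressureCorrectionConfig | None = None) -> dict:
    """Velocity error of coarse runs against a finer-reference run at matched
    time; returns spacings, L2/Linf norms and the fitted log-log slope."""
    params = params or ActiveParams()
    ref = run_benchmark(n_ref, steps, params, pc_cfg)
    hs, l2s, lis = [], [], []
    for n in resolutions:
        st = run_benchmark(n, steps, params, pc_cfg)
        v_ref = shepard_interpolate(ref.ps.positions, ref.v, st.ps.positions)
        l2, li = _error_norms(st.v - v_ref)
        hs.append(st.ps.h_nominal)
        l2s.append(l2)
        lis.append(li)
    slope = float(np.polyfit(np.log(hs), np.log(l2s), 1)[0])
    return {"h": hs, "l2": l2s, "linf": lis, "slope": slope}


def temporal_convergence(n: int, step_counts, ref_steps: int, t_final: float,
                         params: ActiveParams | None = None,
                         pc_cfg: PressureCorrectionConfig | None = None) -> dict:
    """Polarity error at a fixed final time for decreasing time step against a
    fine-time-step reference on the same initial lattice."""
    params = params or ActiveParams()
    base = params or ActiveParams()
    ref = run_benchmark(n, ref_steps, replace(base, dt=t_final / ref_steps), pc_cfg)
    dts, l2s, lis = [], [], []
    for m in step_counts:
        st = run_benchmark(n, m, replace(base, dt=t_final / m), pc_cfg)
        p_ref = shepard_interpolate(ref.ps.positions, ref.p, st.ps.positions)
        l2, li = _error_norms(st.p - p_ref)
        dts.append(t_final / m)
        l2s.append(l2)
        lis.append(li)
    slope = float(np.polyfit(np.log(dts), np.log(l2s), 1)[0])
    return {"dt": dts, "l2": l2s, "linf": lis, "slope": slope}
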