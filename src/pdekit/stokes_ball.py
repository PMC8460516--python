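"""Steady Stokes flow in the unit ball with vector-spherical-harmonic
boundary velocity, validated against the closed-form interior solution.

For a single (l, m) mode with boundary velocity
``a_Y * Y_vec + a_Psi * Psi_vec + a_Phi * Phi_vec`` the regular interior
solution of ``lap(v) = grad(Pi), div(v) = 0`` is polynomial in Cartesian
coordinates:

    v = a * grad(S) + b * [ c_g * r^2 * grad(S) - c_x * x * S ] + a_Phi * (x cross grad(S))
    Pi = b * S

with ``S`` the real solid harmonic ``r^l * Y_lm``,
``c_g = (l+3) / (2 (l+1) (2l+3))``, ``c_x = l / ((l+1) (2l+3))``, and
(a, b) fixed by matching ``(a_Y, a_Psi)`` at r = 1.  The toroidal part
carries ``u2(r) = a_Phi r^l`` and is decoupled.  All evaluations here are
generated from the sympy expression for S, which keeps the origin and the
poles regular.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import sympy as sym

from .dcpse import build_operator_bundle
from .expr import Derivative, EquationSet, get_field, ArrayExpr
from .geometry import BallDomain, ball_particles
from .solvers import PressureCorrectionConfig, pressure_correction

__all__ = [
    "VSHMode",
    "AnalyticStokesSolution",
    "real_solid_harmonic",
    "vsh_basis",
    "analytic_solution",
    "solve_ball",
]


@dataclass(frozen=True)
class VSHMode:
    l: int
    m: int
    amplitudes: tuple = (1.0, 1.0, 1.0)  # (a_Y, a_Psi, a_Phi)

    def __post_init__(self):
        if abs(self.m) > self.l:
            raise ValueError("mode requires |m| <= l")


@lru_cache(maxsize=32)
def _solid_harmonic_exprs(l: int, m: int):
    """Sympy (S, grad S) for the real solid harmonic r^l Y_lm (Condon-Shortley
    phase; m<0 gives the sine combination)."""
    x, y, z = sym.symbols("x y z", real=True)
    r, th, ph = sym.symbols("r theta phi", positive=True)
    if m == 0:
        Yr = sym.re(sym.Ynm(l, 0, th, ph).expand(func=True))
    elif m > 0:
        Yr = sym.sqrt(2) * (-1) ** m * sym.re(sym.Ynm(l, m, th, ph).expand(func=True))
    else:
        Yr = sym.sqrt(2) * (-1) ** m * sym.im(sym.Ynm(l, -m, th, ph).expand(func=True))
    S = (r**l * Yr).rewrite(sym.cos)
    # reduce every trig term to products of sin/cos of theta and phi alone,
    # then substitute Cartesian forms; expand_trig must come last or sympy
    # re-contracts sums like sin(phi + 2*theta)
    S = sym.expand(sym.expand_trig(sym.expand(S)))
    rho = sym.sqrt(x**2 + y**2)
    rr = sym.sqrt(x**2 + y**2 + z**2)
    S_cart = S.subs(
        [(sym.cos(th), z / rr), (sym.sin(th), rho / rr),
         (sym.cos(ph), x / rho), (sym.sin(ph), y / rho), (r, rr)]
    )
    S_cart = sym.simplify(sym.expand(sym.radsimp(S_cart)))
    poly = sym.expand(S_cart)
    grad = [sym.expand(sym.diff(poly, c)) for c in (x, y, z)]
    return (x, y, z), poly, grad


def real_solid_harmonic(l: int, m: int):
    """Callables ``S(points)`` and ``gradS(points)`` for r^l Y_lm (real form)."""
    (x, y, z), poly, grad = _solid_harmonic_exprs(l, m)
    f = sym.lambdify((x, y, z), poly, modules="numpy")
    gfs = [sym.lambdify((x, y, z), g, modules="numpy") for g in grad]

    def S(pts):
        pts = np.atleast_2d(pts)
        return np.broadcast_to(
            np.asarray(f(pts[:, 0], pts[:, 1], pts[:, 2]), dtype=float), (pts.shape[0],)
        ).copy()

    def gradS(pts):
        pts = np.atleast_2d(pts)
        cols = [
            np.broadcast_to(np.asarray(g(pts[:, 0], pts[:, 1], pts[:, 2]), dtype=float),
                            (pts.shape[0],))
            for g in gfs
        ]
        return np.stack(cols, axis=-1)

    return S, gradS


def vsh_basis(l: int, m: int, x) -> tuple:
    """Vector spherical harmonics (Y_vec, Psi_vec, Phi_vec) at point(s) x.

    Y_vec = Y_lm r_hat, Psi_vec = r grad(Y_lm), Phi_vec = r_hat x Psi_vec;
    evaluated through the solid harmonic so the expressions stay finite away
    from the origin (x = 0 is rejected).
    """
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    if np.any(r == 0):
        raise ValueError("vector spherical harmonics are undefined at the origin")
    S, gradS = real_solid_harmonic(l, m)
    s = S(pts)
    gs = gradS(pts)
    rhat = pts / r[:, None]
    Yval = s / r**l
    Y_vec = Yval[:, None] * rhat
    # Psi = r grad(Y) = r grad(S r^-l) = r^(1-l) gradS - l r^-l S rhat
    Psi = r[:, None] ** (1 - l) * gs - l * (s / r**l)[:, None] * rhat
    Phi = np.cross(rhat, Psi)
    if np.asarray(x).ndim == 1:
        return Y_vec[0], Psi[0], Phi[0]
    return Y_vec, Psi, Phi


@dataclass
class AnalyticStokesSolution:
    """Interior Stokes solution for one VSH mode; radial coefficient
    profiles plus full-field evaluators."""

    mode: VSHMode
    a: float
    b: float

    def __post_init__(self):
        l = self.mode.l
        self._S, self._gradS = real_solid_harmonic(l, self.mode.m)
        self._cg = (l + 3.0) / (2.0 * (l + 1.0) * (2.0 * l + 3.0))
        self._cx = l / ((l + 1.0) * (2.0 * l + 3.0))

    # -- radial profiles -----------------------------------------------------
    def u_r(self, r):
        l = self.mode.l
        return self.a * l * r ** (l - 1) + self.b * l / (2.0 * (2 * l + 3.0)) * r ** (l + 1)

    def u_1(self, r):
        l = self.mode.l
        return self.a * r ** (l - 1) + self.b * self._cg * r ** (l + 1)

    def u_2(self, r):
        return self.mode.amplitudes[2] * np.asarray(r) ** self.mode.l

    def p(self, r):
        return self.b * np.asarray(r) ** self.mode.l

    # -- field evaluation ----------------------------------------------------
    def velocity(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        gs = self._gradS(pts)
        s = self._S(pts)
        r2 = np.sum(pts * pts, axis=1)
        a_phi = self.mode.amplitudes[2]
        v = self.a * gs
        v = v + self.b * (self._cg * r2[:, None] * gs - self._cx * s[:, None] * pts)
        v = v + a_phi * np.cross(pts, gs)
        return v

    def pressure(self, pts) -> np.ndarray:
        return self.b * self._S(np.atleast_2d(np.asarray(pts, dtype=float)))


def analytic_solution(mode: VSHMode) -> AnalyticStokesSolution:
    """Coefficients (a, b) from matching (a_Y, a_Psi) at r = 1.

    Matching system (f = radial profile of Y_vec, g = of Psi_vec):
        f(1) = a*l + b*l/(2(2l+3))          = a_Y
        g(1) = a   + b*(l+3)/(2(l+1)(2l+3)) = a_Psi
    """
    l = mode.l
    if l < 1:
        raise ValueError("modes require l >= 1 (l = 0 has nonzero net flux)")
    a_Y, a_Psi, _ = mode.amplitudes
    M = np.array(
        [
            [l, l / (2.0 * (2 * l + 3.0))],
            [1.0, (l + 3.0) / (2.0 * (l + 1.0) * (2 * l + 3.0))],
        ]
    )
    a, b = np.linalg.solve(M, [a_Y, a_Psi])
    return AnalyticStokesSolution(mode=mode, a=float(a), b=float(b))


def solve_ball(h: float, mode: VSHMode,
               pc_cfg: PressureCorrectionConfig | None = None,
               conv_order: int = 2, rc_factor: float = 3.1):
    """Mesh-free Stokes solve in the unit ball against VSH boundary data.

    Returns ``(v, Pi, ps, errors)`` with ``errors = {"l2":, "linf":}``, the
    RMS and max norms of ``|v - v_analytic|`` over the bulk.
    """
    pc_cfg = pc_cfg or PressureCorrectionConfig(eps=1e-6)
    ball = BallDomain((0.0, 0.0, 0.0), 1.0)
    ps = ball_particles(ball, h)
    ps.add_property("v", rank="vector")
    ps.add_property("Pi", rank="scalar")
    exact = analytic_solution(mode)
    vb = np.zeros((ps.N, 3))
    vb[ps.boundary_idx] = exact.velocity(ps.positions[ps.boundary_idx])

    ops = build_operator_bundle(ps, conv_order=conv_order, rc_factor=rc_factor)
    Dx = [Derivative(op) for op in ops.dx]
    Dxx = [Derivative(op) for op in ops.dxx]

    def momentum(v_prev, Pi):
        ps.properties["Pi"][:] = Pi
        Pi_f = get_field(ps, "Pi")
        v_h = get_field(ps, "v")
        system = EquationSet(unknowns=[("v", a) for a in range(3)])
        for a in range(3):
            lap = Dxx[0](v_h[a]) + Dxx[1](v_h[a]) + Dxx[2](v_h[a])
            system.add(lap, Dx[a](Pi_f), ps.bulk_idx, ("v", a))
            system.add(v_h[a], ArrayExpr(ps, vb[:, a]), ps.boundary_idx, ("v", a))
        return system

    v, Pi, report = pressure_correction(momentum, ps, ops, pc_cfg)
    v_exact = exact.velocity(ps.positions)
    diff = np.linalg.norm((v - v_exact)[ps.bulk_idx], axis=1)
    errors = {
        "l2": float(np.sqrt(np.mean(diff**2))),
        "linf": float(np.max(diff)),
        "report": report,
    }
    ps.properties["v"][:] = v
    ps.properties["Pi"][:] = Pi
    return v, Pi, ps, errors
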