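import math

import numpy as np
import pytest
import sympy as sym

from pdekit.active_fluid import (
    ActiveParams,
    ActiveState,
    BENCHMARK_BOX,
    active_stokes_solve,
    init_polarity,
    make_benchmark_state,
    molecular_field,
    passive_active_force,
    polarity_rhs,
    shepard_interpolate,
    step,
    strain_vorticity,
    stress_fields,
)
from pdekit.dcpse import build_operator_bundle
from pdekit.geometry import BoxDomain, grid_particles
from pdekit.solvers import PressureCorrectionConfig

PC = PressureCorrectionConfig(eps=1e-3, max_outer=20)


@pytest.fixture(scope="module")
def bench_21():
    return make_benchmark_state(21)


@pytest.fixture(scope="module")
def ops_21(bench_21):
    return build_operator_bundle(bench_21.ps, mixed=True)


class TestInitPolarity:
    def test_center_value(self):
        """At (Lx/2, Ly/2): A = 2*pi*(cos 0 - sin 0) = 2*pi => p = (0, 1)."""
        ps = grid_particles(BENCHMARK_BOX, 21)
        p = init_polarity(ps, 10.0, 10.0)
        center = np.flatnonzero(
            np.isclose(ps.positions[:, 0], 5.0) & np.isclose(ps.positions[:, 1], 5.0)
        )[0]
        assert p[center] == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_unit_norm(self):
        ps = grid_particles(BENCHMARK_BOX, 21)
        p = init_polarity(ps, 10.0, 10.0)
        assert np.allclose(np.linalg.norm(p, axis=1), 1.0, atol=1e-14)

    def test_independent_scalar_oracle(self):
        """Value at (Lx/2, 3Ly/4) against a from-scratch evaluation."""
        ps = grid_particles(BENCHMARK_BOX, 21)
        p = init_polarity(ps, 10.0, 10.0)
        i = np.flatnonzero(
            np.isclose(ps.positions[:, 0], 5.0) & np.isclose(ps.positions[:, 1], 7.5)
        )[0]
        x, y = 5.0, 7.5
        A = 2 * math.pi * (math.cos((2 * x - 10) / 10) - math.sin((2 * y - 10) / 10))
        assert p[i] == pytest.approx([math.sin(A), math.cos(A)], abs=1e-14)


class TestMolecularField:
    def test_uniform_polarity_zero(self, bench_21, ops_21):
        p = np.tile([0.6, 0.8], (bench_21.ps.N, 1))
        h = molecular_field(p, ops_21, 1.0, 1.0)
        assert np.max(np.abs(h[bench_21.ps.bulk_idx])) < 1e-8

    def test_sine_mode_matches_laplacian(self, bench_21, ops_21):
        """p = (sin kx, 0), Ks=Kb=K: elastic part is (-K k^2 sin kx, 0)."""
        ps = bench_21.ps
        k = 2 * np.pi / 10.0
        p = np.column_stack([np.sin(k * ps.positions[:, 0]), np.zeros(ps.N)])
        he = molecular_field(p, ops_21, 2.0, 2.0, project=False)
        expect = -2.0 * k**2 * np.sin(k * ps.positions[:, 0])
        bulk = ps.bulk_idx
        assert np.max(np.abs(he[bulk, 0] - expect[bulk])) < 30 * ps.h_nominal**2
        assert np.max(np.abs(he[bulk, 1])) < 30 * ps.h_nominal**2

    def test_projection_orthogonal(self, bench_21, ops_21):
        p = init_polarity(bench_21.ps, 10.0, 10.0)
        h = molecular_field(p, ops_21, 1.0, 1.0)
        assert np.max(np.abs(np.sum(p * h, axis=1))) < 1e-10

    def test_unequal_constants_differ_from_laplacian(self, bench_21, ops_21):
        p = init_polarity(bench_21.ps, 10.0, 10.0)
        h_split = molecular_field(p, ops_21, 1.0, 0.0, project=False)
        h_lap = molecular_field(p, ops_21, 1.0, 1.0, project=False)
        assert np.max(np.abs(h_split - h_lap)) > 1e-3


class TestStrainVorticity:
    def test_rigid_rotation(self, bench_21, ops_21):
        ps = bench_21.ps
        v = np.column_stack([-ps.positions[:, 1], ps.positions[:, 0]])
        u, w = strain_vorticity(v, ops_21)
        b = ps.bulk_idx
        assert np.max(np.abs(u[b])) < 1e-8
        assert np.allclose(w[b, 0, 1], -1.0, atol=1e-8)
        assert np.allclose(w[b, 1, 0], 1.0, atol=1e-8)

    def test_simple_shear(self, bench_21, ops_21):
        ps = bench_21.ps
        v = np.column_stack([ps.positions[:, 1], np.zeros(ps.N)])
        u, w = strain_vorticity(v, ops_21)
        b = ps.bulk_idx
        assert np.allclose(u[b, 0, 1], 0.5, atol=1e-8)
        assert np.allclose(w[b, 0, 1], 0.5, atol=1e-8)

    def test_uniform_flow(self, bench_21, ops_21):
        v = np.tile([1.0, -2.0], (bench_21.ps.N, 1))
        u, w = strain_vorticity(v, ops_21)
        b = bench_21.ps.bulk_idx
        assert np.max(np.abs(u[b])) < 1e-8 and np.max(np.abs(w[b])) < 1e-8

    def test_symmetry_structure(self, bench_21, ops_21, rng):
        v = rng.normal(size=(bench_21.ps.N, 2))
        u, w = strain_vorticity(v, ops_21)
        assert np.allclose(u, u.transpose(0, 2, 1))
        assert np.allclose(w, -w.transpose(0, 2, 1))


class TestForce:
    def test_uniform_polarity_zero_force(self, bench_21, ops_21):
        p = np.tile([1.0, 0.0], (bench_21.ps.N, 1))
        h = np.zeros_like(p)
        g = passive_active_force(p, h, ActiveParams(), ops_21)
        assert np.max(np.abs(g[bench_21.ps.bulk_idx])) < 1e-8

    def test_couplings_off(self, bench_21, ops_21):
        p = init_polarity(bench_21.ps, 10.0, 10.0)
        params = ActiveParams(zeta=0.0, nu=0.0)
        h = np.zeros_like(p)  # only zeta/nu terms involve h in the stress
        g = passive_active_force(p, h, params, ops_21)
        assert np.max(np.abs(g[bench_21.ps.bulk_idx])) < 1e-8

    def test_manufactured_symbolic_oracle(self):
        """g for p = (cos th(x), sin th(x)), th = pi x / Lx, against sympy."""
        n = 41
        ps = grid_particles(BENCHMARK_BOX, n)
        ops = build_operator_bundle(ps, mixed=True)
        params = ActiveParams()
        Lx = 10.0
        x_s = sym.Symbol("x")
        th = sym.pi * x_s / Lx
        px_s, py_s = sym.cos(th), sym.sin(th)
        K = params.Ks  # Ks == Kb => elastic field = K lap p
        he_s = [K * sym.diff(c, x_s, 2) for c in (px_s, py_s)]
        # perpendicular projection
        ph = px_s * he_s[0] + py_s * he_s[1]
        h_s = [he_s[0] - ph * px_s, he_s[1] - ph * py_s]
        q = params.zeta * params.dmu
        nu = params.nu
        p2 = px_s**2 + py_s**2
        phh = px_s * h_s[0] + py_s * h_s[1]
        sig = [[None, None], [None, None]]
        comps = (px_s, py_s)
        for a in range(2):
            for b in range(2):
                d_ab = 1 if a == b else 0
                sig[a][b] = (
                    -q * (comps[a] * comps[b] - sym.Rational(1, 2) * p2 * d_ab)
                    + nu / 2 * (comps[a] * h_s[b] + comps[b] * h_s[a] - phh * d_ab)
                    + sym.Rational(1, 2) * (comps[a] * h_s[b] - h_s[a] * comps[b])
                )
        g_s = [sym.diff(sig[a][0], x_s) for a in range(2)]  # d/dy terms vanish
        g_fn = [sym.lambdify(x_s, g, modules="numpy") for g in g_s]

        xv = ps.positions[:, 0]
        p = np.column_stack([np.cos(np.pi * xv / Lx), np.sin(np.pi * xv / Lx)])
        h = molecular_field(p, ops, params.Ks, params.Kb)
        g = passive_active_force(p, h, params, ops)
        bulk = ps.bulk_idx
        pos = ps.positions
        interior = bulk[
            (pos[bulk, 0] > 1.0) & (pos[bulk, 0] < 9.0)
            & (pos[bulk, 1] > 1.0) & (pos[bulk, 1] < 9.0)
        ]
        for a in range(2):
            expect = np.broadcast_to(np.asarray(g_fn[a](xv), dtype=float), (ps.N,))
            err = np.max(np.abs(g[interior, a] - expect[interior]))
            assert err < 50 * ps.h_nominal**2, (a, err)


class TestActiveStokes:
    def test_zero_force_zero_flow(self, bench_21):
        st = make_benchmark_state(21)
        ops = build_operator_bundle(st.ps, mixed=True)
        g = np.zeros((st.ps.N, 2))
        v, Pi, rep = active_stokes_solve(st, ActiveParams(), ops, PC, g=g)
        assert rep.converged
        assert np.max(np.abs(v)) < 1e-8

    def test_gradient_forcing_absorbed_by_pressure(self):
        """g = grad(psi) drives no flow; the pressure absorbs it."""
        st = make_benchmark_state(21)
        ops = build_operator_bundle(st.ps, mixed=True)
        pos = st.ps.positions
        psi = np.sin(np.pi * pos[:, 0] / 10.0) * np.cos(np.pi * pos[:, 1] / 10.0)
        g = ops.gradient(psi)
        v, Pi, rep = active_stokes_solve(st, ActiveParams(), ops, PC, g=g)
        assert rep.converged
        assert np.max(np.abs(v)) < 5e-3  # velocity response ~ discretization error

    def test_activity_sign_flip_reverses_flow(self):
        """With only the active stress present, flipping zeta*dmu reverses v
        pointwise (Stokes linearity in the forcing)."""
        params = dict(nu=0.0, lam=0.0, Ks=0.0, Kb=0.0)  # elastic stress off
        st = make_benchmark_state(21)
        ops = build_operator_bundle(st.ps, mixed=True)
        v1, _, _ = active_stokes_solve(st, ActiveParams(zeta=0.07, **params), ops, PC)
        st2 = make_benchmark_state(21)
        v2, _, _ = active_stokes_solve(st2, ActiveParams(zeta=-0.07, **params), ops, PC)
        scale = np.max(np.abs(v1))
        assert scale > 0
        assert np.max(np.abs(v1 + v2)) < 0.05 * scale

    def test_benchmark_flow_has_multiple_vortices(self):
        """First solve of the benchmark: both velocity components change sign
        along the vertical midline."""
        st = make_benchmark_state(41)
        ops = build_operator_bundle(st.ps, mixed=True)
        v, Pi, rep = active_stokes_solve(st, ActiveParams(), ops, PC)
        assert rep.converged
        mid = np.flatnonzero(np.isclose(st.ps.positions[:, 0], 5.0))
        mid = mid[np.argsort(st.ps.positions[mid, 1])]
        for comp in range(2):
            signs = np.sign(v[mid, comp])
            changes = np.count_nonzero(np.diff(signs[signs != 0]))
            assert changes >= 2, f"component {comp} lacks vortical structure"


class TestPolarityRhs:
    def test_all_zero(self):
        p = np.array([[1.0, 0.0]])
        zero2 = np.zeros((1, 2))
        zero22 = np.zeros((1, 2, 2))
        params = ActiveParams(lam=0.0)
        out = polarity_rhs(p, zero2, zero2, zero22, zero22, params)
        assert np.allclose(out, 0.0)

    def test_pure_vorticity_contraction(self):
        """w_xy = -1, p = (1,0): rhs = (w_xy p_y, w_yx p_x) = (0, 1)."""
        p = np.array([[1.0, 0.0]])
        w = np.array([[[0.0, -1.0], [1.0, 0.0]]])
        params = ActiveParams(lam=0.0)
        out = polarity_rhs(p, np.zeros((1, 2)), np.zeros((1, 2)), np.zeros((1, 2, 2)), w, params)
        assert np.allclose(out, [[0.0, 1.0]])

    def test_lambda_term(self):
        """lam=0.1, dmu=-1, p=(0,1) -> (0, -0.1)."""
        p = np.array([[0.0, 1.0]])
        params = ActiveParams(lam=0.1, dmu=-1.0)
        out = polarity_rhs(p, np.zeros((1, 2)), np.zeros((1, 2)),
                           np.zeros((1, 2, 2)), np.zeros((1, 2, 2)), params)
        assert np.allclose(out, [[0.0, -0.1]])


class TestStep:
    def test_zero_activity_uniform_fixed_point(self):
        st = make_benchmark_state(21)
        p0 = np.tile([1.0, 0.0], (st.ps.N, 1))
        st = ActiveState(ps=st.ps, p=p0.copy(), v=st.v, Pi=st.Pi, p_anchor=p0.copy())
        params = ActiveParams(zeta=0.0, lam=0.0, dt=1e-4)
        out = step(st, params, PC)
        assert np.max(np.abs(out.v)) < 1e-8
        assert np.max(np.abs(out.p - p0)) < 1e-10
        assert np.array_equal(out.ps.positions, st.ps.positions)

    def test_benchmark_step_keeps_unit_norm(self):
        st = make_benchmark_state(41)
        out = step(st, ActiveParams(dt=2e-7), PC)
        assert np.max(np.abs(np.linalg.norm(out.p, axis=1) - 1.0)) < 1e-12
        assert np.array_equal(out.p[out.ps.boundary_idx], st.p_anchor[st.ps.boundary_idx])
        assert np.array_equal(
            out.ps.positions[out.ps.boundary_idx], st.ps.positions[st.ps.boundary_idx]
        )

    def test_halved_step_euler_consistency(self):
        """Two half steps vs one full step differ at O(dt^2) in positions."""

        def diff(dt):
            full = step(make_benchmark_state(21), ActiveParams(dt=dt), PC)
            half = step(
                step(make_benchmark_state(21), ActiveParams(dt=dt / 2), PC),
                ActiveParams(dt=dt / 2), PC,
            )
            return np.max(np.abs(full.ps.positions - half.ps.positions))

        d_big, d_small = diff(4e-4), diff(2e-4)
        assert d_small < 0.35 * d_big  # quadratic local error would give 0.25


class TestShepard:
    def test_exact_at_coincident_points(self, rng):
        pts = rng.uniform(size=(50, 2))
        vals = rng.normal(size=(50, 2))
        out = shepard_interpolate(pts, vals, pts, k=4)
        assert np.allclose(out, vals, atol=1e-8)

    def test_constant_field_reproduced(self, rng):
        pts = rng.uniform(size=(100, 2))
        vals = np.full((100,), 3.5)
        dst = rng.uniform(0.2, 0.8, size=(20, 2))
        out = shepard_interpolate(pts, vals, dst)
        assert np.allclose(out, 3.5)
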