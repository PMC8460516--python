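import numpy as np
import pytest
import scipy.sparse as sp

from pdekit.dcpse import MultiIndex, OperatorSpec, build_fd, build_operator_bundle
from pdekit.expr import (
    ArrayExpr,
    Derivative,
    EquationSet,
    EvaluationError,
    ExpressionError,
    NonlinearExpressionError,
    assemble,
    assign,
    evaluate,
    get_field,
)
from pdekit.geometry import BoxDomain, grid_particles
from pdekit.solvers import solve_linear


@pytest.fixture
def ps_fields(unit_lattice_21):
    ps = unit_lattice_21.copy()
    ps.add_property("P", ps.positions[:, 0] + 2 * ps.positions[:, 1])
    ps.add_property("V", rank="vector")
    ps.add_property("T", rank="tensor")
    return ps


class TestGetField:
    def test_scalar_handle(self, ps_fields):
        h = get_field(ps_fields, "P")
        assert h.rank == "scalar" and h.is_scalar_valued

    def test_vector_component(self, ps_fields):
        h = get_field(ps_fields, "V", "x")
        assert h.is_scalar_valued
        assert evaluate(h).shape == (ps_fields.N,)

    def test_tensor_component(self, ps_fields):
        h = get_field(ps_fields, "T")[("x", "y")]
        assert h.is_scalar_valued

    def test_unknown_property(self, ps_fields):
        with pytest.raises(ExpressionError):
            get_field(ps_fields, "nope")

    def test_invalid_component(self, ps_fields):
        with pytest.raises(ExpressionError):
            get_field(ps_fields, "V", 5)


class TestEvaluate:
    def test_derivative_of_constant_plus_five(self, ps_fields):
        ops = build_operator_bundle(ps_fields)
        Dx, Dy = Derivative(ops.dx[0]), Derivative(ops.dx[1])
        ps_fields.properties["P"][:] = 4.2
        P = get_field(ps_fields, "P")
        out = evaluate(Dx(P) + Dy(P) + 5.0)
        assert np.allclose(out[ps_fields.bulk_idx], 5.0, atol=1e-8)

    def test_linear_field_gives_eight(self, ps_fields):
        ops = build_operator_bundle(ps_fields)
        Dx, Dy = Derivative(ops.dx[0]), Derivative(ops.dx[1])
        P = get_field(ps_fields, "P")  # P = x + 2y
        out = evaluate(Dx(P) + Dy(P) + 5.0)
        assert np.allclose(out, 8.0, atol=1e-8)

    def test_mul_div_roundtrip(self, ps_fields, rng):
        f = rng.normal(size=ps_fields.N)
        g = rng.uniform(1.0, 2.0, size=ps_fields.N)
        fe, ge = ArrayExpr(ps_fields, f), ArrayExpr(ps_fields, g)
        out = evaluate((fe * ge) / ge)
        assert np.allclose(out, f, rtol=1e-14)

    def test_division_by_zero_names_particle(self, ps_fields):
        g = np.ones(ps_fields.N)
        g[17] = 0.0
        with pytest.raises(EvaluationError, match="particle 17"):
            evaluate(ArrayExpr(ps_fields, np.ones(ps_fields.N)) / ArrayExpr(ps_fields, g))

    def test_mixed_particle_sets_rejected(self, ps_fields, unit_lattice_21):
        other = unit_lattice_21.copy()
        other.add_property("Q", np.ones(other.N))
        with pytest.raises(ExpressionError):
            get_field(ps_fields, "P") + get_field(other, "Q")

    def test_backend_agnostic_evaluation(self, ps_fields):
        """Identical trees with FD vs DC-PSE operators agree to O(h^2)."""
        ps = ps_fields
        dc = build_operator_bundle(ps, backend="dcpse")
        fd = build_operator_bundle(ps, backend="fd")
        ps.properties["P"][:] = np.sin(ps.positions[:, 0]) * np.cos(ps.positions[:, 1])
        P = get_field(ps, "P")
        out_dc = evaluate(Derivative(dc.dx[0])(P) * 2.0 - Derivative(dc.dxx[1])(P))
        out_fd = evaluate(Derivative(fd.dx[0])(P) * 2.0 - Derivative(fd.dxx[1])(P))
        assert np.max(np.abs((out_dc - out_fd)[ps.bulk_idx])) < 10 * ps.h_nominal**2


class TestAssign:
    def test_component_assignment(self, ps_fields):
        V = get_field(ps_fields, "V")
        ps_fields.properties["V"][:, 1] = 2.0
        assign(V["x"], 5.0)
        assert np.all(ps_fields.properties["V"][:, 0] == 5.0)
        assert np.all(ps_fields.properties["V"][:, 1] == 2.0)

    def test_copy_before_write(self, ps_fields):
        ops = build_operator_bundle(ps_fields)
        Dx = Derivative(ops.dx[0])
        P = get_field(ps_fields, "P")
        before = evaluate(Dx(P))
        assign(P, Dx(P))
        assert np.allclose(ps_fields.properties["P"], before)

    def test_subset_assignment(self, ps_fields):
        P = get_field(ps_fields, "P")
        bulk_before = ps_fields.properties["P"][ps_fields.bulk_idx].copy()
        assign(P, -1.0, subset=ps_fields.boundary_idx)
        assert np.all(ps_fields.properties["P"][ps_fields.boundary_idx] == -1.0)
        assert np.array_equal(ps_fields.properties["P"][ps_fields.bulk_idx], bulk_before)


class TestAssemble:
    def test_identity_equation(self, ps_fields):
        P = get_field(ps_fields, "P")
        system = EquationSet(unknowns=[("P", None)])
        system.add(P, 3.0, np.arange(ps_fields.N), ("P", None))
        A, b, _ = assemble(system)
        assert (A != sp.eye(ps_fields.N)).nnz == 0
        assert np.all(b == 3.0)

    def test_1d_poisson_tridiagonal_oracle(self):
        """FD Dxx rows on a line of the lattice reproduce (1,-2,1)/h^2."""
        nx = 21
        box = BoxDomain((0.0, 0.0), (1.0, 0.1))
        ps = grid_particles(box, (nx, 3))
        h = ps.h_nominal
        ps.add_property("u")
        u = get_field(ps, "u")
        dxx = build_fd(ps, OperatorSpec(MultiIndex((2, 0))))
        # middle line j=1
        line = np.array([i * 3 + 1 for i in range(nx)])
        interior = line[1:-1]
        ends = line[[0, -1]]
        rest = np.setdiff1d(np.arange(ps.N), line)
        system = EquationSet(unknowns=[("u", None)])
        system.add(Derivative(dxx)(u), 1.0, interior, ("u", None))
        system.add(u, 0.0, ends, ("u", None))
        system.add(u, 0.0, rest, ("u", None))
        A, b, _ = assemble(system)
        A = A.tocsr()
        inv_h2 = 1.0 / h**2
        for i, p in enumerate(interior):
            row = A[p].toarray().ravel()
            expect = np.zeros(ps.N)
            expect[p - 3] = inv_h2
            expect[p] = -2 * inv_h2
            expect[p + 3] = inv_h2
            assert np.allclose(row, expect)
        for p in ends:
            row = A[p].toarray().ravel()
            assert row[p] == 1.0 and np.count_nonzero(row) == 1

    def test_nonlinearity_error(self, ps_fields):
        ops = build_operator_bundle(ps_fields)
        Dx = Derivative(ops.dx[0])
        P = get_field(ps_fields, "P")
        system = EquationSet(unknowns=[("P", None)])
        system.add(P * Dx(P), 0.0, ps_fields.bulk_idx, ("P", None))
        system.add(P, 0.0, ps_fields.boundary_idx, ("P", None))
        with pytest.raises(NonlinearExpressionError):
            assemble(system)

    def test_unknown_in_rhs_rejected(self, ps_fields):
        P = get_field(ps_fields, "P")
        system = EquationSet(unknowns=[("P", None)])
        system.add(P, P * 2.0, np.arange(ps_fields.N), ("P", None))
        with pytest.raises(ExpressionError):
            assemble(system)

    def test_coverage_errors(self, ps_fields):
        P = get_field(ps_fields, "P")
        system = EquationSet(unknowns=[("P", None)])
        system.add(P, 0.0, ps_fields.bulk_idx, ("P", None))  # boundary uncovered
        with pytest.raises(ExpressionError, match="uncovered"):
            assemble(system)
        system2 = EquationSet(unknowns=[("P", None)])
        system2.add(P, 0.0, np.arange(ps_fields.N), ("P", None))
        system2.add(P, 1.0, np.array([0]), ("P", None))
        with pytest.raises(ExpressionError, match="doubly covered"):
            assemble(system2)

    def test_matrix_free_consistency(self, ps_fields, rng):
        """A @ x equals the lhs evaluated at unknowns = x, minus constants."""
        ps = ps_fields
        ops = build_operator_bundle(ps)
        Dx, Dyy = Derivative(ops.dx[0]), Derivative(ops.dxx[1])
        ps.add_property("w")
        w = get_field(ps, "w")
        coeff = ArrayExpr(ps, rng.uniform(0.5, 1.5, ps.N))
        lhs = coeff * Dx(w) - 3.0 * Dyy(w) + w * 2.0
        system = EquationSet(unknowns=[("w", None)])
        system.add(lhs, 0.0, np.arange(ps.N), ("w", None))
        A, b, _ = assemble(system)
        x = rng.normal(size=ps.N)
        ps.properties["w"][:] = x
        direct = evaluate(lhs)
        assert np.allclose(A @ x, direct, atol=1e-10)

    def test_manufactured_poisson_recovery(self):
        """assemble+solve recovers a manufactured solution at order r=2."""
        errs, hs = [], []
        for n in (21, 41):
            ps = grid_particles(BoxDomain((0, 0), (1, 1)), n)
            ops = build_operator_bundle(ps)
            x, y = ps.positions.T
            ustar = np.sin(np.pi * x) * np.sin(np.pi * y)
            ps.add_property("u")
            ps.add_property("f", -2 * np.pi**2 * ustar)
            u, f = get_field(ps, "u"), get_field(ps, "f")
            D2 = [Derivative(o) for o in ops.dxx]
            system = EquationSet(unknowns=[("u", None)])
            system.add(D2[0](u) + D2[1](u), f, ps.bulk_idx, ("u", None))
            system.add(u, 0.0, ps.boundary_idx, ("u", None))
            A, b, _ = assemble(system)
            sol = solve_linear(A, b)
            errs.append(np.max(np.abs(sol - ustar)))
            hs.append(ps.h_nominal)
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert slope > 1.5
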