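"""Linear solves behind one interface, and the steady pressure-correction loop.

The pressure-correction driver enforces incompressibility for *any*
momentum assembler: it repeatedly solves the momentum system at the current
pressure, solves a Poisson equation for a correction potential whose
gradient removes the divergence of the intermediate velocity, corrects
velocity and pressure, and iterates until the max-norm of the discrete
divergence over the bulk drops below a user tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dcpse import OperatorBundle
from .expr import EquationSet, _linearize, assemble
from .geometry import ParticleSet

__all__ = [
    "LinearSolverConfig",
    "PressureCorrectionConfig",
    "SolveReport",
    "LinearSolveError",
    "solve_linear",
    "CachedDirectSolver",
    "pressure_correction",
]


class LinearSolveError(RuntimeError):
    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class LinearSolverConfig:
    method: str = "direct"  # "direct" | "gmres"
    rtol: float = 1e-10
    max_iter: int = 2000
    restart: int = 100

    def __post_init__(self):
        if not self.rtol > 0:
            raise ValueError("rtol must be positive")
        if self.method not in ("direct", "gmres"):
            raise ValueError(f"unknown method {self.method!r}")


def solve_linear(A: sp.spmatrix, b: np.ndarray, cfg: LinearSolverConfig | None = None) -> np.ndarray:
    """Solve ``A x = b`` with a sparse direct factorization or GMRES+ILU."""
    cfg = cfg or LinearSolverConfig()
    A = A.tocsc()
    b = np.asarray(b, dtype=float)
    if A.shape[0] != A.shape[1] or A.shape[0] != b.shape[0]:
        raise ValueError("A must be square and conforming with b")
    if cfg.method == "direct":
        try:
            lu = spla.splu(A)
            x = lu.solve(b)
        except RuntimeError as exc:
            raise LinearSolveError(f"direct factorization failed: {exc}") from exc
        if not np.all(np.isfinite(x)):
            raise LinearSolveError("singular system: direct solve returned non-finite values")
        return x
    try:
        ilu = spla.spilu(A, drop_tol=1e-5, fill_factor=20)
        M = spla.LinearOperator(A.shape, ilu.solve)
    except RuntimeError:
        M = None
    x, info = spla.gmres(
        A, b, rtol=cfg.rtol, atol=0.0, restart=cfg.restart, maxiter=cfg.max_iter, M=M
    )
    res = float(np.linalg.norm(A @ x - b))
    if info != 0 or not np.all(np.isfinite(x)):
        raise LinearSolveError(
            f"GMRES did not converge (info={info}, residual={res:.3e})", residual=res
        )
    return x


class CachedDirectSolver:
    """Direct solver that reuses its LU factor while the matrix is unchanged.

    Pressure-correction (and Picard) loops repeatedly solve with the same
    matrix and varying right-hand sides; recognizing an unchanged CSR
    structure+data avoids refactorizing.
    """

    def __init__(self, cfg: LinearSolverConfig | None = None):
        self.cfg = cfg or LinearSolverConfig()
        self._key = None
        self._lu = None

    def solve(self, A: sp.spmatrix, b: np.ndarray) -> np.ndarray:
        if self.cfg.method != "direct":
            return solve_linear(A, b, self.cfg)
        A = A.tocsc()
        same = (
            self._key is not None
            and self._key[0] == A.shape
            and self._key[1] == A.nnz
            and np.array_equal(self._key[2], A.indptr)
            and np.array_equal(self._key[3], A.indices)
            and np.array_equal(self._key[4], A.data)
        )
        if not same:
            try:
                self._lu = spla.splu(A)
            except RuntimeError as exc:
                raise LinearSolveError(f"direct factorization failed: {exc}") from exc
            self._key = (A.shape, A.nnz, A.indptr.copy(), A.indices.copy(), A.data.copy())
        x = self._lu.solve(np.asarray(b, dtype=float))
        if not np.all(np.isfinite(x)):
            raise LinearSolveError("singular system: direct solve returned non-finite values")
        return x


@dataclass(frozen=True)
class PressureCorrectionConfig:
    eps: float = 1e-4          # max-norm divergence tolerance over bulk
    max_outer: int = 100
    relax_p: float = 1.0
    linear: LinearSolverConfig = dc_field(default_factory=LinearSolverConfig)

    def __post_init__(self):
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if not 0 < self.relax_p <= 1:
            raise ValueError("relax_p must be in (0, 1]")


@dataclass
class SolveReport:
    outer_iters: int = 0
    div_history: list = dc_field(default_factory=list)
    converged: bool = False
    extras: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outer_iters": self.outer_iters,
            "div_history": [float(v) for v in self.div_history],
            "converged": bool(self.converged),
            **{k: v for k, v in self.extras.items()},
        }


def _phi_poisson_system(ps: ParticleSet, ops: OperatorBundle) -> tuple:
    """Assemble the correction-potential Poisson matrix once.

    The Laplacian is the exact composition divergence ∘ bulk-mask ∘ gradient
    of the discrete first-derivative operators, so that subtracting
    ``grad(phi)`` on the bulk cancels the measured divergence identically
    (no operator commutation residual).  Boundary rows impose homogeneous
    Neumann ``n · grad(phi) = 0``; one *boundary* reference particle is
    pinned to zero to remove the constant nullspace, so every bulk
    divergence row is retained.
    """
    N = ps.N
    mask = np.zeros(N)
    mask[ps.bulk_idx] = 1.0
    Mb = sp.diags(mask)
    L = None
    for op in ops.dx:
        term = op.matrix @ Mb @ op.matrix
        L = term if L is None else L + term
    if len(ps.boundary_idx):
        ref = int(ps.boundary_idx[0])
        bnd_wo_ref = ps.boundary_idx[ps.boundary_idx != ref]
    else:
        ref = int(ps.bulk_idx[0])
        bnd_wo_ref = ps.boundary_idx
    rhs_rows = ps.bulk_idx if ref not in ps.bulk_idx else ps.bulk_idx[ps.bulk_idx != ref]
    neum = None
    for k, op in enumerate(ops.dx):
        term = sp.diags(ps.normals[:, k]) @ op.matrix
        neum = term if neum is None else neum + term
    L = L.tocsr()
    neum = neum.tocsr()
    pin = sp.csr_matrix((np.ones(1), (np.zeros(1, dtype=np.intp), [ref])), shape=(1, N))
    parts = sp.vstack([L[rhs_rows], pin, neum[bnd_wo_ref]])
    order = np.concatenate([rhs_rows, [ref], bnd_wo_ref])
    A = parts[np.argsort(order)].tocsc()
    return A, ref, rhs_rows


def _pressure_jacobian(system: EquationSet, pressure_key: tuple, N: int) -> sp.csr_matrix:
    """d(b)/d(Pi) of the assembled momentum rhs, extracted structurally.

    Treats the pressure field as the sole unknown slot and linearizes
    ``rhs - lhs`` of every equation; rows follow the assemble() ordering.
    The momentum system is affine in the pressure in every app here, so this
    matrix turns each Schur matvec into a sparse matvec plus a cached
    triangular solve instead of a full re-assembly.
    """
    slots = {pressure_key: 0}
    K = len(system.unknowns)
    rows_parts, cols_parts, data_parts = [], [], []
    order = {key: s for s, key in enumerate(system.unknowns)}
    for eq in system.equations:
        s = order[eq.unknown]
        M_l, _ = _linearize(eq.lhs, slots, N)
        M_r, _ = _linearize(eq.rhs, slots, N)
        M = None
        if M_r is not None:
            M = M_r
        if M_l is not None:
            M = (-M_l) if M is None else M - M_l
        if M is None:
            continue
        sub = M[eq.subset].tocoo()
        rows_parts.append(s * N + eq.subset[sub.row])
        cols_parts.append(sub.col)
        data_parts.append(sub.data)
    if not rows_parts:
        return sp.csr_matrix((K * N, N))
    return sp.coo_matrix(
        (
            np.concatenate(data_parts),
            (np.concatenate(rows_parts), np.concatenate(cols_parts)),
        ),
        shape=(K * N, N),
    ).tocsr()


def _momentum_structure(system: EquationSet, pressure_key: tuple, N: int, bulk):
    """Full-row linearization of the bulk momentum equations.

    For every equation imposed on (a subset of) the bulk — i.e. the PDE rows,
    as opposed to Dirichlet boundary rows — linearize ``lhs - rhs`` with
    respect to the velocity slots and the pressure, over *all* N particles.
    Returns ``(A_v, B_pi, c)`` with block-row ordering ``s*N + particle``
    such that the momentum residual is ``A_v x - B_pi Pi - c``.

    This lets the pressure update impose the normal component of the
    momentum equation at boundary particles (the consistent pressure
    boundary closure) without knowing the application's viscosity or
    forcing.
    """
    slots = {key: s for s, key in enumerate(system.unknowns)}
    K = len(slots)
    slots_all = dict(slots)
    slots_all[pressure_key] = K  # pressure appended as one extra slot
    zero_row = sp.csr_matrix((N, (K + 1) * N))
    blocks = [zero_row] * K
    c = np.zeros(K * N)
    for eq in system.equations:
        s = slots[eq.unknown]
        if eq.subset.size == 0 or not np.all(np.isin(eq.subset, bulk)):
            continue  # only PDE rows; boundary-value equations are skipped
        M_l, c_l = _linearize(eq.lhs, slots_all, N)
        M_r, c_r = _linearize(eq.rhs, slots_all, N)
        M = M_l if M_r is None else (M_l - M_r if M_l is not None else -M_r)
        if M is None:
            continue
        blocks[s] = M
        cl = c_l if not np.isscalar(c_l) else np.full(N, c_l)
        cr = c_r if not np.isscalar(c_r) else np.full(N, c_r)
        c[s * N : (s + 1) * N] = cl - cr
    M_all = sp.vstack(blocks).tocsr()
    # residual(lhs - rhs) = M_v x + M_p Pi + c
    return M_all[:, : K * N], M_all[:, K * N :], c


def pressure_correction(
    momentum,
    ps: ParticleSet,
    ops: OperatorBundle,
    cfg: PressureCorrectionConfig | None = None,
    v0: np.ndarray | None = None,
    Pi0: np.ndarray | None = None,
    pressure_key: tuple = ("Pi", None),
):
    """Iterate momentum solve / Poisson correction until the bulk divergence
    max-norm is below ``cfg.eps``.

    Parameters
    ----------
    momentum
        Callback ``momentum(v_prev, Pi) -> EquationSet`` producing a
        well-posed linear system for the velocity components (one unknown
        slot per axis, in axis order); velocity boundary rows are imposed
        inside the callback.
    Returns
    -------
    (v, Pi, report)
    """
    cfg = cfg or PressureCorrectionConfig()
    N, d = ps.N, ps.d
    v = np.zeros((N, d)) if v0 is None else np.array(v0, dtype=float)
    Pi = np.zeros(N) if Pi0 is None else np.array(Pi0, dtype=float)
    bulk = ps.bulk_idx
    bnd = ps.boundary_idx

    A_phi, ref, phi_rhs_rows = _phi_poisson_system(ps, ops)
    phi_solver = CachedDirectSolver(LinearSolverConfig(method="direct"))
    mom_solver = CachedDirectSolver(cfg.linear)

    def unpack(x, index_map):
        vs = np.empty((N, d))
        for key, s in index_map.items():
            vs[:, _axis_of(key, index_map)] = x[s * N : (s + 1) * N]
        return vs

    report = SolveReport()
    for it in range(cfg.max_outer):
        v_prev = v
        system = momentum(v_prev, Pi)
        A_mom, b_mom, imap = assemble(system)
        v_star = unpack(mom_solver.solve(A_mom, b_mom), imap)
        div_star = ops.divergence(v_star)
        dmax = float(np.max(np.abs(div_star[bulk]))) if len(bulk) else 0.0
        report.div_history.append(dmax)
        report.outer_iters = it + 1

        # project: solve L phi = div(v*), subtract grad(phi) on the bulk
        b_phi = np.zeros(N)
        b_phi[phi_rhs_rows] = div_star[phi_rhs_rows]
        phi = phi_solver.solve(A_phi, b_phi)
        grad_phi = ops.gradient(phi)
        v = v_star.copy()
        v[bulk] -= grad_phi[bulk]

        if dmax <= cfg.eps:
            report.converged = True
            break

        # pressure update: solve the divergence-pressure (Schur) map for the
        # correction dPi with div(v*(Pi + dPi)) = 0 on the bulk, using the
        # cached momentum factorization for each matvec.  Fixed-point
        # updates (Pi += phi or Pi -= mu*div) stall algebraically on
        # corner-singular geometries; a Krylov solve of the same affine map
        # converges mesh-independently.
        # pressure update: solve the divergence-pressure (Schur) map for the
        # correction dPi that makes div(v*(Pi + dPi)) vanish on the bulk.
        # Boundary rows impose the normal component of the momentum equation
        # at boundary particles (consistent pressure boundary closure,
        # extracted structurally from the equation set); the mean(q) term
        # deflates the constant-pressure nullspace.
        B = _pressure_jacobian(system, pressure_key, N)
        M_v, M_p, c_mom = _momentum_structure(system, pressure_key, N, bulk)
        ncontract = sp.csr_matrix(
            (
                ps.normals[bnd].T.ravel(),
                (
                    np.tile(bnd, d),
                    np.concatenate([s * N + bnd for s in range(d)]),
                ),
            ),
            shape=(N, d * N),
        )
        nMv = ncontract @ M_v         # N x dN, rows only at bnd
        nMp = ncontract @ M_p         # N x N
        x_star = np.concatenate([v_star[:, _axis_of(k, imap)] for k in
                                 sorted(imap, key=imap.get)])
        mom_resid_bnd = (nMv @ x_star) + (nMp @ Pi) + (ncontract @ c_mom)

        def schur_matvec(q):
            x_q = mom_solver.solve(A_mom, B @ q)
            r = ops.divergence(unpack(x_q, imap))
            r[bnd] = (nMv @ x_q + nMp @ q)[bnd]
            return r + np.mean(q)

        rhs = -div_star.copy()
        rhs[bnd] = -mom_resid_bnd[bnd]
        S = spla.LinearOperator((N, N), matvec=schur_matvec)
        atol = max(0.2 * cfg.eps, 0.02 * float(np.linalg.norm(rhs)), 1e-12)
        d_pi, info = spla.lgmres(S, rhs, rtol=1e-12, atol=atol, maxiter=50)
        if info != 0:
            report.extras["schur_info"] = int(info)
        Pi = Pi + cfg.relax_p * d_pi

    div_corr = ops.divergence(v)
    report.extras["div_corrected"] = (
        float(np.max(np.abs(div_corr[bulk]))) if len(bulk) else 0.0
    )
    return v, Pi, report


def _axis_of(key, index_map) -> int:
    # unknown slots are velocity components; their declared order gives the axis
    ordered = sorted(index_map, key=index_map.get)
    return ordered.index(key) if key[1] is None else key[1]
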