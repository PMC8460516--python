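"""Derivative operators on scattered particles.

Two backends share one contract (explicit application plus sparse-row
extraction):

* ``build_dcpse`` — kernel weights on arbitrary point clouds, corrected per
  evaluation point so the discrete operator is exact on all monomials of
  total degree ``<= |beta| + r - 1``.  Among all weight vectors satisfying
  those moment conditions, the one minimizing ``sum_q w_q^2 exp(+|z_q|^2)``
  is returned (Gaussian-windowed minimal norm; ``z_q`` is the neighbor
  offset scaled by the nominal spacing).
* ``build_fd`` — classical second-order central stencils on unjittered
  lattices, with one-sided second-order closures on the faces, wrapped in
  the same :class:`DiffOp` container so downstream code is backend-agnostic.

The evaluation point itself is always part of its stencil, and the zeroth
moment condition forces weights of any true derivative to sum to zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import NeighborLists, ParticleSet, neighbor_search

__all__ = [
    "MultiIndex",
    "OperatorSpec",
    "DiffOp",
    "OperatorBuildError",
    "build_dcpse",
    "build_dcpse_family",
    "build_fd",
    "apply_op",
    "op_rows",
    "OperatorBundle",
    "build_operator_bundle",
]

DEFAULT_RC_FACTOR = 3.1
DEFAULT_COND_THRESHOLD = 1e12


class OperatorBuildError(RuntimeError):
    """Raised when the per-particle moment system cannot be solved."""


@dataclass(frozen=True)
class MultiIndex:
    """Derivative multi-index beta (one non-negative exponent per axis)."""

    components: tuple

    def __post_init__(self):
        comps = tuple(int(c) for c in self.components)
        if any(c < 0 for c in comps):
            raise ValueError("multi-index components must be non-negative")
        object.__setattr__(self, "components", comps)

    @property
    def order(self) -> int:
        return sum(self.components)

    @property
    def d(self) -> int:
        return len(self.components)

    def factorial(self) -> float:
        return float(math.prod(math.factorial(c) for c in self.components))


@dataclass(frozen=True)
class OperatorSpec:
    beta: MultiIndex
    conv_order: int = 2
    rc_factor: float = DEFAULT_RC_FACTOR

    def __post_init__(self):
        if self.conv_order < 1:
            raise ValueError("conv_order must be >= 1")
        if self.beta.order < 1:
            raise ValueError("derivative operators require |beta| >= 1")

    @property
    def degmax(self) -> int:
        """Highest monomial degree reproduced exactly."""
        return self.beta.order + self.conv_order - 1


def monomial_multiindices(d: int, degmax: int) -> list:
    """All multi-indices with 0 <= |alpha| <= degmax, degree-major order.

    Degree-major ordering guarantees that the condition set for a lower
    ``degmax`` is a prefix of the one for a higher ``degmax``, which lets a
    family of operators share one moment (Gram) matrix.
    """
    out = []
    for deg in range(degmax + 1):
        def rec(prefix, remaining, axes_left):
            if axes_left == 1:
                out.append(tuple(prefix + [remaining]))
                return
            for c in range(remaining, -1, -1):
                rec(prefix + [c], remaining - c, axes_left - 1)
        rec([], deg, d)
    return out


class DiffOp:
    """A discretized derivative: per-point stencils stored as a sparse matrix.

    ``matrix`` is N x N CSR with nonzero rows exactly at ``eval_idx``;
    row p holds the stencil weights w_pq (units length^-|beta|).
    """

    def __init__(self, spec: OperatorSpec, eval_idx: np.ndarray, matrix: sp.csr_matrix):
        self.spec = spec
        self.eval_idx = np.asarray(eval_idx, dtype=np.intp)
        self.matrix = matrix.tocsr()
        self._mask = np.zeros(matrix.shape[0], dtype=bool)
        self._mask[self.eval_idx] = True

    @property
    def N(self) -> int:
        return self.matrix.shape[0]

    def stencil(self, p: int):
        """(neighbor indices, weights) of the stencil at particle p."""
        row = self.matrix.getrow(p)
        return row.indices.copy(), row.data.copy()

    def defined_at(self, idx) -> bool:
        return bool(np.all(self._mask[idx]))


def apply_op(op: DiffOp, values: np.ndarray) -> np.ndarray:
    """Explicit application: ``out[p] = sum_q w_pq values[q]``.

    Rows outside ``eval_idx`` are zero.  Works column-wise on (N, m) input.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != op.N:
        raise ValueError(f"field has leading dimension {values.shape[0]}, expected {op.N}")
    return op.matrix @ values


def op_rows(op: DiffOp, rows_for) -> tuple:
    """Sparse triplets (row, col, weight) reproducing apply_op on *rows_for*."""
    rows_for = np.asarray(rows_for, dtype=np.intp)
    if rows_for.size and not op.defined_at(rows_for):
        raise ValueError("requested rows outside the operator's eval_idx")
    sub = op.matrix[rows_for]
    coo = sub.tocoo()
    return rows_for[coo.row], coo.col.astype(np.intp), coo.data


# ---------------------------------------------------------------------------
# DC-PSE construction
# ---------------------------------------------------------------------------

def build_dcpse_family(
    ps: ParticleSet,
    nbrs: NeighborLists,
    specs: list,
    eval_idx=None,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> list:
    """Build several DC-PSE operators sharing one neighbor structure.

    All operators use local scale ``eps = h_nominal`` and stencils containing
    the evaluation point itself.  Particles are processed in groups of equal
    neighbor count so the per-particle moment solves batch into stacked
    ``np.linalg.solve`` calls.
    """
    if not specs:
        return []
    d = ps.d
    eps = ps.h_nominal
    if eval_idx is None:
        eval_idx = np.arange(ps.N)
    eval_idx = np.asarray(eval_idx, dtype=np.intp)

    degmax_all = max(s.degmax for s in specs)
    alphas = monomial_multiindices(d, degmax_all)
    alpha_arr = np.asarray(alphas, dtype=np.intp)  # (n_cond, d)
    n_cond_of = {}
    rhs_of = {}
    for s in specs:
        sub = [a for a in alphas if sum(a) <= s.degmax]
        n_b = len(sub)
        n_cond_of[s] = n_b
        b = np.zeros(n_b)
        b[sub.index(s.beta.components)] = s.beta.factorial()
        rhs_of[s] = b
    n_cond_min = {s: n_cond_of[s] for s in specs}

    counts = nbrs.counts()[eval_idx]
    need = max(n_cond_of.values())
    starved = eval_idx[(counts + 1) < need]
    if starved.size:
        raise OperatorBuildError(
            f"particle {int(starved[0])} has only {int(counts[(counts + 1) < need][0])} "
            f"neighbors; need at least {need - 1} (plus itself) for the requested operators"
        )

    rows_all = {s: [] for s in specs}
    cols_all = {s: [] for s in specs}
    data_all = {s: [] for s in specs}
    max_cond = 0.0

    order = np.argsort(counts, kind="stable")
    sorted_idx = eval_idx[order]
    sorted_counts = counts[order]
    boundaries = np.flatnonzero(np.diff(sorted_counts)) + 1
    groups = np.split(np.arange(sorted_idx.size), boundaries)

    pos = ps.positions
    for grp in groups:
        pts = sorted_idx[grp]
        k = int(sorted_counts[grp[0]])
        nbr_idx = np.empty((pts.size, k + 1), dtype=np.intp)
        nbr_idx[:, 0] = pts  # self first
        for i, p in enumerate(pts):
            nbr_idx[i, 1:] = nbrs.lists[p]
        z = (pos[nbr_idx] - pos[pts][:, None, :]) / eps  # (G, k+1, d)
        # monomial matrix M[g, i, q] = prod_dim z^alpha_i
        M = np.ones((pts.size, alpha_arr.shape[0], k + 1))
        for dim in range(d):
            maxp = int(alpha_arr[:, dim].max())
            if maxp == 0:
                continue
            powers = np.ones((pts.size, maxp + 1, k + 1))
            for pw in range(1, maxp + 1):
                powers[:, pw] = powers[:, pw - 1] * z[:, :, dim]
            M *= powers[:, alpha_arr[:, dim], :]
        G = np.exp(-np.sum(z * z, axis=-1))  # window weights (G, k+1)
        K_full = np.einsum("gik,gk,gjk->gij", M, G, M)

        for s in specs:
            nb = n_cond_of[s]
            Kb = K_full[:, :nb, :nb]
            rhs = np.broadcast_to(rhs_of[s], (pts.size, nb))
            try:
                lam = np.linalg.solve(Kb, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                bad = _first_singular(Kb, pts)
                raise OperatorBuildError(
                    f"rank-deficient moment system at particle {bad} "
                    f"for beta={s.beta.components}"
                ) from None
            w_scaled = G * np.einsum("gik,gi->gk", M[:, :nb, :], lam)
            resid = np.einsum("gik,gk->gi", M[:, :nb, :], w_scaled) - rhs
            bad = np.flatnonzero(np.max(np.abs(resid), axis=1) > 1e-7)
            if bad.size:
                raise OperatorBuildError(
                    f"degenerate neighborhood at particle {int(pts[bad[0]])} "
                    f"for beta={s.beta.components} (moment residual "
                    f"{float(np.max(np.abs(resid[bad[0]]))):.2e})"
                )
            w = w_scaled / eps ** s.beta.order
            rows_all[s].append(np.repeat(pts, k + 1))
            cols_all[s].append(nbr_idx.ravel())
            data_all[s].append(w.ravel())
        max_cond = max(max_cond, float(np.max(np.linalg.cond(K_full))))

    if max_cond > cond_threshold:
        warnings.warn(
            f"DC-PSE moment matrix condition number {max_cond:.2e} exceeds "
            f"threshold {cond_threshold:.1e}",
            RuntimeWarning,
            stacklevel=2,
        )

    ops = []
    for s in specs:
        rows = np.concatenate(rows_all[s])
        cols = np.concatenate(cols_all[s])
        data = np.concatenate(data_all[s])
        mat = sp.coo_matrix((data, (rows, cols)), shape=(ps.N, ps.N)).tocsr()
        ops.append(DiffOp(s, eval_idx, mat))
    return ops


def _first_singular(Kb: np.ndarray, pts: np.ndarray) -> int:
    for g in range(Kb.shape[0]):
        if np.linalg.matrix_rank(Kb[g]) < Kb.shape[1]:
            return int(pts[g])
    return int(pts[0])


def build_dcpse(
    ps: ParticleSet,
    nbrs: NeighborLists,
    spec: OperatorSpec,
    eval_idx=None,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> DiffOp:
    """Build one DC-PSE operator (see :func:`build_dcpse_family`)."""
    return build_dcpse_family(ps, nbrs, [spec], eval_idx, cond_threshold)[0]


# ---------------------------------------------------------------------------
# finite-difference backend
# ---------------------------------------------------------------------------

def _fd_1d_stencil(i: int, n: int, order: int, h: float):
    """Second-order 1-d stencil (offsets in lattice index, weights) at node i."""
    if order == 0:
        return [0], [1.0]
    if order == 1:
        if 0 < i < n - 1:
            return [-1, 1], [-0.5 / h, 0.5 / h]
        if i == 0:
            return [0, 1, 2], [-1.5 / h, 2.0 / h, -0.5 / h]
        return [-2, -1, 0], [0.5 / h, -2.0 / h, 1.5 / h]
    if order == 2:
        if 0 < i < n - 1:
            return [-1, 0, 1], [1.0 / h**2, -2.0 / h**2, 1.0 / h**2]
        if i == 0:
            return [0, 1, 2, 3], [2.0 / h**2, -5.0 / h**2, 4.0 / h**2, -1.0 / h**2]
        return [-3, -2, -1, 0], [-1.0 / h**2, 4.0 / h**2, -5.0 / h**2, 2.0 / h**2]
    raise ValueError("finite-difference backend supports derivative order <= 2 per axis")


def build_fd(ps: ParticleSet, spec: OperatorSpec) -> DiffOp:
    """Second-order finite-difference stencils on an unjittered lattice.

    Central stencils in the interior, one-sided second-order closures on the
    faces, so the operator is defined at every particle.  Mixed derivatives
    are tensor products of the per-axis 1-d stencils.
    """
    if not ps.is_lattice():
        raise OperatorBuildError("build_fd requires an unjittered lattice ParticleSet")
    shape = ps.lattice_shape
    d = ps.d
    beta = spec.beta.components
    if len(beta) != d:
        raise ValueError("multi-index dimensionality mismatch")
    if any(b > 2 for b in beta):
        raise OperatorBuildError("FD backend supports per-axis derivative order <= 2")
    h = ps.h_nominal
    strides = np.ones(d, dtype=np.intp)
    for k in range(d - 2, -1, -1):
        strides[k] = strides[k + 1] * shape[k + 1]

    grid_idx = np.unravel_index(np.arange(ps.N), shape)
    rows, cols, data = [], [], []
    for p in range(ps.N):
        offs = [[0]]
        wts = [[1.0]]
        for ax in range(d):
            o, w = _fd_1d_stencil(int(grid_idx[ax][p]), shape[ax], beta[ax], h)
            offs.append(o)
            wts.append(w)
        # tensor product over axes
        combo_off = np.zeros(1, dtype=np.intp)
        combo_w = np.ones(1)
        for ax in range(d):
            o, w = offs[ax + 1], wts[ax + 1]
            combo_off = (combo_off[:, None] + np.asarray(o, dtype=np.intp) * strides[ax]).ravel()
            combo_w = (combo_w[:, None] * np.asarray(w)).ravel()
        rows.append(np.full(combo_off.size, p, dtype=np.intp))
        cols.append(p + combo_off)
        data.append(combo_w)
    mat = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ps.N, ps.N),
    ).tocsr()
    return DiffOp(spec, np.arange(ps.N), mat)


# ---------------------------------------------------------------------------
# operator bundle used by the flow solvers
# ---------------------------------------------------------------------------

@dataclass
class OperatorBundle:
    """First/second derivative operators shared by the flow drivers.

    ``dx[i]``  : first derivative along axis i, defined at every particle
    ``dxx[i]`` : pure second derivative along axis i
    ``dmixed`` : {(i, j): d^2/dx_i dx_j} for i < j (only when requested)
    """

    ps: ParticleSet
    dx: list
    dxx: list
    dmixed: dict = field(default_factory=dict)
    backend: str = "dcpse"

    def laplacian_apply(self, values: np.ndarray) -> np.ndarray:
        out = apply_op(self.dxx[0], values)
        for op in self.dxx[1:]:
            out = out + apply_op(op, values)
        return out

    def divergence(self, vec: np.ndarray) -> np.ndarray:
        out = apply_op(self.dx[0], vec[:, 0])
        for i in range(1, len(self.dx)):
            out = out + apply_op(self.dx[i], vec[:, i])
        return out

    def gradient(self, values: np.ndarray) -> np.ndarray:
        return np.stack([apply_op(op, values) for op in self.dx], axis=-1)


def build_operator_bundle(
    ps: ParticleSet,
    backend: str = "dcpse",
    conv_order: int = 2,
    rc_factor: float = DEFAULT_RC_FACTOR,
    mixed: bool = False,
    nbrs: NeighborLists | None = None,
) -> OperatorBundle:
    """Build the standard first/second-derivative operator family."""
    d = ps.d
    e = lambda ax, o: MultiIndex(tuple(o if k == ax else 0 for k in range(d)))
    first = [OperatorSpec(e(ax, 1), conv_order, rc_factor) for ax in range(d)]
    second = [OperatorSpec(e(ax, 2), conv_order, rc_factor) for ax in range(d)]
    mixed_specs = {}
    if mixed:
        for i in range(d):
            for j in range(i + 1, d):
                comp = [0] * d
                comp[i] = 1
                comp[j] = 1
                mixed_specs[(i, j)] = OperatorSpec(MultiIndex(tuple(comp)), conv_order, rc_factor)

    if backend == "fd":
        dx = [build_fd(ps, s) for s in first]
        dxx = [build_fd(ps, s) for s in second]
        dm = {k: build_fd(ps, s) for k, s in mixed_specs.items()}
    elif backend == "dcpse":
        if nbrs is None:
            nbrs = neighbor_search(ps, rc_factor * ps.h_nominal)
        specs = first + second + list(mixed_specs.values())
        ops = build_dcpse_family(ps, nbrs, specs)
        dx = ops[:d]
        dxx = ops[d : 2 * d]
        dm = dict(zip(mixed_specs.keys(), ops[2 * d :]))
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return OperatorBundle(ps=ps, dx=dx, dxx=dxx, dmixed=dm, backend=backend)
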