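"""Deferred-evaluation field expressions and implicit system assembly.

An :class:`Expr` is a finite tree whose leaves are field handles or
constants and whose interior nodes are the binary operators ``+ - * /``,
negation, or a discretized derivative applied to a sub-expression.  The
same tree supports two uses:

* :func:`evaluate` — explicit, recursive elementwise evaluation over all
  particles of the owning set;
* :func:`assemble` — extraction of sparse matrix rows for trees that are
  affine in a declared set of unknown scalar slots, producing the linear
  system ``A x = b`` of an :class:`EquationSet`.

Affinity is checked structurally: an unknown-dependence flag propagates up
the tree, and a product or quotient with both operands dependent raises
:class:`NonlinearExpressionError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dcpse import DiffOp
from .geometry import ParticleSet

__all__ = [
    "Expr",
    "FieldHandle",
    "ConstExpr",
    "ArrayExpr",
    "DerivExpr",
    "Derivative",
    "Equation",
    "EquationSet",
    "get_field",
    "evaluate",
    "assign",
    "assemble",
    "ExpressionError",
    "NonlinearExpressionError",
    "EvaluationError",
]

_COMPONENT_NAMES = {"x": 0, "y": 1, "z": 2}


class ExpressionError(ValueError):
    pass


class NonlinearExpressionError(ExpressionError):
    """A product/quotient of two unknown-dependent subtrees during assembly."""


class EvaluationError(RuntimeError):
    pass


def _normalize_component(component):
    if component is None:
        return None
    if isinstance(component, str):
        return _COMPONENT_NAMES[component]
    if isinstance(component, (tuple, list)):
        return tuple(
            _COMPONENT_NAMES[c] if isinstance(c, str) else int(c) for c in component
        )
    return int(component)


class Expr:
    """Base node; subclasses set ``ps`` (owning ParticleSet or None)."""

    ps: ParticleSet | None = None

    # -- operator overloads -------------------------------------------------
    def __add__(self, other):
        return BinExpr(self, as_expr(other), "+")

    def __radd__(self, other):
        return BinExpr(as_expr(other), self, "+")

    def __sub__(self, other):
        return BinExpr(self, as_expr(other), "-")

    def __rsub__(self, other):
        return BinExpr(as_expr(other), self, "-")

    def __mul__(self, other):
        return BinExpr(self, as_expr(other), "*")

    def __rmul__(self, other):
        return BinExpr(as_expr(other), self, "*")

    def __truediv__(self, other):
        return BinExpr(self, as_expr(other), "/")

    def __rtruediv__(self, other):
        return BinExpr(as_expr(other), self, "/")

    def __neg__(self):
        return NegExpr(self)


def as_expr(x) -> Expr:
    if isinstance(x, Expr):
        return x
    if np.isscalar(x):
        return ConstExpr(float(x))
    raise ExpressionError(f"cannot coerce {type(x).__name__} to an expression")


@dataclass
class ConstExpr(Expr):
    value: float
    ps = None


class ArrayExpr(Expr):
    """Per-particle constant data (not an unknown): e.g. frozen coefficients."""

    def __init__(self, ps: ParticleSet, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape[0] != ps.N:
            raise ExpressionError("array leading dimension must equal N")
        self.ps = ps
        self.values = values


class FieldHandle(Expr):
    """Symbolic alias for a stored property (optionally component-selected).

    A component-selected handle of a vector/tensor property behaves as a
    scalar field.  No data is copied; evaluation reads the live array.
    """

    def __init__(self, ps: ParticleSet, name: str, component=None):
        if name not in ps.properties:
            raise ExpressionError(f"unknown property {name!r}")
        arr = ps.properties[name]
        component = _normalize_component(component)
        rank = {1: "scalar", 2: "vector", 3: "tensor"}[arr.ndim]
        if rank == "scalar" and component is not None:
            raise ExpressionError("scalar property takes no component selector")
        if rank == "vector" and component is not None:
            if not isinstance(component, int) or not 0 <= component < ps.d:
                raise ExpressionError(f"invalid vector component {component!r}")
        if rank == "tensor" and component is not None:
            if not (isinstance(component, tuple) and len(component) == 2):
                raise ExpressionError("tensor component selector must be a pair")
        self.ps = ps
        self.name = name
        self.component = component
        self.rank = rank

    def __getitem__(self, component) -> "FieldHandle":
        if self.component is not None:
            raise ExpressionError("component already selected")
        return FieldHandle(self.ps, self.name, component)

    @property
    def is_scalar_valued(self) -> bool:
        return self.rank == "scalar" or self.component is not None

    def slot_key(self):
        return (self.name, self.component)

    def read(self) -> np.ndarray:
        arr = self.ps.properties[self.name]
        if self.component is None:
            return arr
        if self.rank == "vector":
            return arr[:, self.component]
        return arr[:, self.component[0], self.component[1]]


def get_field(ps: ParticleSet, name: str, component=None) -> FieldHandle:
    """Create a symbolic alias for a stored property."""
    return FieldHandle(ps, name, component)


class BinExpr(Expr):
    def __init__(self, left: Expr, right: Expr, op: str):
        self.left = left
        self.right = right
        self.op = op
        self.ps = _common_ps(left, right)


class NegExpr(Expr):
    def __init__(self, child: Expr):
        self.child = child
        self.ps = child.ps


class DerivExpr(Expr):
    def __init__(self, diffop: DiffOp, child: Expr):
        self.diffop = diffop
        self.child = child
        self.ps = child.ps


class Derivative:
    """Wrap a :class:`DiffOp` as a callable usable inside expressions."""

    def __init__(self, diffop: DiffOp):
        self.diffop = diffop

    def __call__(self, e) -> DerivExpr:
        return DerivExpr(self.diffop, as_expr(e))


def _common_ps(*exprs):
    ps = None
    for e in exprs:
        if e.ps is not None:
            if ps is None:
                ps = e.ps
            elif ps is not e.ps:
                raise ExpressionError("expression mixes different ParticleSets")
    return ps


# ---------------------------------------------------------------------------
# explicit evaluation
# ---------------------------------------------------------------------------

def _eval(e: Expr):
    if isinstance(e, ConstExpr):
        return e.value
    if isinstance(e, ArrayExpr):
        return e.values
    if isinstance(e, FieldHandle):
        return e.read()
    if isinstance(e, NegExpr):
        return -_eval(e.child)
    if isinstance(e, DerivExpr):
        child = _eval(e.child)
        if np.isscalar(child):
            child = np.full(e.diffop.N, child)
        return e.diffop.matrix @ child
    if isinstance(e, BinExpr):
        a, b = _eval(e.left), _eval(e.right)
        if e.op == "+":
            return a + b
        if e.op == "-":
            return a - b
        if e.op == "*":
            return a * b
        bb = np.asarray(b)
        zero = bb == 0
        if np.any(zero):
            if bb.ndim == 0:
                raise EvaluationError("division by zero (scalar divisor)")
            raise EvaluationError(
                f"division by zero at particle {int(np.argmax(zero.reshape(bb.shape[0], -1).any(axis=1)))}"
            )
        return a / b
    raise ExpressionError(f"unknown node {type(e).__name__}")


def evaluate(e: Expr) -> np.ndarray:
    """Recursively evaluate *e* over all particles of its owning set."""
    res = _eval(e)
    if np.isscalar(res):
        if e.ps is None:
            raise ExpressionError("pure-constant expression has no particle set")
        res = np.full(e.ps.N, res)
    return np.asarray(res, dtype=float)


def assign(target: FieldHandle, e, subset=None) -> np.ndarray:
    """Evaluate *e* fully, then write into the target property (copy-before-write).

    The expression may reference the target itself; the pre-assignment values
    are used throughout.  ``subset`` restricts the write to those particles.
    """
    e = as_expr(e)
    res = _eval(e)
    arr = target.ps.properties[target.name]
    if subset is None:
        subset = slice(None)
    if target.component is None:
        view_shape = arr[subset].shape
        arr[subset] = np.broadcast_to(res if np.isscalar(res) else np.asarray(res)[subset], view_shape)
    elif target.rank == "vector":
        res_s = res if np.isscalar(res) else np.asarray(res)[subset]
        arr[subset, target.component] = res_s
    else:
        i, j = target.component
        res_s = res if np.isscalar(res) else np.asarray(res)[subset]
        arr[subset, i, j] = res_s
    return arr


# ---------------------------------------------------------------------------
# implicit assembly
# ---------------------------------------------------------------------------

@dataclass
class Equation:
    """``lhs == rhs`` imposed on a particle subset, determining one unknown slot."""

    lhs: Expr
    rhs: Expr
    subset: np.ndarray
    unknown: tuple

    def __post_init__(self):
        self.lhs = as_expr(self.lhs)
        self.rhs = as_expr(self.rhs)
        self.subset = np.asarray(self.subset, dtype=np.intp)


@dataclass
class EquationSet:
    """Ordered unknown scalar slots plus the equations covering them.

    ``unknowns`` entries are slot keys ``(property_name, component)``.
    Every (slot, particle) pair must be covered by exactly one equation.
    """

    unknowns: list
    equations: list = field(default_factory=list)

    def add(self, lhs, rhs, subset, unknown):
        self.equations.append(Equation(lhs, rhs, subset, unknown))


def _linearize(e: Expr, slots: dict, N: int):
    """Return (M, c): value(e) = M @ x + c, with M None when independent of x."""
    K = len(slots)
    if isinstance(e, ConstExpr):
        return None, e.value
    if isinstance(e, ArrayExpr):
        return None, e.values
    if isinstance(e, FieldHandle):
        key = e.slot_key()
        if key in slots:
            s = slots[key]
            M = sp.csr_matrix(
                (np.ones(N), (np.arange(N), s * N + np.arange(N))), shape=(N, K * N)
            )
            return M, 0.0
        if not e.is_scalar_valued:
            raise ExpressionError(
                f"non-scalar field {e.name!r} used without component selector in assembly"
            )
        return None, e.read().copy()
    if isinstance(e, NegExpr):
        M, c = _linearize(e.child, slots, N)
        return (None if M is None else -M), -c
    if isinstance(e, DerivExpr):
        M, c = _linearize(e.child, slots, N)
        R = e.diffop.matrix
        if np.isscalar(c):
            c = np.full(N, c)
        return (None if M is None else R @ M), R @ c
    if isinstance(e, BinExpr):
        M1, c1 = _linearize(e.left, slots, N)
        M2, c2 = _linearize(e.right, slots, N)
        if e.op == "+":
            M = M1 if M2 is None else (M2 if M1 is None else M1 + M2)
            return M, c1 + c2
        if e.op == "-":
            M = M1 if M2 is None else ((-M2) if M1 is None else M1 - M2)
            return M, c1 - c2
        if e.op == "*":
            if M1 is not None and M2 is not None:
                raise NonlinearExpressionError(
                    "product of two unknown-dependent subexpressions"
                )
            if M2 is not None:  # swap so dependent side is left
                M1, M2, c1, c2 = M2, M1, c2, c1
            if M1 is None:
                return None, c1 * c2
            scale = c2 if np.isscalar(c2) else sp.diags(np.asarray(c2))
            M = M1 * scale if np.isscalar(scale) else scale @ M1
            return M, c1 * c2
        # division
        if M2 is not None:
            raise NonlinearExpressionError("division by an unknown-dependent expression")
        c2a = np.asarray(c2)
        if np.any(c2a == 0):
            raise EvaluationError("division by zero during assembly")
        inv = 1.0 / c2a
        if M1 is None:
            return None, c1 * inv
        M = M1 * float(inv) if c2a.ndim == 0 else sp.diags(inv) @ M1
        return M, c1 * inv
    raise ExpressionError(f"unknown node {type(e).__name__}")


def assemble(system: EquationSet):
    """Assemble the sparse linear system of an :class:`EquationSet`.

    Returns ``(A, b, index_map)`` where ``A`` is ``(N*K) x (N*K)`` CSR,
    row ordering is particle-major within unknown blocks
    (row of slot s, particle i = ``s*N + i``), and ``index_map`` maps each
    slot key to its block index.
    """
    if not system.equations:
        raise ExpressionError("empty equation set")
    ps = None
    for eq in system.equations:
        ps = _common_ps(eq.lhs, eq.rhs) or ps
    if ps is None:
        raise ExpressionError("no particle set referenced by the equation set")
    N = ps.N
    slots = {key: s for s, key in enumerate(system.unknowns)}
    K = len(slots)

    coverage = np.zeros(K * N, dtype=np.intp)
    rows_parts, cols_parts, data_parts = [], [], []
    b = np.zeros(K * N)
    for eq in system.equations:
        if eq.unknown not in slots:
            raise ExpressionError(f"equation targets undeclared unknown {eq.unknown!r}")
        s = slots[eq.unknown]
        M_l, c_l = _linearize(eq.lhs, slots, N)
        M_r, c_r = _linearize(eq.rhs, slots, N)
        if M_r is not None:
            raise ExpressionError("rhs must not contain unknowns")
        if M_l is None:
            raise ExpressionError("lhs does not involve any unknown")
        rows_global = s * N + eq.subset
        coverage[rows_global] += 1
        sub = M_l[eq.subset].tocoo()
        rows_parts.append(rows_global[sub.row])
        cols_parts.append(sub.col)
        data_parts.append(sub.data)
        rhs_vals = (c_r if not np.isscalar(c_r) else np.full(N, c_r))[eq.subset]
        lhs_const = (c_l if not np.isscalar(c_l) else np.full(N, c_l))[eq.subset]
        b[rows_global] = rhs_vals - lhs_const

    if np.any(coverage != 1):
        bad = int(np.flatnonzero(coverage != 1)[0])
        s, i = divmod(bad, N)
        kind = "uncovered" if coverage[bad] == 0 else "doubly covered"
        raise ExpressionError(
            f"row for unknown {system.unknowns[s]!r} at particle {i} is {kind}"
        )

    A = sp.coo_matrix(
        (np.concatenate(data_parts), (np.concatenate(rows_parts), np.concatenate(cols_parts))),
        shape=(K * N, K * N),
    ).tocsr()
    index_map = dict(slots)
    return A, b, index_map
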