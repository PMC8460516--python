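"""Particle sets on boxes and balls, with bulk/boundary classification and
fixed-radius neighbor search.

All downstream numerics (derivative operators, expression assembly, the flow
solvers) see only a :class:`ParticleSet`: an ``(N, d)`` array of coordinates
plus named property arrays.  Lattice structure, when present, is retained as
optional metadata so that the finite-difference operator backend can recover
it, but no other module performs index arithmetic on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "BoxDomain",
    "BallDomain",
    "ParticleSet",
    "NeighborLists",
    "ConfigurationError",
    "grid_particles",
    "jitter_particles",
    "ball_particles",
    "neighbor_search",
]


class ConfigurationError(ValueError):
    """Raised for invalid domain / discretization configuration."""


@dataclass(frozen=True)
class BoxDomain:
    """Axis-aligned box ``[lo[0], hi[0]] x ... x [lo[d-1], hi[d-1]]``."""

    lo: tuple
    hi: tuple

    def __post_init__(self):
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ConfigurationError("lo and hi must be 1-d vectors of equal length")
        if lo.size not in (2, 3):
            raise ConfigurationError("only 2-d and 3-d boxes are supported")
        if not np.all(hi > lo):
            raise ConfigurationError("hi must exceed lo along every axis")
        object.__setattr__(self, "lo", tuple(lo))
        object.__setattr__(self, "hi", tuple(hi))

    @property
    def d(self) -> int:
        return len(self.lo)

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.hi) - np.asarray(self.lo)


@dataclass(frozen=True)
class BallDomain:
    """Closed ball of given center and radius."""

    center: tuple
    radius: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.ndim != 1 or c.size not in (2, 3):
            raise ConfigurationError("center must be a 2- or 3-vector")
        if not self.radius > 0:
            raise ConfigurationError("radius must be positive")
        object.__setattr__(self, "center", tuple(c))

    @property
    def d(self) -> int:
        return len(self.center)


class ParticleSet:
    """Scattered discretization points carrying named field properties.

    Parameters
    ----------
    positions
        ``(N, d)`` coordinates.
    h_nominal
        Nominal inter-particle spacing (the lattice spacing at creation).
    bulk_idx, boundary_idx
        Disjoint index arrays whose union is ``range(N)``.
    lattice_shape
        Per-axis point counts if the set was created as a regular lattice
        (and has not been jittered); ``None`` otherwise.
    normals
        ``(N, d)`` outward unit normals, nonzero only on boundary particles.
    """

    def __init__(
        self,
        positions: np.ndarray,
        h_nominal: float,
        bulk_idx: np.ndarray,
        boundary_idx: np.ndarray,
        lattice_shape: tuple | None = None,
        normals: np.ndarray | None = None,
        domain=None,
    ):
        positions = np.ascontiguousarray(positions, dtype=float)
        if positions.ndim != 2:
            raise ConfigurationError("positions must be (N, d)")
        if not h_nominal > 0:
            raise ConfigurationError("h_nominal must be positive")
        bulk_idx = np.asarray(bulk_idx, dtype=np.intp)
        boundary_idx = np.asarray(boundary_idx, dtype=np.intp)
        n = positions.shape[0]
        marker = np.zeros(n, dtype=int)
        marker[bulk_idx] += 1
        marker[boundary_idx] += 1
        if not np.all(marker == 1):
            raise ConfigurationError(
                "bulk_idx and boundary_idx must partition the particle indices"
            )
        self.positions = positions
        self.h_nominal = float(h_nominal)
        self.bulk_idx = bulk_idx
        self.boundary_idx = boundary_idx
        self.lattice_shape = tuple(lattice_shape) if lattice_shape else None
        self.domain = domain
        if normals is None:
            normals = np.zeros_like(positions)
        self.normals = np.asarray(normals, dtype=float)
        self.properties: dict[str, np.ndarray] = {}

    # -- basic introspection -------------------------------------------------
    @property
    def N(self) -> int:
        return self.positions.shape[0]

    @property
    def d(self) -> int:
        return self.positions.shape[1]

    def is_lattice(self) -> bool:
        return self.lattice_shape is not None

    # -- properties ----------------------------------------------------------
    def add_property(self, name: str, value=None, rank: str = "scalar") -> np.ndarray:
        """Attach a named field array (scalar: (N,), vector: (N,d), tensor: (N,d,d))."""
        if value is None:
            shape = {
                "scalar": (self.N,),
                "vector": (self.N, self.d),
                "tensor": (self.N, self.d, self.d),
            }[rank]
            value = np.zeros(shape)
        value = np.asarray(value, dtype=float)
        if value.shape[0] != self.N:
            raise ConfigurationError(
                f"property {name!r} leading dimension {value.shape[0]} != N={self.N}"
            )
        self.properties[name] = value
        return value

    def copy(self) -> "ParticleSet":
        out = ParticleSet(
            self.positions.copy(),
            self.h_nominal,
            self.bulk_idx.copy(),
            self.boundary_idx.copy(),
            self.lattice_shape,
            self.normals.copy(),
            self.domain,
        )
        for k, v in self.properties.items():
            out.properties[k] = v.copy()
        return out


@dataclass
class NeighborLists:
    """Exact fixed-radius neighbor lists (self excluded, strict ``< rc``)."""

    rc: float
    lists: list = field(repr=False)

    def counts(self) -> np.ndarray:
        return np.array([len(l) for l in self.lists], dtype=np.intp)


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def grid_particles(box: BoxDomain, n_per_dim) -> ParticleSet:
    """Regular lattice covering *box*, including its faces.

    ``n_per_dim`` may be a scalar or one count per axis; spacing must agree
    across axes to within a relative tolerance of 1e-9.
    """
    d = box.d
    n = np.broadcast_to(np.asarray(n_per_dim, dtype=int), (d,)).copy()
    if np.any(n < 3):
        raise ConfigurationError("need at least 3 points per axis")
    lo = np.asarray(box.lo)
    hi = np.asarray(box.hi)
    spacings = (hi - lo) / (n - 1)
    h = spacings[0]
    if np.any(np.abs(spacings - h) > 1e-9 * h):
        raise ConfigurationError(
            f"anisotropic lattice spacing {spacings} not supported"
        )
    axes = [np.linspace(lo[k], hi[k], n[k]) for k in range(d)]
    mesh = np.meshgrid(*axes, indexing="ij")
    positions = np.stack([m.ravel() for m in mesh], axis=-1)

    idx = np.stack([m.ravel() for m in np.meshgrid(*[np.arange(nk) for nk in n], indexing="ij")], axis=-1)
    on_face_lo = idx == 0
    on_face_hi = idx == (n - 1)
    on_face = on_face_lo | on_face_hi
    is_boundary = on_face.any(axis=1)

    # outward normals: sum of face normals, normalized (corners get diagonals)
    normals = np.zeros_like(positions)
    normals -= on_face_lo.astype(float)
    normals += on_face_hi.astype(float)
    lens = np.linalg.norm(normals, axis=1)
    nz = lens > 0
    normals[nz] /= lens[nz, None]

    all_idx = np.arange(positions.shape[0])
    return ParticleSet(
        positions,
        h,
        all_idx[~is_boundary],
        all_idx[is_boundary],
        lattice_shape=tuple(int(k) for k in n),
        normals=normals,
        domain=box,
    )


def jitter_particles(ps: ParticleSet, amplitude: float, seed: int) -> ParticleSet:
    """Displace bulk particles by iid uniform(-a*h, a*h) per coordinate.

    Boundary particles are left bitwise unchanged.  ``amplitude >= 0.5`` is
    rejected because adjacent particles could then coincide.
    """
    if not 0 <= amplitude < 0.5:
        raise ConfigurationError("jitter amplitude must be in [0, 0.5)")
    out = ps.copy()
    if amplitude > 0:
        rng = np.random.default_rng(seed)
        disp = rng.uniform(
            -amplitude * ps.h_nominal,
            amplitude * ps.h_nominal,
            size=(len(ps.bulk_idx), ps.d),
        )
        out.positions[ps.bulk_idx] += disp
        out.lattice_shape = None  # no longer a lattice
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point cloud (spiral layout)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * k
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=-1)


def ball_particles(ball: BallDomain, h: float) -> ParticleSet:
    """Interior lattice + spiral surface cloud for a 3-d ball.

    Bulk: lattice points with ``|x - c| < R - h/2``.  Boundary: Fibonacci
    spiral on the sphere with one point per ``h^2`` of surface area.
    """
    if ball.d != 3:
        raise ConfigurationError("ball_particles supports 3-d balls only")
    R = float(ball.radius)
    if not h < R / 4:
        raise ConfigurationError(f"spacing h={h} too coarse for radius {R}")
    c = np.asarray(ball.center)
    n_half = int(np.floor(R / h))
    ax = np.arange(-n_half, n_half + 1) * h
    mesh = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    r = np.linalg.norm(pts, axis=1)
    bulk_pts = pts[r < R - h / 2] + c

    n_surf = max(int(round(4.0 * np.pi * R * R / (h * h))), 12)
    surf_pts = c + R * _fibonacci_sphere(n_surf)

    positions = np.vstack([bulk_pts, surf_pts])
    nb = bulk_pts.shape[0]
    normals = np.zeros_like(positions)
    normals[nb:] = (surf_pts - c) / R
    return ParticleSet(
        positions,
        h,
        np.arange(nb),
        np.arange(nb, positions.shape[0]),
        lattice_shape=None,
        normals=normals,
        domain=ball,
    )


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------

def neighbor_search(ps: ParticleSet, rc: float) -> NeighborLists:
    """Exact fixed-radius neighbors with strict distance ``< rc`` (self excluded)."""
    if not rc > 0:
        raise ConfigurationError("rc must be positive")
    tree = cKDTree(ps.positions)
    pairs = tree.query_pairs(rc, output_type="ndarray")
    if pairs.size:
        dd = np.linalg.norm(
            ps.positions[pairs[:, 0]] - ps.positions[pairs[:, 1]], axis=1
        )
        pairs = pairs[dd < rc]
    # symmetrize and bucket by particle
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    counts = np.bincount(src, minlength=ps.N)
    splits = np.cumsum(counts)[:-1]
    lists = [np.sort(a) for a in np.split(dst, splits)]
    return NeighborLists(rc=float(rc), lists=lists)
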