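"""n-cube and n-sphere primitives.

The design-space picture rests on elementary hypersurface geometry: an
n-sphere or n-cube is an n-dimensional manifold embedded in (n+1)-dimensional
Euclidean space, with the degenerate n=0 case being the point pair
{c - r, c + r}.  This module supplies the combinatorics (vertices, k-faces,
boundaries of hypercubes) and the maps between spheres, planes and cubes
(stereographic projection and the radial max-norm sphere<->cube bijection)
used by rendering and by the gallery illustrations.

Conventions: shapes are centred at the origin with unit radius/half-width
unless stated otherwise; affine placement is a rendering concern.  The
stereographic pole defaults to the "north" unit vector e_n, projecting onto
the equatorial hyperplane through the centre.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .errors import (
    InvalidDimensionError,
    InvalidPointError,
    OffSurfaceError,
    PoleProjectionError,
)

#: default relative tolerance for "lies on the surface" membership tests
SURFACE_TOL = 1e-9


@dataclass(frozen=True)
class NCube:
    """The n-dimensional hypercube [-r, r]^n (its boundary is an
    (n-1)-dimensional hypersurface; conversely an n-cube surface bounds an
    (n+1)-dimensional solid)."""

    n: int
    center: tuple[float, ...] = ()
    half_width: float = 1.0

    def __post_init__(self):
        if self.n < 0:
            raise InvalidDimensionError(f"cube dimension must be >= 0, got {self.n}")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.center and len(self.center) != self.n:
            raise ValueError("center must have n coordinates")

    @property
    def vertex_count(self) -> int:
        return 2 ** self.n


@dataclass(frozen=True)
class NSphere:
    """The n-sphere of radius r: boundary of the (n+1)-ball, living in
    R^(n+1).  For n = 0 the boundary is the point pair {c - r, c + r}."""

    n: int
    center: tuple[float, ...] = ()
    radius: float = 1.0

    def __post_init__(self):
        if self.n < 0:
            raise InvalidDimensionError(f"sphere dimension must be >= 0, got {self.n}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def ambient_dim(self) -> int:
        return self.n + 1


@dataclass(frozen=True)
class FaceDescriptor:
    """A k-face of an n-cube: n-k coordinates fixed at +-1 (times the
    half-width), k coordinates free.  ``fixed`` and ``free`` partition the
    coordinate indices 0..n-1."""

    fixed: tuple[tuple[int, int], ...]  # (coordinate index, sign)
    free: frozenset[int]

    @property
    def k(self) -> int:
        return len(self.free)

    @property
    def n(self) -> int:
        return len(self.fixed) + len(self.free)

    def vertices(self, half_width: float = 1.0) -> np.ndarray:
        """The 2^k vertices of this face, shape (2^k, n)."""
        n = self.n
        free = sorted(self.free)
        base = np.zeros(n)
        for i, s in self.fixed:
            base[i] = s
        out = []
        for signs in itertools.product((-1, 1), repeat=len(free)):
            v = base.copy()
            for i, s in zip(free, signs):
                v[i] = s
            out.append(v)
        return np.array(out).reshape(-1, n) * half_width


# ---------------------------------------------------------------------------
# combinatorics
# ---------------------------------------------------------------------------


def cube_vertices(n: int, half_width: float = 1.0, center: Optional[Iterable[float]] = None) -> np.ndarray:
    """All 2^n vertices of the n-cube, as an array of shape (2^n, n).

    n = 0 yields a single vertex (the centre itself, the empty sign vector).
    """
    if n < 0:
        raise InvalidDimensionError(f"dimension must be >= 0, got {n}")
    if n == 0:
        verts = np.zeros((1, 0))
    else:
        verts = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
    verts = verts * half_width
    if center is not None:
        verts = verts + np.asarray(list(center), dtype=float)
    return verts


def cube_k_faces(n: int, k: int) -> frozenset[FaceDescriptor]:
    """All k-faces of the n-cube: every choice of k free coordinates with
    +-1 signs on the remaining n-k.  |faces| = C(n, k) * 2^(n-k)."""
    if n < 0 or k < 0:
        raise InvalidDimensionError("dimensions must be >= 0")
    if k > n:
        raise InvalidDimensionError(f"a {n}-cube has no {k}-faces")
    faces = set()
    for free in itertools.combinations(range(n), k):
        fixed_idx = [i for i in range(n) if i not in free]
        for signs in itertools.product((-1, 1), repeat=n - k):
            faces.add(
                FaceDescriptor(fixed=tuple(zip(fixed_idx, signs)), free=frozenset(free))
            )
    return frozenset(faces)


def boundary(cube: NCube) -> frozenset[FaceDescriptor]:
    """The facets ((n-1)-faces) of an n-cube: the n-cube surface bounding the
    solid.  A point (0-cube) has an empty boundary."""
    if cube.n == 0:
        return frozenset()
    return cube_k_faces(cube.n, cube.n - 1)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def _default_pole(ambient_dim: int) -> np.ndarray:
    pole = np.zeros(ambient_dim)
    pole[-1] = 1.0
    return pole


def _householder_to_north(pole: np.ndarray) -> np.ndarray:
    """Orthogonal matrix H with H @ pole = e_{d-1} (H is its own inverse)."""
    d = pole.shape[0]
    north = _default_pole(d)
    v = pole - north
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        return np.eye(d)
    v = v / nv
    return np.eye(d) - 2.0 * np.outer(v, v)


def stereographic(
    point: Iterable[float],
    pole: Optional[Iterable[float]] = None,
    tol: float = SURFACE_TOL,
) -> np.ndarray:
    """Stereographic projection of a unit-sphere point from ``pole`` onto the
    equatorial hyperplane through the centre.

    The map is continuous and injective away from the pole; the pole's
    antipode lands at the origin.  ``point`` must lie on the unit sphere
    within ``tol`` (relative).
    """
    x = np.asarray(list(point), dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidPointError("non-finite coordinates")
    r = np.linalg.norm(x)
    if abs(r - 1.0) > tol * max(1.0, r):
        raise OffSurfaceError(f"|point| = {r} is not 1 within tolerance {tol}")
    p = _default_pole(x.shape[0]) if pole is None else np.asarray(list(pole), dtype=float)
    H = _householder_to_north(p / np.linalg.norm(p))
    y = H @ x  # pole now at north
    denom = 1.0 - y[-1]
    if abs(denom) < tol:
        raise PoleProjectionError("cannot project the pole itself")
    return y[:-1] / denom


def inverse_stereographic(
    point: Iterable[float], pole: Optional[Iterable[float]] = None
) -> np.ndarray:
    """Inverse stereographic map: a point of the equatorial n-plane back onto
    the unit n-sphere (the origin maps to the pole's antipode)."""
    y = np.asarray(list(point), dtype=float)
    if not np.all(np.isfinite(y)):
        raise InvalidPointError("non-finite coordinates")
    s = float(y @ y)
    x = np.empty(y.shape[0] + 1)
    x[:-1] = 2.0 * y / (s + 1.0)
    x[-1] = (s - 1.0) / (s + 1.0)
    if pole is not None:
        p = np.asarray(list(pole), dtype=float)
        H = _householder_to_north(p / np.linalg.norm(p))
        x = H @ x  # H is an involution
    return x


def sphere_to_cube(
    point: Iterable[float], half_width: float = 1.0, tol: float = SURFACE_TOL
) -> np.ndarray:
    """Radial max-norm map from a sphere surface onto the boundary of the
    concentric cube: scale the point so its max-norm equals the half-width.
    Bijective between the two boundaries; face centres (axis-aligned points)
    are fixed points when radius = half-width."""
    x = np.asarray(list(point), dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidPointError("non-finite coordinates")
    m = np.max(np.abs(x))
    if m < tol:
        raise InvalidPointError("the zero vector has no radial image")
    return x * (half_width / m)


def cube_to_sphere(
    point: Iterable[float], radius: float = 1.0, tol: float = SURFACE_TOL
) -> np.ndarray:
    """Inverse of :func:`sphere_to_cube`: radially rescale a cube-boundary
    point onto the concentric sphere of the given radius."""
    x = np.asarray(list(point), dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidPointError("non-finite coordinates")
    r = np.linalg.norm(x)
    if r < tol:
        raise InvalidPointError("the zero vector has no radial image")
    return x * (radius / r)
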