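"""Internal coordinates ξ (distance, bend angle, dihedral) and their exact
Cartesian first derivatives ∂ξ/∂x.

Only first derivatives are provided: the Gauss–Newton preconditioner is built
from outer products ∂ξ/∂x ⊗ ∂ξ/∂x and deliberately avoids second derivatives
of the internal coordinates.  All inter-atom vectors go through the
minimum-image convention so molecules may span periodic boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import GeometryError, Structure, minimum_image_vector

__all__ = ["InternalCoordinate", "distance", "angle", "dihedral", "evaluate"]

_TINY = 1e-10
_DEGENERATE_TOL = 1e-6


@dataclass
class InternalCoordinate:
    """A geometric coordinate, its value and its sparse Cartesian gradient.

    ``gradient`` maps member-atom index → ∂ξ/∂x_atom (3-vector).  Units:
    dimensionless/Å for distances, 1/Å for angles and dihedrals.
    """

    kind: str
    atoms: tuple[int, ...]
    value: float
    gradient: dict[int, np.ndarray] = field(default_factory=dict)
    degenerate: bool = False

    def dense_gradient(self, n_atoms: int) -> np.ndarray:
        g = np.zeros(3 * n_atoms)
        for a, ga in self.gradient.items():
            g[3 * a : 3 * a + 3] = ga
        return g


def distance(structure: Structure, i: int, j: int) -> InternalCoordinate:
    """Minimum-image distance |r_ij| with unit-vector gradient."""
    if i == j:
        raise GeometryError("distance requires two distinct atoms")
    r = minimum_image_vector(structure, i, j)
    d = float(np.linalg.norm(r))
    if d < _TINY:
        raise GeometryError(f"atoms {i} and {j} are coincident (r = {d:.2e} Å)")
    u = r / d
    return InternalCoordinate("distance", (i, j), d, {i: -u, j: u})


def _perpendicular(u: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to u."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(u @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, trial)
    return p / np.linalg.norm(p)


def angle(structure: Structure, i: int, j: int, k: int) -> InternalCoordinate:
    """Bend angle i–j–k (apex j) in [0, π].

    Gradients use the cross-product formulation, which stays finite as the
    angle approaches π.  At an exactly degenerate (collinear) geometry the
    gradient direction is ill-defined; a fixed perpendicular frame is
    substituted and the coordinate flagged, which is sufficient for
    positive-semidefinite curvature assembly.
    """
    if len({i, j, k}) != 3:
        raise GeometryError("angle requires three distinct atoms")
    u = minimum_image_vector(structure, j, i)
    v = minimum_image_vector(structure, j, k)
    lu, lv = np.linalg.norm(u), np.linalg.norm(v)
    if lu < _TINY or lv < _TINY:
        raise GeometryError(f"degenerate angle arm at atoms ({i},{j},{k})")
    n = np.cross(u, v)
    ln = np.linalg.norm(n)
    theta = float(np.arctan2(ln, u @ v))
    degenerate = min(theta, np.pi - theta) < _DEGENERATE_TOL
    if ln < _TINY * lu * lv:
        n = _perpendicular(u / lu) * lu * lv  # fixed fallback normal
        ln = np.linalg.norm(n)
    gi = np.cross(u, n) / (lu**2 * ln)
    gk = -np.cross(v, n) / (lv**2 * ln)
    gj = -gi - gk
    return InternalCoordinate("angle", (i, j, k), theta, {i: gi, j: gj, k: gk}, degenerate)


def dihedral(structure: Structure, i: int, j: int, k: int, l: int) -> InternalCoordinate:
    """Signed dihedral between planes (i,j,k) and (j,k,l), in (−π, π].

    Sign via the standard atan2 construction, φ = atan2((n₁×n₂)·b̂₂, n₁·n₂)
    with n₁ = b₁×b₂, n₂ = b₂×b₃: antisymmetric under mirror reflection of l
    through the (i,j,k) plane, 0 for cis and π for trans.  The branch point
    prefers +π over −π so planar-trans has a single canonical value.  (Only
    the outer product of the gradient enters the preconditioner, so any
    self-consistent sign convention yields the same metric.)
    """
    if len({i, j, k, l}) != 4:
        raise GeometryError("dihedral requires four distinct atoms")
    b1 = minimum_image_vector(structure, i, j)
    b2 = minimum_image_vector(structure, j, k)
    b3 = minimum_image_vector(structure, k, l)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2)
    l1, l2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if lb2 < _TINY:
        raise GeometryError(f"collinear axis atoms ({j},{k}) in dihedral")
    if l1 < _TINY or l2 < _TINY:
        raise GeometryError(f"zero-area plane in dihedral ({i},{j},{k},{l})")
    phi = float(np.arctan2(np.cross(n1, n2) @ (b2 / lb2), n1 @ n2))
    if phi <= -np.pi + 1e-12:
        phi = np.pi
    gi = -(lb2 / l1**2) * n1
    gl = (lb2 / l2**2) * n2
    t1 = (b1 @ b2) / lb2**2
    t2 = (b3 @ b2) / lb2**2
    gj = -(1.0 + t1) * gi + t2 * gl
    gk = t1 * gi - (1.0 + t2) * gl
    return InternalCoordinate("dihedral", (i, j, k, l), phi, {i: gi, j: gj, k: gk, l: gl})


_DISPATCH = {"distance": distance, "angle": angle, "dihedral": dihedral}


def evaluate(structure: Structure, kind: str, atoms: tuple[int, ...]) -> InternalCoordinate:
    """Evaluate an internal coordinate by kind name."""
    try:
        fn = _DISPATCH[kind]
    except KeyError:
        raise GeometryError(f"unknown internal-coordinate kind {kind!r}") from None
    return fn(structure, *atoms)
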