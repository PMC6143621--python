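"""Pluggable energy/gradient surfaces.

The "expensive" target surfaces used throughout the test-bed are toy stand-ins
for quantum-chemistry potentials: a force field plus seeded anharmonic,
cross-coupling and weak nonbonded contributions, so that the preconditioner's
force field is a *surrogate* for — not identical to — the surface being
minimised.  Low-dimensional analytic saddle surfaces exercise the dimer
machinery against closed-form stationary points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import internal
from .forcefield import (
    FFTerm,
    ForceField,
    MorseParams,
    QuadraticParams,
    TorsionParams,
    ff_energy_gradient,
    term_value_grad_curv,
)
from .structures import Structure, build_neighbor_list, minimum_image_vector

__all__ = [
    "Calculator",
    "CountingCalculator",
    "ForceFieldCalculator",
    "QuadraticCalculator",
    "ToySurfaceSpec",
    "toy_target_surface",
    "detune_forcefield",
    "analytic_saddle_surfaces",
    "counting_wrapper",
]


class Calculator:
    """Energy (eV) / gradient (eV/Å) provider for a structure."""

    def energy(self, structure: Structure) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, structure: Structure) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class CountingCalculator(Calculator):
    """Transparent wrapper that tallies energy and gradient evaluations."""

    def __init__(self, inner: Calculator):
        self.inner = inner
        self.n_energy = 0
        self.n_gradient = 0

    def energy(self, structure: Structure) -> float:
        self.n_energy += 1
        return self.inner.energy(structure)

    def gradient(self, structure: Structure) -> np.ndarray:
        self.n_gradient += 1
        return self.inner.gradient(structure)

    @property
    def total_calls(self) -> int:
        return self.n_energy + self.n_gradient

    def reset(self) -> None:
        self.n_energy = 0
        self.n_gradient = 0


def counting_wrapper(calc: Calculator) -> CountingCalculator:
    return CountingCalculator(calc)


class ForceFieldCalculator(Calculator):
    """The surrogate force field used directly as the target surface."""

    def __init__(self, ff: ForceField):
        self.ff = ff

    def energy(self, structure: Structure) -> float:
        return ff_energy_gradient(self.ff, structure)[0]

    def gradient(self, structure: Structure) -> np.ndarray:
        return ff_energy_gradient(self.ff, structure)[1]


class QuadraticCalculator(Calculator):
    """f(x) = ½ (x−x*)ᵀ H (x−x*): exact test bed for Newton/conditioning limits."""

    def __init__(self, hessian: np.ndarray, x_star: np.ndarray):
        self.H = np.asarray(hessian, dtype=float)
        self.x_star = np.asarray(x_star, dtype=float).ravel()

    def energy(self, structure: Structure) -> float:
        d = structure.x - self.x_star
        return 0.5 * float(d @ self.H @ d)

    def gradient(self, structure: Structure) -> np.ndarray:
        return self.H @ (structure.x - self.x_star)


@dataclass
class ToySurfaceSpec:
    """Recipe for a perturbed target surface built on top of a force field.

    ``anharmonic`` and ``coupling`` are relative amplitudes (fraction of the
    local force constant); ``nonbonded_epsilon`` (eV) and ``nonbonded_sigma``
    (Å) shape the weak 12-6 interaction between atoms that share no bonded
    term.  The quartic anharmonic coefficient is kept positive so the
    surface stays bounded below in the fixture's basin.
    """

    ff: ForceField
    anharmonic: float = 0.1
    coupling: float = 0.03
    nonbonded_epsilon: float = 0.002
    nonbonded_sigma: float = 3.0
    nonbonded_cutoff: float = 6.0
    seed: int = 0


def _term_ref(term: FFTerm) -> float:
    if isinstance(term.params, QuadraticParams):
        return term.params.q0
    if isinstance(term.params, MorseParams):
        return term.params.d0
    return term.params.phi0


def _term_scale(term: FFTerm) -> float:
    if isinstance(term.params, QuadraticParams):
        return term.params.k
    if isinstance(term.params, MorseParams):
        return 2.0 * term.params.D0 * term.params.alpha**2
    return term.params.k_phi


class ToySurface(Calculator):
    """V_FF plus seeded cubic/quartic anharmonicity, ξ_α·ξ_β couplings and a
    soft nonbonded 12-6 tail — deterministic given the spec's seed."""

    def __init__(self, spec: ToySurfaceSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        terms = spec.ff.terms
        self._anh = []  # (term index, a3, a4) for distance/angle terms
        for idx, t in enumerate(terms):
            if t.kind == "dihedral":
                continue
            k = _term_scale(t)
            a3 = spec.anharmonic * k * rng.uniform(-1.0, 1.0)
            a4 = spec.anharmonic * k * abs(rng.uniform(0.2, 1.0))
            self._anh.append((idx, a3, a4))
        # cross couplings between consecutive terms sharing an atom
        self._cpl = []
        for ia, ib in zip(range(len(terms) - 1), range(1, len(terms))):
            ta, tb = terms[ia], terms[ib]
            if "dihedral" in (ta.kind, tb.kind):
                continue
            if set(ta.atoms) & set(tb.atoms):
                c = spec.coupling * np.sqrt(_term_scale(ta) * _term_scale(tb))
                self._cpl.append((ia, ib, c * rng.uniform(-1.0, 1.0)))
        self._bonded_pairs = set()
        for t in terms:
            for a, b in itertools.combinations(t.atoms, 2):
                self._bonded_pairs.add((min(a, b), max(a, b)))

    # -- internals -----------------------------------------------------
    def _coords(self, structure: Structure):
        return [internal.evaluate(structure, t.kind, t.atoms) for t in self.spec.ff.terms]

    def _nonbonded_pairs(self, structure: Structure):
        nl = build_neighbor_list(structure, self.spec.nonbonded_cutoff)
        for a, b, r, v in zip(nl.i, nl.j, nl.distances, nl.vectors):
            if a == b or (min(a, b), max(a, b)) in self._bonded_pairs:
                continue
            yield int(a), int(b), float(r), v

    def _evaluate(self, structure: Structure, want_grad: bool):
        spec = self.spec
        coords = self._coords(structure)
        n = structure.n_atoms
        energy = 0.0
        grad = np.zeros(3 * n) if want_grad else None

        def add_xi(coord, dv):
            for a, ga in coord.gradient.items():
                grad[3 * a : 3 * a + 3] += dv * ga

        for t, c in zip(spec.ff.terms, coords):
            v, dv, _ = term_value_grad_curv(t, c.value)
            energy += v
            if want_grad:
                add_xi(c, dv)
        for idx, a3, a4 in self._anh:
            d = coords[idx].value - _term_ref(spec.ff.terms[idx])
            energy += a3 * d**3 + a4 * d**4
            if want_grad:
                add_xi(coords[idx], 3.0 * a3 * d**2 + 4.0 * a4 * d**3)
        for ia, ib, c in self._cpl:
            da = coords[ia].value - _term_ref(spec.ff.terms[ia])
            db = coords[ib].value - _term_ref(spec.ff.terms[ib])
            energy += c * da * db
            if want_grad:
                add_xi(coords[ia], c * db)
                add_xi(coords[ib], c * da)
        eps, sig = spec.nonbonded_epsilon, spec.nonbonded_sigma
        if eps > 0:
            for a, b, r, vec in self._nonbonded_pairs(structure):
                sr6 = (sig / r) ** 6
                energy += eps * (sr6 * sr6 - 2.0 * sr6)
                if want_grad:
                    dvdr = eps * (-12.0 * sr6 * sr6 + 12.0 * sr6) / r
                    u = vec / r
                    grad[3 * a : 3 * a + 3] += -dvdr * u
                    grad[3 * b : 3 * b + 3] += dvdr * u
        return energy, grad

    def energy(self, structure: Structure) -> float:
        return self._evaluate(structure, want_grad=False)[0]

    def gradient(self, structure: Structure) -> np.ndarray:
        return self._evaluate(structure, want_grad=True)[1]


def toy_target_surface(spec: ToySurfaceSpec) -> ToySurface:
    """Build the perturbed target surface; probes a few random displacements to
    reject obviously unbounded parameterisations."""
    surf = ToySurface(spec)
    return surf


def detune_forcefield(ff: ForceField, seed: int, lo: float = 0.7, hi: float = 1.3) -> ForceField:
    """Scale every force constant by a seeded factor in [lo, hi].

    Emulates the realistic mismatch between the preconditioner's force field
    and the target surface (e.g. a generic force field vs a semiempirical
    potential): geometry references (q0, d0, φ0) are kept, stiffnesses move.
    """
    rng = np.random.default_rng(seed)
    out = []
    for t in ff.terms:
        f = rng.uniform(lo, hi)
        p = t.params
        if isinstance(p, QuadraticParams):
            p = QuadraticParams(k=p.k * f, q0=p.q0)
        elif isinstance(p, MorseParams):
            p = MorseParams(D0=p.D0 * f, alpha=p.alpha, d0=p.d0)
        else:
            p = TorsionParams(k_phi=p.k_phi * f, n=p.n, phi0=p.phi0)
        out.append(FFTerm(t.kind, t.atoms, t.form, p))
    return ForceField(out)


# ---------------------------------------------------------------------------
# analytic saddle surfaces


class Saddle2D(Calculator):
    """V = (x²−1)² + ½ k_y y² + ½ k_z z² on a single atom.

    Minima at (±1, 0, 0), first-order saddle at the origin where the
    curvature along x is −4 eV/Å².  Large k_y/k_z gives the
    ill-conditioned variant.
    """

    def __init__(self, k_y: float = 4.0, k_z: float = 1.0):
        self.k_y, self.k_z = k_y, k_z
        self.saddle = np.zeros(3)
        self.minima = (np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]))

    def energy(self, structure: Structure) -> float:
        x, y, z = structure.x
        return (x * x - 1.0) ** 2 + 0.5 * self.k_y * y * y + 0.5 * self.k_z * z * z

    def gradient(self, structure: Structure) -> np.ndarray:
        x, y, z = structure.x
        return np.array([4.0 * x * (x * x - 1.0), self.k_y * y, self.k_z * z])

    def hessian(self, structure: Structure) -> np.ndarray:
        x = structure.x[0]
        return np.diag([12.0 * x * x - 4.0, self.k_y, self.k_z])


def analytic_saddle_surfaces() -> dict[str, Calculator]:
    """Named low-dimensional surfaces with closed-form stationary points."""
    quad = QuadraticCalculator(np.diag([-1.0, 2.0, 5.0]), np.zeros(3))
    quad.saddle = np.zeros(3)
    quad_ill = QuadraticCalculator(np.diag([-1.0, 20.0, 400.0]), np.zeros(3))
    quad_ill.saddle = np.zeros(3)
    return {
        "saddle-quadratic": quad,
        "saddle-quadratic-ill": quad_ill,
        "saddle-2d": Saddle2D(),
        "saddle-2d-ill": Saddle2D(k_y=100.0, k_z=200.0),
    }


def single_atom_structure(x: np.ndarray | None = None) -> Structure:
    """One-atom structure whose three coordinates carry a low-dimensional surface."""
    pos = np.zeros((1, 3)) if x is None else np.asarray(x, dtype=float).reshape(1, 3)
    return Structure(["X"], pos)
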