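"""Surrogate molecular-mechanics potential V_FF = Σ_α V_α(ξ_α).

Term forms are the standard short-range bonded shapes: quadratic
(½k(q−q0)², bonds/bends/torsions), Morse (D0(1−e^{−α(d−d0)})², bonds) and
cosine torsion (½k_φ(1+cos(nφ−φ0))).  Each form exposes value, first and
second derivative with respect to its internal coordinate; Cartesian
energies/gradients follow by the chain rule through
:mod:`precondopt.internal`.  Parameter files are JSON keyed by explicit
atom-index tuples — no atom typing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import internal
from .structures import ParseError, Structure

__all__ = [
    "QuadraticParams",
    "MorseParams",
    "TorsionParams",
    "FFTerm",
    "ForceField",
    "term_value_grad_curv",
    "ff_energy_gradient",
    "read_ff",
    "write_ff",
]


@dataclass(frozen=True)
class QuadraticParams:
    k: float  # eV/Å² (distances) or eV/rad² (angles, dihedrals)
    q0: float  # Å or rad

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("quadratic force constant k must be > 0")


@dataclass(frozen=True)
class MorseParams:
    D0: float  # well depth, eV
    alpha: float  # range parameter, 1/Å
    d0: float  # equilibrium distance, Å

    def __post_init__(self):
        if self.D0 <= 0 or self.alpha <= 0 or self.d0 <= 0:
            raise ValueError("Morse parameters D0, alpha, d0 must all be > 0")


@dataclass(frozen=True)
class TorsionParams:
    k_phi: float  # barrier scale, eV
    n: int  # multiplicity
    phi0: float  # phase, rad

    def __post_init__(self):
        if int(self.n) < 1:
            raise ValueError("torsion multiplicity n must be ≥ 1")


_FORM_KINDS = {
    "quadratic": ("distance", "angle", "dihedral"),
    "morse": ("distance",),
    "torsion": ("dihedral",),
}
_ARITY = {"distance": 2, "angle": 3, "dihedral": 4}


@dataclass(frozen=True)
class FFTerm:
    """One potential term V_α acting on one internal coordinate ξ_α."""

    kind: str  # internal-coordinate kind
    atoms: tuple[int, ...]
    form: str  # quadratic | morse | torsion
    params: QuadraticParams | MorseParams | TorsionParams

    def __post_init__(self):
        if self.form not in _FORM_KINDS:
            raise ValueError(f"unknown term form {self.form!r}")
        if self.kind not in _FORM_KINDS[self.form]:
            raise ValueError(f"form {self.form!r} incompatible with coordinate {self.kind!r}")
        if len(self.atoms) != _ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} coordinate needs {_ARITY[self.kind]} atoms, got {len(self.atoms)}"
            )
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"repeated atom index in term {self.atoms}")


@dataclass
class ForceField:
    terms: list[FFTerm]

    def __len__(self) -> int:
        return len(self.terms)


def term_value_grad_curv(term: FFTerm, xi: float) -> tuple[float, float, float]:
    """(V_α, ∂V_α/∂ξ, ∂²V_α/∂ξ²) at coordinate value ξ.

    The torsion curvature −½ k_φ n² cos(nφ−φ0) is genuinely negative over
    half its period; positivation (|·|) is the preconditioner's job, not
    the potential's.
    """
    p = term.params
    if term.form == "quadratic":
        dq = xi - p.q0
        return 0.5 * p.k * dq * dq, p.k * dq, p.k
    if term.form == "morse":
        e = np.exp(-p.alpha * (xi - p.d0))
        v = p.D0 * (1.0 - e) ** 2
        dv = 2.0 * p.D0 * p.alpha * e * (1.0 - e)
        ddv = 2.0 * p.D0 * p.alpha**2 * (2.0 * e * e - e)
        return float(v), float(dv), float(ddv)
    # torsion
    arg = p.n * xi - p.phi0
    v = 0.5 * p.k_phi * (1.0 + np.cos(arg))
    dv = -0.5 * p.k_phi * p.n * np.sin(arg)
    ddv = -0.5 * p.k_phi * p.n**2 * np.cos(arg)
    return float(v), float(dv), float(ddv)


def _distance_terms_fast(terms, indices, structure, grad):
    """Vectorised energy/gradient for quadratic and Morse distance terms."""
    from .structures import minimum_image_vectors

    ai = np.array([terms[t].atoms[0] for t in indices])
    aj = np.array([terms[t].atoms[1] for t in indices])
    vec = minimum_image_vectors(structure, ai, aj)
    r = np.linalg.norm(vec, axis=1)
    if np.any(r < 1e-10):
        bad = indices[int(np.argmin(r))]
        raise ValueError(f"term {bad}: coincident atoms {terms[bad].atoms}")
    u = vec / r[:, None]
    energy = 0.0
    dv = np.empty(len(indices))
    for m, t in enumerate(indices):
        p = terms[t].params
        if isinstance(p, QuadraticParams):
            dq = r[m] - p.q0
            energy += 0.5 * p.k * dq * dq
            dv[m] = p.k * dq
        else:  # Morse
            e = np.exp(-p.alpha * (r[m] - p.d0))
            energy += p.D0 * (1.0 - e) ** 2
            dv[m] = 2.0 * p.D0 * p.alpha * e * (1.0 - e)
    f = dv[:, None] * u
    np.add.at(grad.reshape(-1, 3), aj, f)
    np.add.at(grad.reshape(-1, 3), ai, -f)
    return energy


def ff_energy_gradient(ff: ForceField, structure: Structure) -> tuple[float, np.ndarray]:
    """Total energy (eV) and Cartesian gradient (3N, eV/Å) of the force field.

    Distance terms take a vectorised fast path; angle and dihedral terms go
    through :mod:`precondopt.internal` term by term.
    """
    n = structure.n_atoms
    energy = 0.0
    grad = np.zeros(3 * n)
    dist_idx = [k for k, t in enumerate(ff.terms) if t.kind == "distance"]
    if dist_idx:
        for k in dist_idx:
            if max(ff.terms[k].atoms) >= n:
                raise IndexError(
                    f"term {k} references atom {max(ff.terms[k].atoms)} but N={n}"
                )
        energy += _distance_terms_fast(ff.terms, np.array(dist_idx), structure, grad)
    for idx, term in enumerate(ff.terms):
        if term.kind == "distance":
            continue
        if max(term.atoms) >= n:
            raise IndexError(f"term {idx} references atom {max(term.atoms)} but N={n}")
        try:
            coord = internal.evaluate(structure, term.kind, term.atoms)
        except Exception as exc:
            raise type(exc)(f"term {idx} ({term.kind} {term.atoms}): {exc}") from exc
        v, dv, _ = term_value_grad_curv(term, coord.value)
        energy += v
        for a, ga in coord.gradient.items():
            grad[3 * a : 3 * a + 3] += dv * ga
    return energy, grad


# ---------------------------------------------------------------------------
# parameter-file I/O (JSON schema, YAML-compatible)

_PARAM_FIELDS = {
    "quadratic": ("k", "q0"),
    "morse": ("D0", "alpha", "d0"),
    "torsion": ("k_phi", "n", "phi0"),
}
_PARAM_TYPES = {"quadratic": QuadraticParams, "morse": MorseParams, "torsion": TorsionParams}


def _term_to_record(term: FFTerm) -> dict:
    rec = {"kind": term.kind, "atoms": list(term.atoms), "form": term.form}
    rec["params"] = {f: getattr(term.params, f) for f in _PARAM_FIELDS[term.form]}
    return rec


def _term_from_record(rec: dict, idx: int) -> FFTerm:
    for key in ("kind", "atoms", "form", "params"):
        if key not in rec:
            raise ParseError(f"term record {idx}: missing field {key!r}")
    form = rec["form"]
    if form not in _PARAM_TYPES:
        raise ParseError(f"term record {idx}: unknown form {form!r}")
    fields = _PARAM_FIELDS[form]
    missing = [f for f in fields if f not in rec["params"]]
    if missing:
        raise ParseError(f"term record {idx}: missing parameter(s) {missing} for {form!r}")
    kwargs = {f: rec["params"][f] for f in fields}
    if form == "torsion":
        kwargs["n"] = int(kwargs["n"])
    try:
        term = FFTerm(rec["kind"], tuple(int(a) for a in rec["atoms"]), form,
                      _PARAM_TYPES[form](**kwargs))
    except ValueError as exc:
        raise ParseError(f"term record {idx}: {exc}") from exc
    return term


def write_ff(ff: ForceField, path) -> None:
    with open(path, "w") as fh:
        json.dump({"terms": [_term_to_record(t) for t in ff.terms]}, fh, indent=1)
        fh.write("\n")


def read_ff(path) -> ForceField:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict) or "terms" not in data:
        raise ParseError(f"{path}: expected a top-level object with a 'terms' list")
    return ForceField([_term_from_record(r, i) for i, r in enumerate(data["terms"])])
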