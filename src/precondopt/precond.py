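"""Positive-definite preconditioners for geometry optimisation.

Four families are provided, all sparse symmetric 3N×3N operators in eV/Å²:

* **Exp** — a graph-Laplacian-like connectivity metric with exponentially
  decaying off-diagonal weights, lifted isotropically to Cartesian blocks.
  With decay A = 0 and scale μ = 1 it reduces exactly to the graph Laplacian
  of the cutoff connectivity graph.
* **FF** — the Gauss–Newton part of the force-field Hessian:
  P_FF = Σ_α (∂ξ_α/∂x ⊗ ∂ξ_α/∂x)·|∂²V_α/∂ξ_α²|.  Dropping the second
  derivative of the internal coordinates keeps it positive semidefinite and
  avoids second derivatives of ξ entirely.
* **Exp+FF** — for molecular crystals: Exp off-diagonal blocks are retained
  only where the FF block is entirely zero (the nonbonded part), with their
  own Laplacian diagonal compensation, then added to P_FF.
* **EAM** — pair-distance-only Gauss–Newton metric from an embedded-atom
  surrogate, with per-pair curvature from the pair, density and embedding
  splines.

An isolated molecule's P_FF has at least six zero eigenvalues (rigid
translations and rotations); regularisation P → P + cI makes every variant
positive definite.  Generic values c = 0.1 eV/Å² (minimisation) and
1.0 eV/Å² (saddle search) are the defaults downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .forcefield import ForceField, term_value_grad_curv
from . import internal
from .structures import Structure, build_neighbor_list

__all__ = [
    "ExpParams",
    "EAMParams",
    "Preconditioner",
    "NumericalError",
    "assemble_exp",
    "estimate_exp_params",
    "assemble_pff",
    "combine_exp_ff",
    "assemble_peam",
    "regularize",
    "apply_inverse",
    "baseline_exact_hessian",
    "identity_preconditioner",
]


class NumericalError(RuntimeError):
    """Raised when a linear-algebra contract cannot be met."""


@dataclass
class ExpParams:
    """Parameters of the exponential connectivity metric.

    μ sets the overall energy-curvature scale (eV/Å²), A the decay rate of
    the off-diagonal weight with distance relative to the nearest-neighbour
    distance r_nn, and r_cut the connectivity cutoff.
    """

    mu: float = 1.0
    A: float = 3.0
    r_nn: float = 1.0
    r_cut: float = 2.0

    def __post_init__(self):
        if self.mu <= 0 or self.r_cut <= 0 or self.r_nn <= 0:
            raise ValueError("mu, r_cut and r_nn must be positive")


@dataclass
class EAMParams:
    """Splined embedded-atom surrogate: pair Φ(r), density ρ(r), embedding F(n).

    Each spline must be callable with a ``.derivative()`` method (e.g.
    ``scipy.interpolate.CubicSpline``); Φ and ρ vanish beyond ``cutoff``.
    """

    pair: object
    density: object
    embedding: object
    cutoff: float

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class Preconditioner:
    """A symmetric sparse metric with cached factorisation.

    ``c`` records the accumulated +cI regularisation; ``apply_inverse``
    demands positive definiteness (i.e. a regularised operator for the
    semidefinite families).
    """

    matrix: sp.csr_matrix
    c: float = 0.0
    _factor: object = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def _factorize(self):
        if self._factor is None:
            try:
                self._factor = spla.splu(sp.csc_matrix(self.matrix))
            except RuntimeError as exc:
                raise NumericalError(
                    f"factorisation failed ({exc}); regularise with P + cI first"
                ) from exc
        return self._factor

    def apply_inverse(self, g: np.ndarray) -> np.ndarray:
        return apply_inverse(self, g)

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


def identity_preconditioner(n3: int, scale: float = 1.0) -> Preconditioner:
    """The trivial metric scale·I (unpreconditioned optimisation)."""
    return Preconditioner(sp.identity(n3, format="csr") * scale, c=scale)


def _symmetrize(m: sp.spmatrix) -> sp.csr_matrix:
    m = sp.csr_matrix(m)
    return ((m + m.T) * 0.5).tocsr()


# ---------------------------------------------------------------------------
# Exp preconditioner


def _exp_laplacian(structure: Structure, params: ExpParams,
                   skip_pairs: set[tuple[int, int]] | None = None) -> sp.csr_matrix:
    """The N×N Laplacian-like matrix L with off-diagonal
    −μ·exp(−A(r_ij/r_nn − 1)) on every neighbour-list edge, diagonal set so
    each row sums to zero.  Self-image edges cancel at Γ and are skipped;
    ``skip_pairs`` removes whole atom-pair couplings (used by the Exp+FF
    merge)."""
    n = structure.n_atoms
    nl = build_neighbor_list(structure, params.r_cut)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for a, b, r in zip(nl.i, nl.j, nl.distances):
        if a == b:
            continue
        if skip_pairs is not None and (min(a, b), max(a, b)) in skip_pairs:
            continue
        w = params.mu * np.exp(-params.A * (r / params.r_nn - 1.0))
        rows += [a, b]
        cols += [b, a]
        vals += [-w, -w]
        diag[a] += w
        diag[b] += w
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def assemble_exp(structure: Structure, params: ExpParams,
                 _skip_pairs: set[tuple[int, int]] | None = None) -> Preconditioner:
    """Assemble the Exp preconditioner (Laplacian lift, isotropic 3×3 blocks).

    An empty neighbour list yields the zero matrix (with a warning):
    regularisation will turn it into cI, i.e. plain gradient descent.
    """
    L = _exp_laplacian(structure, params, _skip_pairs)
    if L.nnz == 0 or abs(L).sum() == 0.0:
        import warnings

        warnings.warn(
            f"no neighbours within r_cut={params.r_cut} Å; Exp preconditioner is zero",
            stacklevel=2,
        )
    P = sp.kron(L, sp.identity(3, format="csr"), format="csr")
    return Preconditioner(_symmetrize(P))


def estimate_exp_params(
    structure: Structure,
    calculator=None,
    A: float = 3.0,
    r_cut: float | None = None,
    mu: float | None = None,
) -> ExpParams:
    """Estimate Exp parameters from the initial structure.

    r_nn is the minimum interatomic distance; defaults r_cut = 2·r_nn and
    A = 3.0 (the molecular-crystal setting).  If a calculator is supplied, μ
    is estimated from a single extra gradient evaluation: for a smooth test
    displacement v (0.01 Å sine profile across the largest extent),
    μ ← ⟨v, ∇E(x+v) − ∇E(x)⟩ / ⟨v, P_{μ=1} v⟩, clamped to [1e−2, 1e4];
    otherwise μ = 1.
    """
    pos = structure.positions
    n = structure.n_atoms
    if n < 2:
        r_nn = 1.0
    else:
        grow = 2.0
        while True:
            nl = build_neighbor_list(structure, grow)
            dists = nl.distances[nl.distances > 1e-12]
            if len(dists):
                r_nn = float(dists.min())
                break
            grow *= 2.0
            if grow > 1e4:
                r_nn = 1.0
                break
    params = ExpParams(mu=1.0, A=A, r_nn=r_nn, r_cut=2.0 * r_nn if r_cut is None else r_cut)
    if mu is not None:
        params.mu = mu
        return params
    if calculator is None:
        return params
    extent = pos.max(axis=0) - pos.min(axis=0)
    axis = int(np.argmax(extent))
    span = max(extent[axis], 1e-6)
    phase = (pos[:, axis] - pos[:, axis].min()) / span
    v = np.zeros((n, 3))
    v[:, axis] = 0.01 * np.sin(np.pi * phase + 0.1)
    v = v.ravel()
    g0 = calculator.gradient(structure)
    g1 = calculator.gradient(structure.with_x(structure.x + v))
    p1 = assemble_exp(structure, params)
    denom = float(v @ (p1.matrix @ v))
    if denom > 1e-14:
        est = float(v @ (g1 - g0)) / denom
        params.mu = float(np.clip(est, 1e-2, 1e4))
    return params


# ---------------------------------------------------------------------------
# FF Gauss–Newton preconditioner


def assemble_pff(structure: Structure, ff: ForceField) -> Preconditioner:
    """P_FF = Σ_α (∂ξ_α/∂x ⊗ ∂ξ_α/∂x)·|∂²V_α/∂ξ_α²|.

    Positive semidefinite by construction; second derivatives of the
    internal coordinates never enter.  Near-degenerate coordinate gradients
    contribute their (finite) outer product as-is — definiteness is the job
    of the +cI regularisation.
    """
    n3 = 3 * structure.n_atoms
    rows, cols, vals = [], [], []
    for idx, term in enumerate(ff.terms):
        try:
            coord = internal.evaluate(structure, term.kind, term.atoms)
        except Exception as exc:
            raise type(exc)(f"term {idx} ({term.kind} {term.atoms}): {exc}") from exc
        curv = abs(term_value_grad_curv(term, coord.value)[2])
        if curv == 0.0:
            continue
        members = list(coord.gradient.items())
        for a, ga in members:
            for b, gb in members:
                block = curv * np.outer(ga, gb)
                for p in range(3):
                    for q in range(3):
                        rows.append(3 * a + p)
                        cols.append(3 * b + q)
                        vals.append(block[p, q])
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n3, n3))
    return Preconditioner(_symmetrize(P))


def _ff_covered_pairs(pff: Preconditioner, n_atoms: int) -> set[tuple[int, int]]:
    """Atom pairs whose 3×3 block in P_FF holds any nonzero entry."""
    coo = pff.matrix.tocoo()
    pairs = set()
    for r, c, v in zip(coo.row, coo.col, coo.data):
        if v == 0.0:
            continue
        a, b = r // 3, c // 3
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    return pairs


def combine_exp_ff(pff: Preconditioner, structure: Structure, params: ExpParams) -> Preconditioner:
    """P_Exp+FF: FF blocks where the force field acts, Exp connectivity elsewhere.

    The retained Exp off-diagonals carry their own Laplacian diagonal
    compensation (so the Exp part alone stays PSD), and the P_FF diagonal is
    untouched.  Merge granularity is the atom-pair 3×3 block.
    """
    covered = _ff_covered_pairs(pff, structure.n_atoms)
    exp_part = assemble_exp(structure, params, _skip_pairs=covered)
    return Preconditioner(_symmetrize(pff.matrix + exp_part.matrix))


# ---------------------------------------------------------------------------
# EAM preconditioner


def assemble_peam(structure: Structure, params: EAMParams) -> Preconditioner:
    """Pair-distance Gauss–Newton metric from an embedded-atom surrogate.

    Per pair (i,j) the 1-D curvature is
    Φ''(r) + [F'(n_i)+F'(n_j)]·ρ''(r) + [F''(n_i)+F''(n_j)]·ρ'(r)²
    with n_i the host density at atom i, taken in absolute value and
    outer-producted with the pair-distance gradient.  Cross-pair embedding
    couplings between different pairs sharing an atom are excluded (per-pair
    diagonal curvature reading).
    """
    phi, rho, F = params.pair, params.density, params.embedding
    dphi2 = phi.derivative(2)
    drho1, drho2 = rho.derivative(1), rho.derivative(2)
    dF1, dF2 = F.derivative(1), F.derivative(2)
    n = structure.n_atoms
    nl = build_neighbor_list(structure, params.cutoff)
    lo, hi = rho.x[0], rho.x[-1]
    for r in nl.distances:
        if r < lo or (r > hi and r < params.cutoff):
            raise ValueError(f"pair distance {r:.4f} Å outside spline domain [{lo}, {hi}]")
    dens = np.zeros(n)
    for a, b, r in zip(nl.i, nl.j, nl.distances):
        if a == b:
            dens[a] += 2.0 * float(rho(r))
        else:
            dens[a] += float(rho(r))
            dens[b] += float(rho(r))
    n3 = 3 * n
    rows, cols, vals = [], [], []
    for a, b, r, vec in zip(nl.i, nl.j, nl.distances, nl.vectors):
        if a == b:
            continue  # Γ-point: self-image pair curvature cancels
        curv = float(dphi2(r))
        curv += (float(dF1(dens[a])) + float(dF1(dens[b]))) * float(drho2(r))
        curv += (float(dF2(dens[a])) + float(dF2(dens[b]))) * float(drho1(r)) ** 2
        curv = abs(curv)
        if curv == 0.0:
            continue
        u = vec / r
        block = curv * np.outer(u, u)
        for (ai, sa), (bi, sb) in [((a, 1), (a, 1)), ((b, 1), (b, 1)),
                                   ((a, 1), (b, -1)), ((b, -1), (a, 1))]:
            sign = sa * sb
            for p in range(3):
                for q in range(3):
                    rows.append(3 * ai + p)
                    cols.append(3 * bi + q)
                    vals.append(sign * block[p, q])
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n3, n3))
    return Preconditioner(_symmetrize(P))


# ---------------------------------------------------------------------------
# regularisation / solve / baselines


def regularize(p: Preconditioner, c: float) -> Preconditioner:
    """P → P + cI.  Invalidates any cached factorisation."""
    if c <= 0:
        raise ValueError("regularisation constant c must be > 0")
    n = p.matrix.shape[0]
    return Preconditioner(_symmetrize(p.matrix + c * sp.identity(n)), c=p.c + c)


def apply_inverse(p: Preconditioner, g: np.ndarray) -> np.ndarray:
    """Solve P z = g with the cached sparse factorisation.

    The residual contract ‖Pz − g‖∞ ≤ 1e−8·‖g‖∞ is verified; a violation
    (singular or indefinite input) raises :class:`NumericalError` with the
    advice to regularise.
    """
    g = np.asarray(g, dtype=float)
    factor = p._factorize()
    z = factor.solve(g)
    gn = np.abs(g).max() if g.size else 0.0
    if gn > 0:
        res = np.abs(p.matrix @ z - g).max()
        if not np.isfinite(res) or res > 1e-8 * gn:
            raise NumericalError(
                f"inverse-apply residual {res:.3e} exceeds contract; "
                "matrix is likely singular — regularise with P + cI"
            )
    return z


def baseline_exact_hessian(
    source, structure: Structure | None = None, shift: float = 0.1, mode: str = "abs",
    h: float = 1e-4,
) -> Preconditioner:
    """Baseline preconditioners built from the exact (finite-difference) Hessian.

    ``source`` may be a dense symmetric matrix, a :class:`ForceField`, or a
    calculator (the latter two require ``structure``; the Hessian is then
    obtained by central differences of the gradient, step ``h`` Å — only
    affordable for small systems).

    mode "abs": every eigenvalue replaced by max(|λ|, shift) — full spectral
    positivation.  mode "shift": eigenvalues below a small threshold
    (including negatives) moved to ``shift``; the rest untouched.
    """
    if not isinstance(source, np.ndarray):
        from .calculators import ForceFieldCalculator
        from .diagnostics import finite_difference_hessian

        calc = ForceFieldCalculator(source) if isinstance(source, ForceField) else source
        if structure is None:
            raise ValueError("structure required when source is a force field/calculator")
        source = finite_difference_hessian(calc, structure, h=h)
    H = np.asarray(source, dtype=float)
    H = 0.5 * (H + H.T)
    lam, U = np.linalg.eigh(H)
    if mode == "abs":
        lam_new = np.maximum(np.abs(lam), shift)
    elif mode == "shift":
        tol = 1e-6 * max(np.abs(lam).max(), 1.0)
        lam_new = np.where(lam < tol, shift, lam)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    M = (U * lam_new) @ U.T
    return Preconditioner(_symmetrize(sp.csr_matrix(0.5 * (M + M.T))), c=shift)


def make_precond_builder(
    name: str,
    ff: ForceField | None = None,
    exp_params: ExpParams | None = None,
    eam_params: EAMParams | None = None,
    calculator=None,
    c: float = 0.1,
    shift: float = 0.1,
):
    """Factory for ``structure -> Preconditioner`` builders by family name.

    Names: ``id``, ``exp``, ``ff``, ``exp+ff``, ``eam``, ``hessian-shift``,
    ``hessian-abs``.  Every non-identity builder returns the +cI regularised
    operator, ready for ``apply_inverse``.  ``id`` returns ``None`` so
    optimisers take their unpreconditioned path.
    """
    if name == "id":
        return None
    if name == "exp":
        def build(structure: Structure) -> Preconditioner:
            params = exp_params or estimate_exp_params(structure, calculator)
            return regularize(assemble_exp(structure, params), c)
        return build
    if name == "ff":
        if ff is None:
            raise ValueError("preconditioner 'ff' requires a force field")
        return lambda s: regularize(assemble_pff(s, ff), c)
    if name == "exp+ff":
        if ff is None:
            raise ValueError("preconditioner 'exp+ff' requires a force field")

        def build(structure: Structure) -> Preconditioner:
            params = exp_params or estimate_exp_params(structure, calculator)
            return regularize(combine_exp_ff(assemble_pff(structure, ff), structure, params), c)
        return build
    if name == "eam":
        if eam_params is None:
            raise ValueError("preconditioner 'eam' requires EAM splines")
        return lambda s: regularize(assemble_peam(s, eam_params), c)
    if name in ("hessian-shift", "hessian-abs"):
        source = ff if ff is not None else calculator
        if source is None:
            raise ValueError(f"preconditioner {name!r} requires a force field or calculator")
        mode = "shift" if name.endswith("shift") else "abs"
        return lambda s: baseline_exact_hessian(source, s, shift=shift, mode=mode)
    raise ValueError(f"unknown preconditioner {name!r}")
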