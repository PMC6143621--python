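"""Preconditioned LBFGS minimisation and preconditioned dimer saddle search.

The LBFGS two-loop recursion is standard except for a single modification:
the initial-Hessian scaling in the middle is replaced by one application of
the preconditioner inverse, z = P⁻¹q.  Step lengths come from a backtracking
line search enforcing only the Armijo condition.

The dimer method alternates (1) unpreconditioned rotation of the dimer
orientation v towards the lowest Hessian eigenmode and (2) a translation
along a Polak–Ribière conjugate-gradient direction built from the reflected
force q = −(I − 2v⊗v)∇f, with the CG scalar β evaluated in the P⁻¹ metric.
Translation step lengths use a secant curvature estimate along the search
direction, capped by an adaptive trust radius whose acceptance test is the
projection of the post-step reflected force on the step direction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .calculators import Calculator, CountingCalculator
from .precond import Preconditioner, identity_preconditioner
from .structures import Structure

__all__ = [
    "LBFGSState",
    "LineSearchConfig",
    "DimerState",
    "RunReport",
    "LineSearchError",
    "plbfgs_direction",
    "armijo_backtrack",
    "minimize",
    "dimer_rotate",
    "dimer_translate_direction",
    "dimer_search",
]


class LineSearchError(RuntimeError):
    pass


@dataclass
class LBFGSState:
    """Curvature-pair history for the two-loop recursion.

    Pairs with yᵀs ≤ 1e−10 are rejected on push to keep ρ = 1/yᵀs finite.
    """

    memory: int = 10
    s: deque = field(default_factory=deque)
    y: deque = field(default_factory=deque)
    rho: deque = field(default_factory=deque)
    iteration: int = 0

    def push(self, s_k: np.ndarray, y_k: np.ndarray) -> bool:
        ys = float(y_k @ s_k)
        if ys <= 1e-10:
            return False
        if self.memory == 0:
            return False
        self.s.append(s_k.copy())
        self.y.append(y_k.copy())
        self.rho.append(1.0 / ys)
        while len(self.s) > self.memory:
            self.s.popleft()
            self.y.popleft()
            self.rho.popleft()
        return True

    def clear(self) -> None:
        self.s.clear()
        self.y.clear()
        self.rho.clear()


@dataclass
class LineSearchConfig:
    initial_step: float = 1.0
    backtrack_factor: float = 0.5
    armijo_c1: float = 1e-4
    max_trials: int = 20

    def __post_init__(self):
        if not 0.0 < self.backtrack_factor < 1.0:
            raise ValueError("backtracking factor must be in (0, 1)")
        if not 0.0 < self.armijo_c1 <= 0.5:
            raise ValueError("Armijo parameter must be in (0, 0.5]")


@dataclass
class RunReport:
    """Outcome of an optimisation run; call counters include line-search and
    rotation evaluations (the total function/gradient-call accounting used in
    benchmark comparisons)."""

    converged: bool = False
    iterations: int = 0
    n_energy: int = 0
    n_gradient: int = 0
    fmax_final: float = np.inf
    energy_final: float = np.nan
    n_translations: int = 0  # dimer only
    message: str = ""
    trajectory: list = field(default_factory=list)

    @property
    def total_calls(self) -> int:
        return self.n_energy + self.n_gradient

    def as_dict(self) -> dict:
        return {
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "n_energy": int(self.n_energy),
            "n_gradient": int(self.n_gradient),
            "total_calls": int(self.total_calls),
            "fmax_final": float(self.fmax_final),
            "energy_final": float(self.energy_final),
            "n_translations": int(self.n_translations),
            "message": self.message,
        }


def plbfgs_direction(g: np.ndarray, state: LBFGSState, precond: Preconditioner) -> np.ndarray:
    """Two-loop recursion with z = P⁻¹q in place of the initial scaling.

    Returns the descent direction p = −z (so the step is x + αp).  With an
    empty history this is −P⁻¹g; with P = I it is plain LBFGS.
    """
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient passed to plbfgs_direction")
    q = g.copy()
    alphas = []
    for s_i, y_i, rho_i in zip(reversed(state.s), reversed(state.y), reversed(state.rho)):
        a_i = rho_i * float(s_i @ q)
        q -= a_i * y_i
        alphas.append(a_i)
    z = precond.apply_inverse(q)
    for (s_i, y_i, rho_i), a_i in zip(
        zip(state.s, state.y, state.rho), reversed(alphas)
    ):
        b_i = rho_i * float(y_i @ z)
        z += (a_i - b_i) * s_i
    return -z


def armijo_backtrack(
    calculator: Calculator,
    structure: Structure,
    x: np.ndarray,
    p: np.ndarray,
    f0: float,
    g0: np.ndarray,
    config: LineSearchConfig | None = None,
):
    """Backtracking line search enforcing only the Armijo sufficient decrease.

    Returns ``(alpha, x_new, f_new, n_evals)`` for the largest tried step
    satisfying f(x+αp) ≤ f(x) + c₁·α·gᵀp.  Raises :class:`LineSearchError`
    after ``max_trials`` rejections (callers typically reset the LBFGS
    history and restart from steepest descent).
    """
    config = config or LineSearchConfig()
    slope = float(g0 @ p)
    if slope >= 0.0:
        raise ValueError(f"direction is not a descent direction (gᵀp = {slope:.3e} ≥ 0)")
    alpha = config.initial_step
    for trial in range(config.max_trials):
        x_new = x + alpha * p
        f_new = calculator.energy(structure.with_x(x_new))
        if f_new <= f0 + config.armijo_c1 * alpha * slope:
            return alpha, x_new, f_new, trial + 1
        alpha *= config.backtrack_factor
    raise LineSearchError(
        f"Armijo backtracking failed after {config.max_trials} trials "
        f"(slope {slope:.3e}, f0 {f0:.6e})"
    )


def _as_counting(calculator: Calculator) -> CountingCalculator:
    return calculator if isinstance(calculator, CountingCalculator) else CountingCalculator(calculator)


def minimize(
    calculator: Calculator,
    structure: Structure,
    precond_builder=None,
    fmax: float = 1e-3,
    maxsteps: int = 2000,
    memory: int = 10,
    line_search: LineSearchConfig | None = None,
    keep_trajectory: bool = False,
) -> tuple[RunReport, Structure]:
    """Preconditioned LBFGS until ‖∇E‖∞ < fmax (eV/Å) or ``maxsteps``.

    ``precond_builder`` maps a structure to a positive-definite
    :class:`Preconditioner`; it is re-invoked after every accepted step so the
    metric follows the geometry.  ``None`` means identity (unpreconditioned).
    """
    if fmax <= 0:
        raise ValueError("fmax must be positive")
    calc = _as_counting(calculator)
    n3 = 3 * structure.n_atoms
    if precond_builder is None:
        precond_builder = lambda s: identity_preconditioner(n3)  # noqa: E731
    ls = line_search or LineSearchConfig()
    report = RunReport()
    x = structure.x
    cur = structure.with_x(x)
    g = calc.gradient(cur)
    f = calc.energy(cur)
    state = LBFGSState(memory=memory)
    if keep_trajectory:
        report.trajectory.append(cur)
    while True:
        gnorm = np.abs(g).max()
        if gnorm < fmax:
            report.converged = True
            break
        if report.iterations >= maxsteps:
            report.message = f"maxsteps={maxsteps} reached"
            break
        P = precond_builder(cur)
        p = plbfgs_direction(g, state, P)
        if float(g @ p) >= 0.0:
            state.clear()
            p = -P.apply_inverse(g)
        try:
            alpha, x_new, f_new, _ = armijo_backtrack(calc, cur, x, p, f, g, ls)
        except LineSearchError:
            state.clear()
            p = -P.apply_inverse(g)
            try:
                alpha, x_new, f_new, _ = armijo_backtrack(calc, cur, x, p, f, g, ls)
            except LineSearchError as exc:
                report.message = f"line search failed at step {report.iterations}: {exc}"
                break
        new = cur.with_x(x_new)
        g_new = calc.gradient(new)
        state.push(x_new - x, g_new - g)
        x, g, f, cur = x_new, g_new, f_new, new
        state.iteration += 1
        report.iterations += 1
        if keep_trajectory:
            report.trajectory.append(cur)
    report.fmax_final = float(np.abs(g).max())
    report.energy_final = float(f)
    report.n_energy = calc.n_energy
    report.n_gradient = calc.n_gradient
    return report, cur


# ---------------------------------------------------------------------------
# dimer saddle search


@dataclass
class DimerState:
    """Midpoint, orientation and CG memory of the dimer."""

    x: np.ndarray
    v: np.ndarray  # unit orientation
    separation: float = 0.01  # Å, endpoint offset used for curvature estimates
    s_prev: np.ndarray | None = None  # previous CG direction
    q_prev: np.ndarray | None = None  # previous reflected force
    Pq_prev: np.ndarray | None = None
    trust_radius: float = 0.1  # Å

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        nv = np.linalg.norm(self.v)
        if nv < 1e-12:
            raise ValueError("dimer orientation must be a nonzero vector")
        self.v = self.v / nv
        if self.separation <= 0:
            raise ValueError("dimer separation must be positive")


def _curvature_along(calc, structure, x, g0, v, dx):
    """Directional curvature vᵀ∇²f v via a forward gradient difference."""
    g1 = calc.gradient(structure.with_x(x + dx * v))
    return float((g1 - g0) @ v) / dx, g1


def dimer_rotate(
    calculator: Calculator,
    structure: Structure,
    state: DimerState,
    g0: np.ndarray | None = None,
    f_rot_tol: float = 0.1,
    max_iter: int = 3,
) -> np.ndarray:
    """Rotate the dimer orientation towards the lowest Hessian eigenmode.

    Single-endpoint forward-difference rotation: with endpoint gradient
    g₁ = ∇f(x + l·v) the curvature is C(v) = (g₁−g₀)·v/l and the rotation
    force is −2/l · (g₁−g₀)⊥.  Each iteration does one trial rotation and a
    Fourier-style angle solve (C(θ) = c + a·cos2θ + b·sin2θ).  Rotation is
    deliberately unpreconditioned.
    """
    calc = calculator
    x, l = state.x, state.separation
    if g0 is None:
        g0 = calc.gradient(structure.with_x(x))
    v = state.v.copy()
    for _ in range(max_iter):
        g1 = calc.gradient(structure.with_x(x + l * v))
        dg = g1 - g0
        c0 = float(dg @ v) / l
        f_rot = -2.0 / l * (dg - (dg @ v) * v)
        if np.linalg.norm(f_rot) < f_rot_tol:
            break
        w = f_rot / np.linalg.norm(f_rot)
        b = -np.linalg.norm(f_rot) / 2.0  # dC/dθ at 0 = 2b
        theta_t = 0.25 * np.pi
        v_t = v * np.cos(theta_t) + w * np.sin(theta_t)
        g1_t = calc.gradient(structure.with_x(x + l * v_t))
        c_t = float((g1_t - g0) @ v_t) / l
        cos2, sin2 = np.cos(2 * theta_t), np.sin(2 * theta_t)
        a = (c0 - c_t + b * sin2) / (1.0 - cos2)
        theta = 0.5 * np.arctan2(-b, -a)
        if abs(theta) < 1e-10:
            break
        v_new = v * np.cos(theta) + w * np.sin(theta)
        # pick the branch that actually lowers the curvature
        if a * np.cos(2 * theta) + b * np.sin(2 * theta) > 0:
            theta += 0.5 * np.pi
            v_new = v * np.cos(theta) + w * np.sin(theta)
        v = v_new / np.linalg.norm(v_new)
    state.v = v
    return v


def dimer_translate_direction(
    q_k: np.ndarray,
    state: DimerState,
    precond: Preconditioner,
):
    """Polak–Ribière CG step direction for the dimer translation.

    β = q_kᵀP⁻¹(q_k − q_{k−1}) / q_{k−1}ᵀP⁻¹q_{k−1} (the preconditioned
    Polak–Ribière scalar); s_k = q_k + β·s_{k−1}; the returned trial
    direction is the P-metric normalisation P⁻¹s_k / (s_kᵀP⁻¹s_k).  A
    non-positive denominator restarts CG (β = 0).  With P = I the scheme
    reduces to the plain Polak–Ribière formula.
    """
    Pq = precond.apply_inverse(q_k)
    beta = 0.0
    if state.s_prev is not None and state.q_prev is not None:
        denom = float(state.q_prev @ state.Pq_prev)
        if denom > 0.0:
            beta = float(q_k @ (Pq - state.Pq_prev)) / denom
        # else: restart with beta = 0
    s_k = q_k + beta * state.s_prev if (beta != 0.0 and state.s_prev is not None) else q_k.copy()
    Ps = precond.apply_inverse(s_k)
    denom = float(s_k @ Ps)
    if denom <= 0.0:
        s_k = q_k.copy()
        Ps = Pq.copy()
        denom = float(s_k @ Ps)
    direction = Ps / denom
    state.s_prev = s_k
    state.q_prev = q_k.copy()
    state.Pq_prev = Pq
    return s_k, direction


def _rigid_body_basis(structure: Structure) -> np.ndarray:
    """Orthonormal rigid-body modes: 3 translations, plus rotations about the
    centroid for non-periodic structures (2 for collinear geometries)."""
    n = structure.n_atoms
    pos = structure.positions - structure.positions.mean(axis=0)
    vecs = []
    for a in range(3):
        t = np.zeros((n, 3))
        t[:, a] = 1.0
        vecs.append(t.ravel())
    if not structure.pbc.any() and n > 1:
        for a in range(3):
            axis = np.zeros(3)
            axis[a] = 1.0
            r = np.cross(pos, axis)
            if np.linalg.norm(r) > 1e-8:
                vecs.append(r.ravel())
    B = np.array(vecs).T
    Q, R = np.linalg.qr(B)
    keep = np.abs(np.diag(R)) > 1e-8
    return Q[:, keep]


def dimer_search(
    calculator: Calculator,
    structure: Structure,
    v0: np.ndarray | None = None,
    precond_builder=None,
    fmax: float = 1e-3,
    max_translations: int = 500,
    separation: float = 0.01,
    trust_radius: float = 0.1,
    trust_bounds: tuple[float, float] = (1e-4, 0.5),
    rot_tol: float = 0.1,
    rot_iter: int = 3,
    seed: int = 0,
    keep_trajectory: bool = False,
) -> tuple[RunReport, Structure]:
    """Alternating rotation/translation dimer search for a first-order saddle.

    Translation: CG direction in the reflected force field with the boxed
    P⁻¹ metric; step length from a secant curvature estimate along the
    direction, capped by the trust radius; acceptance by the sign of the
    post-step reflected-force projection on the step (grow ×1.5 on accept,
    shrink ×0.5 and reject on overshoot).  Converged when ‖∇f‖∞ < fmax.
    If ``v0`` is omitted a seeded unit Gaussian with rigid-body components
    projected out is used.
    """
    calc = _as_counting(calculator)
    n3 = 3 * structure.n_atoms
    if precond_builder is None:
        precond_builder = lambda s: identity_preconditioner(n3)  # noqa: E731
    if v0 is None:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n3)
        B = _rigid_body_basis(structure)
        if B.size:
            v0 = v0 - B @ (B.T @ v0)
        if np.linalg.norm(v0) < 1e-12:
            v0 = rng.standard_normal(n3)
    state = DimerState(
        x=structure.x, v=v0, separation=separation, trust_radius=trust_radius
    )
    report = RunReport()
    cur = structure.with_x(state.x)
    g0 = calc.gradient(cur)
    if keep_trajectory:
        report.trajectory.append(cur)
    f_final = np.nan
    while True:
        gnorm = np.abs(g0).max()
        if gnorm < fmax:
            report.converged = True
            break
        if report.n_translations >= max_translations:
            report.message = f"max_translations={max_translations} reached"
            break
        # tighten the rotation as the saddle is approached (superlinear phase)
        eff_rot_tol = min(rot_tol, max(0.1 * gnorm, 1e-10))
        dimer_rotate(calc, cur, state, g0=g0, f_rot_tol=eff_rot_tol, max_iter=rot_iter)
        P = precond_builder(cur)
        q_k = -(g0 - 2.0 * (state.v @ g0) * state.v)
        _, direction = dimer_translate_direction(q_k, state, P)
        u = direction / np.linalg.norm(direction)
        # secant curvature of the reflected force field along u
        dx = state.separation
        g_probe = calc.gradient(cur.with_x(state.x + dx * u))
        q_probe = -(g_probe - 2.0 * (state.v @ g_probe) * state.v)
        c_u = -float((q_probe - q_k) @ u) / dx  # effective curvature (PD near saddle)
        step = state.trust_radius if c_u <= 1e-12 else min(
            float(q_k @ u) / c_u, state.trust_radius
        )
        if step <= 0:
            step = state.trust_radius
        x_new = state.x + step * u
        g_new = calc.gradient(cur.with_x(x_new))
        q_new = -(g_new - 2.0 * (state.v @ g_new) * state.v)
        report.n_translations += 1
        report.iterations += 1
        if float(q_new @ u) >= -0.5 * abs(float(q_k @ u)):
            # at most mildly overshot: accept and grow the radius
            state.x = x_new
            g0 = g_new
            cur = cur.with_x(x_new)
            state.trust_radius = min(state.trust_radius * 1.5, trust_bounds[1])
            if keep_trajectory:
                report.trajectory.append(cur)
        else:
            state.trust_radius *= 0.5
            state.s_prev = None  # CG restart after rejection
            if state.trust_radius < trust_bounds[0]:
                report.message = "trust radius collapsed below minimum"
                break
    try:
        f_final = calc.inner.energy(cur)  # bookkeeping only, not counted
    except Exception:
        pass
    report.fmax_final = float(np.abs(g0).max())
    report.energy_final = float(f_final)
    report.n_energy = calc.n_energy
    report.n_gradient = calc.n_gradient
    return report, cur
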