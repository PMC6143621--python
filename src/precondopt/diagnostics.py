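"""Conditioning analysis and the step-count benchmark harness.

The generalized condition number κ_P = λ_P^max/λ_P^min is computed from the
eigenvalues of H u = λ P u after projecting the rigid-body (or lattice
translation) null modes out of the Hessian.  κ_I (P = I) over κ_P measures
how much better conditioned the preconditioned landscape is; empirically the
optimisation speed-up tracks this ratio more closely than system size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la

from .calculators import Calculator, CountingCalculator
from .precond import Preconditioner
from .structures import Structure

__all__ = [
    "ConditionReport",
    "BenchmarkScenario",
    "condition_ratio",
    "finite_difference_hessian",
    "rigid_body_modes",
    "run_benchmark",
]


@dataclass
class ConditionReport:
    lambda_max: float
    lambda_min: float
    kappa_P: float
    kappa_I: float
    ratio: float  # κ_I / κ_P
    n_removed_modes: int
    warning: str = ""

    def as_dict(self) -> dict:
        return {
            "lambda_max": self.lambda_max,
            "lambda_min": self.lambda_min,
            "kappa_P": self.kappa_P,
            "kappa_I": self.kappa_I,
            "kappa_ratio": self.ratio,
            "n_removed_modes": self.n_removed_modes,
            "warning": self.warning,
        }


def rigid_body_modes(structure: Structure) -> np.ndarray:
    """Orthonormal basis of the analytic zero-curvature space.

    Non-periodic: 3 translations + rotations about the centroid (3, or 2 for
    collinear geometries).  Periodic: the 3 lattice translations only.
    """
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
    return Q[:, np.abs(np.diag(R)) > 1e-8]


def finite_difference_hessian(
    calculator: Calculator, structure: Structure, h: float = 1e-4
) -> np.ndarray:
    """Dense symmetrised central-difference Hessian of the calculator's energy.

    Cost: 2·3N gradient calls; intended for small systems (3N ≤ ~1000).
    """
    x0 = structure.x
    n3 = x0.size
    H = np.empty((n3, n3))
    for i in range(n3):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        gp = calculator.gradient(structure.with_x(xp))
        gm = calculator.gradient(structure.with_x(xm))
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def condition_ratio(
    H: np.ndarray, precond: Preconditioner, structure: Structure | None = None,
    zero_tol: float = 1e-6,
) -> ConditionReport:
    """Generalized condition numbers of H in the P metric and the identity metric.

    When a structure is given, its analytic rigid-body space is projected out
    of both H and the metric before solving the generalized eigenproblem
    (deterministic, exact); ``structure=None`` treats H as symmetry-free and
    skips the projection.  A warning is recorded if H's spectrum does not
    actually contain as many near-zero modes as symmetry demands.
    """
    H = 0.5 * (np.asarray(H, float) + np.asarray(H, float).T)
    n3 = H.shape[0]
    warning = ""
    if structure is None:
        n_null = 0
        Q = np.eye(n3)
    else:
        B = rigid_body_modes(structure)
        n_null = B.shape[1]
        proj = np.eye(n3) - B @ B.T
        Q, R = np.linalg.qr(proj)
        keep = np.abs(np.diag(R)) > 1e-8
        Q = Q[:, keep][:, : n3 - n_null]
        lam_raw = np.linalg.eigvalsh(H)
        n_small = int(np.sum(np.abs(lam_raw) < zero_tol * max(np.abs(lam_raw).max(), 1e-30)))
        if n_small < n_null:
            warning = (
                f"expected ≥{n_null} symmetry zero modes, detected {n_small}; "
                f"spectrum head: {np.sort(np.abs(lam_raw))[:n_null + 2]}"
            )
    Ht = Q.T @ H @ Q
    Pd = precond.dense()
    Pt = Q.T @ Pd @ Q
    lam_P = la.eigvalsh(Ht, 0.5 * (Pt + Pt.T))
    lam_I = np.linalg.eigvalsh(Ht)
    kappa_P = float(lam_P.max() / lam_P.min()) if lam_P.min() != 0 else np.inf
    kappa_I = float(lam_I.max() / lam_I.min()) if lam_I.min() != 0 else np.inf
    return ConditionReport(
        lambda_max=float(lam_P.max()),
        lambda_min=float(lam_P.min()),
        kappa_P=kappa_P,
        kappa_I=kappa_I,
        ratio=kappa_I / kappa_P if np.isfinite(kappa_P) else np.nan,
        n_removed_modes=n_null,
        warning=warning,
    )


@dataclass
class BenchmarkScenario:
    """One benchmark: a seeded starting-structure factory, a target-surface
    factory and ≥2 preconditioner arms (one of them the identity)."""

    name: str
    structure_factory: object  # seed -> Structure
    calculator_factory: object  # seed -> Calculator
    arms: dict = field(default_factory=dict)  # name -> builder|None (None = identity)
    fmax: float = 1e-3
    seeds: tuple = (0, 1, 2)
    maxsteps: int = 2000
    task: str = "minimize"  # or "dimer"

    def __post_init__(self):
        if len(self.arms) < 2 or not any(b is None for b in self.arms.values()):
            raise ValueError("scenario needs ≥2 arms including the identity (builder=None)")


def run_benchmark(scenario: BenchmarkScenario) -> dict:
    """Run every arm from identical seeded starts; report per-seed and median
    function/gradient call counts plus gain ratios relative to the identity arm.

    Non-converged runs are recorded as censored (count kept, flag set), not
    dropped.
    """
    from .optim import dimer_search, minimize

    per_arm: dict[str, list[dict]] = {name: [] for name in scenario.arms}
    for seed in scenario.seeds:
        structure = scenario.structure_factory(seed)
        for name, builder in scenario.arms.items():
            calc = CountingCalculator(scenario.calculator_factory(seed))
            if scenario.task == "minimize":
                report, _ = minimize(
                    calc, structure, precond_builder=builder,
                    fmax=scenario.fmax, maxsteps=scenario.maxsteps,
                )
            else:
                report, _ = dimer_search(
                    calc, structure, precond_builder=builder,
                    fmax=scenario.fmax, max_translations=scenario.maxsteps, seed=seed,
                )
            per_arm[name].append(
                {
                    "seed": seed,
                    "converged": report.converged,
                    "censored": not report.converged,
                    "n_energy": report.n_energy,
                    "n_gradient": report.n_gradient,
                    "total_calls": report.total_calls,
                    "n_translations": report.n_translations,
                }
            )
    id_name = next(n for n, b in scenario.arms.items() if b is None)
    medians = {
        name: float(np.median([r["total_calls"] for r in runs]))
        for name, runs in per_arm.items()
    }
    median_grad = {
        name: float(np.median([r["n_gradient"] for r in runs]))
        for name, runs in per_arm.items()
    }
    gains = {
        name: (medians[id_name] / medians[name]) if medians[name] > 0 else np.inf
        for name in per_arm
    }
    return {
        "scenario": scenario.name,
        "task": scenario.task,
        "fmax": scenario.fmax,
        "seeds": list(scenario.seeds),
        "identity_arm": id_name,
        "runs": per_arm,
        "median_total_calls": medians,
        "median_gradient_calls": median_grad,
        "gain_over_identity": gains,
    }


def write_benchmark_report(result: dict, json_path=None, tsv_path=None) -> None:
    """Persist a benchmark result as JSON and/or a TSV summary table."""
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(result, fh, indent=1)
            fh.write("\n")
    if tsv_path:
        with open(tsv_path, "w") as fh:
            fh.write("arm\tmedian_total_calls\tmedian_gradient_calls\tgain_over_identity\n")
            for arm in result["runs"]:
                fh.write(
                    f"{arm}\t{result['median_total_calls'][arm]:g}\t"
                    f"{result['median_gradient_calls'][arm]:g}\t"
                    f"{result['gain_over_identity'][arm]:.3f}\n"
                )
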