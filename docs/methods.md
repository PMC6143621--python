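# Methods

## The optimisation problem

Geometry optimisation minimises a potential energy surface f(x) over atomic
Cartesian coordinates x ∈ R^(3N); saddle-point search locates first-order
saddles (transition states).  First-order methods slow down when f is
ill-conditioned, and molecular systems are ill-conditioned for two distinct
reasons: system size (long-wavelength elastic modes soften as the cell
grows) and stiffness heterogeneity (bond stretches are orders of magnitude
stiffer than torsions or inter-molecular contacts).

A preconditioner P ≈ ∇²f is a positive-definite metric used to transform the
descent direction, x_{k+1} = x_k − α_k P_k⁻¹ g_k.  With P = I this is
steepest descent; with P = ∇²f it is Newton.  The point of this package is a
family of P that are cheap to assemble, sparse, and positive definite by
construction.

## The preconditioner family

**Exp (connectivity) metric.**  From the N×N matrix with off-diagonal
entries −μ·exp(−A(r_ij/r_nn − 1)) on all pairs inside a cutoff r_cut and a
diagonal fixed by zero row sums, lifted to 3N×3N with isotropic 3×3 blocks
L_ij·I.  It is a weighted graph Laplacian: with A = 0 and μ = 1 it reduces
exactly to the 0/1 graph Laplacian of the cutoff connectivity graph.
Parameters: μ (eV/Å², overall curvature scale), A (dimensionless decay,
default 3.0), r_nn (Å, nearest-neighbour distance of the initial structure),
r_cut (Å, default 2·r_nn).  μ defaults to 1 and can be estimated with one
extra gradient evaluation: for a smooth 0.01 Å sine-profile displacement v
along the structure's largest extent, μ ← ⟨v, ∇E(x+v) − ∇E(x)⟩ / ⟨v, P_{μ=1}v⟩,
clamped to [1e−2, 1e4].  This one-displacement Rayleigh-quotient recipe
recovers a known spring constant within a factor of ~2 on a quadratic test
surface (checked in the test suite), which is all a metric scale needs.

**FF (Gauss–Newton) metric.**  Given a surrogate force field
V_FF = Σ_α V_α(ξ_α(x)) over internal coordinates ξ_α (distances, bend
angles, dihedrals), each term's Hessian splits into

    H_α = (∂ξ_α/∂x ⊗ ∂ξ_α/∂x)·V_α'' + (∂²ξ_α/∂x²)·V_α'

The second part vanishes whenever the geometry is at the term's equilibrium
and has ambiguous sign otherwise; the first part is PSD whenever V_α'' ≥ 0.
The metric keeps only the first part with the 1-D curvature forced positive:

    P_FF = Σ_α (∂ξ_α/∂x ⊗ ∂ξ_α/∂x)·|V_α''|

Consequences: (i) P_FF is PSD by construction at *every* geometry, so the
surrogate's parameters never need re-fitting during the run; (ii) second
derivatives of the internal coordinates are never computed — only the same
∂ξ/∂x vectors that force-field gradient code already produces plus the
scalar 1-D curvatures; (iii) with only short-range bonded terms the matrix
is sparse and assembly is linear in the number of terms.  Supported term
forms: quadratic ½k(q−q0)², Morse D0(1−e^(−α(d−d0)))² (curvature
2D0α²(2e^(−2αΔ)−e^(−αΔ))), cosine torsion ½k_φ(1+cos(nφ−φ0)) (curvature
−½k_φn²cos(nφ−φ0), negative over half its period — precisely why the
absolute value is taken in the metric and not in the potential).

**Exp+FF metric.**  For molecular crystals the FF metric captures
intramolecular stiffness but not inter-molecular contacts.  The combination
keeps the FF matrix and adds Exp off-diagonal blocks only on atom pairs
whose P_FF 3×3 block is entirely zero, together with their own Laplacian
diagonal compensation so the retained Exp part alone remains PSD.  Merge
granularity is the atom-pair block (both matrices are isotropic per pair, so
the block is the natural unit).  Relative scaling of the two parts is
carried by μ.

**EAM metric.**  For metals the surrogate is an embedded-atom potential
V = Σ_i [½ Σ_j Φ(r_ij) + F(Σ_j ρ(r_ij))] with splined Φ, ρ, F.  The metric
is the pair-distance Gauss–Newton form with per-pair curvature
|Φ''(r) + (F'(n_i)+F'(n_j))ρ''(r) + (F''(n_i)+F''(n_j))ρ'(r)²| where n_i is
the host density at atom i.  Cross-pair embedding couplings (F''ρ'ρ' between
different pairs sharing an atom) are excluded — the per-pair diagonal
curvature is one defensible reading of the pair-resolved construction; the
alternative (including cross terms) would densify rows around high-
coordination atoms for little benefit in a metric.

**Baselines.**  For comparison the package also builds preconditioners from
the exact (finite-difference) Hessian of a surrogate: mode "abs" replaces
every eigenvalue λ by max(|λ|, shift); mode "shift" moves only near-zero
(and negative) eigenvalues to the shift.  These require a dense eigensolve
and are only affordable for small systems — which is their point: the sparse
FF metric is the practical alternative.

**Regularisation.**  An isolated molecule's P_FF has at least six exact zero
modes (rigid translations and rotations); lattices retain three.  All
metrics are used as P + cI with generic defaults c = 0.1 eV/Å² for
minimisation and c = 1.0 eV/Å² for saddle search.  Inverse applications go
through a cached sparse LU factorisation with an enforced residual contract
‖Pz − g‖∞ ≤ 1e−8·‖g‖∞; the factorisation is invalidated whenever the
geometry (and hence the matrix) changes, and the metric is reassembled after
every accepted optimisation step.

## Optimisers

**Preconditioned LBFGS.**  The standard two-loop recursion with a single
modification: the initial-Hessian scaling at the centre is replaced by one
application z = P⁻¹q.  Step lengths come from backtracking enforcing only
the Armijo condition (defaults: α₀ = 1, factor 0.5, c₁ = 1e−4, ≤20 trials).
History pairs with yᵀs ≤ 1e−10 are discarded; on line-search failure the
history is cleared and the step restarts from −P⁻¹g.  Default memory m = 10.
Convergence criterion is ‖∇E‖∞ < fmax with fmax defaulting to 1e−3 eV/Å
(1e−4 is appropriate when gradient evaluations are cheap).

**Preconditioned dimer.**  Saddle search alternates two steps.  *Rotation*
(deliberately unpreconditioned — preconditioning it can shrink the spectral
gap that rotation convergence relies on): with a single forward endpoint
x + l·v (separation l = 0.01 Å), curvature C(v) = (g₁−g₀)·v/l and rotation
force −2/l·(g₁−g₀)⊥ drive a Fourier-style angle solve
(C(θ) = c + a·cos2θ + b·sin2θ needs one trial rotation per iteration); up to
3 iterations per cycle, tolerance 0.1 eV/Å, tightened proportionally to the
current ‖∇f‖∞ so the orientation keeps pace in the superlinear endgame.
*Translation*: Polak–Ribière CG on the reflected force
q = −(I − 2v⊗v)∇f, with the CG scalar evaluated in the metric,
β = qᵀP⁻¹(q−q_prev) / q_prevᵀP⁻¹q_prev, and the trial direction
P⁻¹s/(sᵀP⁻¹s).  The step length along the normalised direction is a secant
curvature estimate of the reflected force field (one extra gradient), capped
by a trust radius (start 0.1 Å, bounds [1e−4, 0.5] Å, ×1.5 on acceptance,
×0.5 + CG restart on rejection); the acceptance test is the projection of
the post-step reflected force on the step direction, rejecting only
significant overshoots (projection < −½ of the pre-step value — a strict
sign test rejects harmless secant noise and collapses the radius).  The
P-metric normalisation makes the whole translation invariant under P → γP,
so rescaling μ (with the matching cI) leaves trajectories bit-identical —
asserted in the tests.  Initial orientations are seeded unit Gaussians with
rigid-body components projected out.

The reading of the CG output normalisation (metric normalisation of the
trial direction *before* trust-radius capping, with the step length from the
secant estimate) is a design choice; any fixed placement of the scaling
yields the same invariance properties.

## Diagnostics

Conditioning is quantified by generalized condition numbers: solve
Hu = λPu after projecting the analytic rigid-body space (translations +
rotations about the centroid for molecules — 5 for collinear geometries —
or lattice translations for periodic systems) out of the Hessian, and
report κ_P = λmax/λmin, κ_I (P = I) and the ratio κ_I/κ_P.  Both the max and
the min are taken over the projected Hessian (using the unprojected H only
in the numerator would mix in the null space).  Projection uses analytically
constructed modes, not eigenvalue thresholding — deterministic and exact;
thresholding at 1e−6·λmax is retained only for the detection warning.
Finite-difference Hessians are central differences of the gradient
(default h = 1e−4 Å), symmetrised.

The benchmark harness runs every preconditioner arm from identical seeded
starts and reports per-seed and median function/gradient call counts plus
gain ratios over the identity arm (medians, since single runs of a seeded
start are noisy); non-converged runs are recorded as censored, never
dropped.

## Synthetic test bed

The fixture generator produces the study conditions:

* **chain-molecule** — an n-atom zigzag chain with quadratic bonds
  (k = 40 eV/Å², r0 = 1.5 Å), quadratic bends (k = 4 eV/rad², θ0 ≈ 109.5°)
  and 3-fold cosine torsions (k_φ = 0.05 eV, minimum at trans).  The ≥800×
  bond/torsion stiffness contrast makes the unpreconditioned problem
  ill-conditioned in the stiffness sense.
* **ring-molecule** — the cyclic analogue; its planar geometry puts the
  torsions in the negative-curvature half of their period, exercising the
  |V''| positivation.
* **toy-crystal** — several short chains in a periodic box with bonded terms
  only; inter-molecular coupling is left to the Exp part of Exp+FF.
* **cubic-lattice / lattice-vacancy** — n×n×n fcc (or diamond) supercells
  (a = 4 Å) with quadratic springs on every neighbour-list pair at its ideal
  length; the vacancy variant removes one atom.  Size-driven
  ill-conditioning grows with n.

Starting points are Gaussian perturbations of the ideal geometry with
stddev 0.05 Å (the generic "thermalised start" magnitude; molecules use up
to 0.1–0.15 Å where a larger basin excursion is wanted).  Generation is a
pure function of the spec (seeded).

The "expensive" target surfaces are the force field plus seeded cubic and
quartic anharmonicity per coordinate (relative amplitude 0.1 of the local
force constant, quartic coefficient positive so the basin stays bounded),
weak couplings ξ_α·ξ_β between adjacent terms (relative amplitude 0.03), and
a soft 12-6 nonbonded tail (ε = 0.002 eV, σ = 3 Å) between atoms sharing no
bonded term.  The preconditioner's force field is additionally *detuned*
(stiffnesses rescaled by seeded factors in [0.7, 1.3]) so that P is built
from a model different from the target — the realistic situation of a
generic force field preconditioning a quantum surface.  What this test bed
does **not** emulate: electrostatics, strong anharmonicity far from minima,
bond topology changes, or the specific molecules of any published benchmark;
a speed-up here demonstrates the mechanism (conditioning), not chemistry.

Problem sizes used by the shipped acceptance pipeline were chosen to keep a
full run in about a minute on one core: chains of 6–10 atoms, fcc supercells
of 2³ and 4³ cells (32 and 256 atoms), 3-coordinate analytic saddle
surfaces, 300 randomized geometries for the positivity sweep.

## Numerical choices and degenerate inputs

* Minimum-image vectors search the 27 candidate images around the
  fractional-wrapped representative, so mildly skewed cells are exact.  The
  neighbour list enumerates genuine multiple images for cells smaller than
  2·r_cut; self-image edges are skipped in Laplacian-type assembly because
  their Γ-point contribution cancels identically.
* Angle gradients use the cross-product formulation (stable near π, unlike
  the arccos derivative).  Exactly collinear angles are flagged degenerate
  and assembled with a fixed perpendicular fallback frame — the metric only
  needs PSD-ness there, not exactness.  Dihedrals use the atan2 construction
  with the +π branch preferred at planar-trans; since only ∂ξ/∂x ⊗ ∂ξ/∂x
  enters the metric, the sign convention is immaterial to P_FF.
* Coincident atoms (r < 1e−10 Å), zero-area dihedral planes and collinear
  dihedral axes raise geometry errors naming the offending term.
* LBFGS directions that fail the descent test (possible with a stale
  history) trigger a history reset rather than a failed step.

## Known limitations

* The dimer implementation rotates with a single forward endpoint; central
  (two-endpoint) rotation would halve the finite-difference error per
  gradient at twice the cost.
* Exact Hessian baselines use dense eigensolves — small systems only.
* The EAM metric's per-pair curvature excludes cross-pair embedding terms
  (see above); for strongly non-linear embedding functions this
  underestimates coupling between bonds sharing an atom.
* No variable-cell degrees of freedom: cells are fixed throughout.
* The parameter-file schema is keyed by explicit atom-index tuples; there is
  no atom typing or connectivity perception, by design — published general
  force fields differ mainly in parameter values, to which the metric is
  insensitive, so toy parameter sets suffice for the mechanism.
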