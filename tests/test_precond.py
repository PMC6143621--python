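import numpy as np
import pytest
import scipy.sparse as sp
from scipy.interpolate import CubicSpline

from precondopt import (
    EAMParams,
    ExpParams,
    FFTerm,
    FixtureSpec,
    ForceField,
    ForceFieldCalculator,
    NumericalError,
    QuadraticCalculator,
    QuadraticParams,
    Structure,
    TorsionParams,
    assemble_exp,
    assemble_peam,
    assemble_pff,
    baseline_exact_hessian,
    build_neighbor_list,
    combine_exp_ff,
    estimate_exp_params,
    finite_difference_hessian,
    make_fixture,
    make_precond_builder,
    regularize,
)
from precondopt.precond import Preconditioner
from precondopt import internal


def toy_eam(seed=0):
    r = np.linspace(1.5, 6.0, 60)
    phi = CubicSpline(r, 0.5 * np.exp(-2.0 * (r - 2.83)) - 0.3 * np.exp(-(r - 2.83)))
    rho = CubicSpline(r, np.exp(-1.2 * (r - 2.83)))
    n = np.linspace(0.0, 40.0, 80)
    F = CubicSpline(n, -np.sqrt(n))
    return EAMParams(pair=phi, density=rho, embedding=F, cutoff=5.5)


class TestExp:
    def test_laplacian_limit(self):
        """A=0, μ=1 reduces exactly to the 0/1 graph Laplacian of the cutoff graph."""
        s, _ = make_fixture(FixtureSpec("cubic-lattice", n=2, perturbation=0.0))
        r_cut = 3.0
        P = assemble_exp(s, ExpParams(mu=1.0, A=0.0, r_nn=2.8, r_cut=r_cut))
        nl = build_neighbor_list(s, r_cut)
        N = s.n_atoms
        L = np.zeros((N, N))
        for a, b in zip(nl.i, nl.j):
            if a == b:
                continue
            L[a, b] -= 1
            L[b, a] -= 1
            L[a, a] += 1
            L[b, b] += 1
        np.testing.assert_array_equal(P.dense(), np.kron(L, np.eye(3)))

    def test_two_atoms_at_rnn(self):
        s = Structure(["A", "B"], [[0, 0, 0], [2.0, 0, 0]])
        P = assemble_exp(s, ExpParams(mu=1.0, A=3.0, r_nn=2.0, r_cut=3.0))
        D = P.dense()
        assert D[0, 3] == pytest.approx(-1.0)
        assert D[0, 0] == pytest.approx(1.0)

    def test_row_sums_zero(self):
        s, _ = make_fixture(FixtureSpec("cubic-lattice", n=2, perturbation=0.05, seed=2))
        P = assemble_exp(s, ExpParams(mu=2.5, A=3.0, r_nn=2.83, r_cut=5.0))
        for axis in range(3):
            ones = np.zeros(P.n)
            ones[axis::3] = 1.0
            assert np.abs(P.matrix @ ones).max() < 1e-12

    def test_empty_neighbourhood_warns_and_zero(self):
        s = Structure(["A", "B"], [[0, 0, 0], [9.0, 0, 0]])
        with pytest.warns(UserWarning, match="no neighbours"):
            P = assemble_exp(s, ExpParams(mu=1.0, A=3.0, r_nn=1.0, r_cut=2.0))
        assert P.matrix.nnz == 0 or abs(P.matrix).max() == 0

    def test_estimated_params_crystal_defaults(self):
        s, _ = make_fixture(FixtureSpec("cubic-lattice", n=2, perturbation=0.0))
        p = estimate_exp_params(s)
        r_nn = 4.0 * np.sqrt(0.5)
        assert p.A == 3.0
        assert p.r_nn == pytest.approx(r_nn, rel=1e-6)
        assert p.r_cut == pytest.approx(2 * r_nn, rel=1e-6)
        assert p.mu == 1.0  # no calculator supplied

    def test_mu_estimate_within_factor_two_of_stiffness(self):
        k = 7.0
        s = Structure(["C"] * 4, [[0, 0, 0], [1.6, 0, 0], [3.2, 0, 0], [4.8, 0, 0]])
        H = np.zeros((12, 12))
        for a in range(3):
            u = np.zeros(12)
            u[3 * a] = 1
            u[3 * a + 3] = -1
            H += k * np.outer(u, u)
        H += 0.5 * np.eye(12)
        p = estimate_exp_params(s, QuadraticCalculator(H, s.x))
        assert k / 2 <= p.mu <= 2 * k


class TestPFF:
    def test_single_bond_rank_one(self):
        k = 13.0
        s = Structure(["A", "B"], [[0.2, -0.1, 0.3], [1.1, 0.8, -0.4]])
        ff = ForceField([FFTerm("distance", (0, 1), "quadratic", QuadraticParams(k=k, q0=1.0))])
        P = assemble_pff(s, ff)
        lam = np.sort(np.linalg.eigvalsh(P.dense()))
        np.testing.assert_allclose(lam[:5], 0.0, atol=1e-10)
        assert lam[5] == pytest.approx(2 * k)

    def test_gauss_newton_identity_at_equilibrium(self):
        """All-quadratic FF with q0 at the current geometry: P_FF equals the
        true Hessian because the first-derivative term vanishes there."""
        s, terms = make_fixture(FixtureSpec("chain-molecule", n=8, perturbation=0.1, seed=3))
        qterms = []
        for t in terms:
            c = internal.evaluate(s, t.kind, t.atoms)
            k = {"distance": 40.0, "angle": 4.0, "dihedral": 0.3}[t.kind]
            qterms.append(FFTerm(t.kind, t.atoms, "quadratic", QuadraticParams(k=k, q0=c.value)))
        qff = ForceField(qterms)
        P = assemble_pff(s, qff)
        H = finite_difference_hessian(ForceFieldCalculator(qff), s, h=1e-5)
        assert np.abs(P.dense() - H).max() < 1e-6

    def test_torsion_negative_curvature_still_psd(self):
        # planar cis geometry: torsion curvature is negative, |·| flips it
        s = Structure(["C"] * 4, [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        ff = ForceField(
            [FFTerm("dihedral", (0, 1, 2, 3), "torsion", TorsionParams(k_phi=1.0, n=3, phi0=0.0))]
        )
        P = assemble_pff(s, ff)
        lam = np.linalg.eigvalsh(P.dense())
        assert lam.min() >= -1e-10 * max(lam.max(), 1.0)
        assert lam.max() > 0  # the |−4.5 k_φ| curvature made it in

    @pytest.mark.parametrize("kind,n", [("chain-molecule", 6), ("ring-molecule", 6)])
    def test_psd_over_random_geometries(self, kind, n):
        for seed in range(30):
            s, terms = make_fixture(FixtureSpec(kind, n=n, perturbation=0.15, seed=seed))
            P = assemble_pff(s, ForceField(terms))
            lam = np.linalg.eigvalsh(P.dense())
            assert lam.min() >= -1e-8 * max(lam.max(), 1.0)

    def test_symmetric_exactly(self, chain):
        s, ff = chain
        P = assemble_pff(s, ff)
        assert (P.matrix != P.matrix.T).nnz == 0


class TestCombine:
    def test_empty_ff_gives_exp(self):
        s, _ = make_fixture(FixtureSpec("toy-crystal", n=3, n_molecules=2, seed=1))
        params = ExpParams(mu=1.0, A=3.0, r_nn=1.5, r_cut=7.0)
        pexp = assemble_exp(s, params)
        merged = combine_exp_ff(assemble_pff(s, ForceField([])), s, params)
        np.testing.assert_array_equal(merged.dense(), pexp.dense())

    def test_full_coverage_gives_pff(self):
        s = Structure(["A", "B"], [[0, 0, 0], [1.4, 0, 0]])
        ff = ForceField([FFTerm("distance", (0, 1), "quadratic", QuadraticParams(k=5, q0=1.4))])
        pff = assemble_pff(s, ff)
        with pytest.warns(UserWarning):  # nothing left for Exp to cover
            merged = combine_exp_ff(pff, s, ExpParams(mu=1.0, A=3.0, r_nn=1.4, r_cut=2.0))
        np.testing.assert_allclose(merged.dense(), pff.dense(), atol=1e-14)

    def test_two_molecule_merge_matches_hand_assembly(self):
        s, terms = make_fixture(
            FixtureSpec("toy-crystal", n=3, n_molecules=2, perturbation=0.02, seed=1)
        )
        ff = ForceField(terms)
        pff = assemble_pff(s, ff)
        params = ExpParams(mu=1.3, A=3.0, r_nn=1.5, r_cut=8.0)
        merged = combine_exp_ff(pff, s, params)
        D_ff = pff.dense()
        N = s.n_atoms
        covered = {
            (min(a, b), max(a, b))
            for a in range(N)
            for b in range(N)
            if a != b and np.any(D_ff[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] != 0)
        }
        nl = build_neighbor_list(s, params.r_cut)
        L = np.zeros((N, N))
        for a, b, r in zip(nl.i, nl.j, nl.distances):
            if a == b or (min(a, b), max(a, b)) in covered:
                continue
            w = params.mu * np.exp(-params.A * (r / params.r_nn - 1))
            L[a, b] -= w
            L[b, a] -= w
            L[a, a] += w
            L[b, b] += w
        np.testing.assert_allclose(merged.dense(), D_ff + np.kron(L, np.eye(3)), atol=1e-12)
        # intra-molecular off-diagonal blocks come from FF only
        intra = merged.dense()[0:3, 3:6]
        np.testing.assert_allclose(intra, D_ff[0:3, 3:6])

    def test_merged_is_psd(self):
        s, terms = make_fixture(
            FixtureSpec("toy-crystal", n=3, n_molecules=2, perturbation=0.05, seed=4)
        )
        merged = combine_exp_ff(
            assemble_pff(s, ForceField(terms)), s, ExpParams(mu=1.0, A=3.0, r_nn=1.5, r_cut=8.0)
        )
        lam = np.linalg.eigvalsh(merged.dense())
        assert lam.min() >= -1e-8 * lam.max()


class TestEAM:
    def test_zero_embedding_reduces_to_pair(self):
        s, _ = make_fixture(FixtureSpec("cubic-lattice", n=2, perturbation=0.03, seed=0))
        eam = toy_eam()
        n = np.linspace(0.0, 40.0, 80)
        eam0 = EAMParams(eam.pair, eam.density, CubicSpline(n, 0.0 * n), eam.cutoff)
        P = assemble_peam(s, eam0)
        d2 = eam.pair.derivative(2)
        nl = build_neighbor_list(s, eam.cutoff)
        D = np.zeros((3 * s.n_atoms,) * 2)
        for a, b, r, v in zip(nl.i, nl.j, nl.distances, nl.vectors):
            if a == b:
                continue
            u = v / r
            blk = abs(float(d2(r))) * np.outer(u, u)
            D[3 * a : 3 * a + 3, 3 * a : 3 * a + 3] += blk
            D[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] += blk
            D[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] -= blk
            D[3 * b : 3 * b + 3, 3 * a : 3 * a + 3] -= blk
        np.testing.assert_allclose(P.dense(), D, atol=1e-12)

    def test_single_pair_quadratic_matches_pff(self):
        r = np.linspace(0.5, 4.0, 120)
        k, r0 = 11.0, 2.0
        phi = CubicSpline(r, 0.5 * k * (r - r0) ** 2)
        n = np.linspace(0.0, 10.0, 40)
        zero = CubicSpline(n, 0.0 * n)
        rho = CubicSpline(r, 0.0 * r)
        s = Structure(["A", "B"], [[0, 0, 0], [0, 0, 2.1]])
        P = assemble_peam(s, EAMParams(phi, rho, zero, cutoff=3.5))
        ff = ForceField([FFTerm("distance", (0, 1), "quadratic", QuadraticParams(k=k, q0=r0))])
        np.testing.assert_allclose(P.dense(), assemble_pff(s, ff).dense(), atol=1e-6)

    def test_curvature_matches_spline_finite_differences(self):
        """Independent oracle: rebuild the per-pair curvature from central
        finite differences of the Φ, ρ, F splines themselves."""
        s, _ = make_fixture(FixtureSpec("cubic-lattice", n=2, perturbation=0.05, seed=5))
        eam = toy_eam()
        P = assemble_peam(s, eam)
        h = 1e-4

        def fd2(f, x):
            return (float(f(x + h)) - 2 * float(f(x)) + float(f(x - h))) / h**2

        def fd1(f, x):
            return (float(f(x + h)) - float(f(x - h))) / (2 * h)

        nl = build_neighbor_list(s, eam.cutoff)
        dens = np.zeros(s.n_atoms)
        for a, b, r in zip(nl.i, nl.j, nl.distances):
            if a == b:
                dens[a] += 2 * float(eam.density(r))
            else:
                dens[a] += float(eam.density(r))
                dens[b] += float(eam.density(r))
        D = np.zeros((3 * s.n_atoms,) * 2)
        for a, b, r, v in zip(nl.i, nl.j, nl.distances, nl.vectors):
            if a == b:
                continue
            curv = fd2(eam.pair, r)
            curv += (fd1(eam.embedding, dens[a]) + fd1(eam.embedding, dens[b])) * fd2(eam.density, r)
            curv += (fd2(eam.embedding, dens[a]) + fd2(eam.embedding, dens[b])) * fd1(eam.density, r) ** 2
            u = v / r
            blk = abs(curv) * np.outer(u, u)
            D[3 * a : 3 * a + 3, 3 * a : 3 * a + 3] += blk
            D[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] += blk
            D[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] -= blk
            D[3 * b : 3 * b + 3, 3 * a : 3 * a + 3] -= blk
        assert np.abs(P.dense() - D).max() < 1e-5 * max(1.0, np.abs(D).max())

    def test_out_of_domain_distance_rejected(self):
        eam = toy_eam()
        s = Structure(["A", "B"], [[0, 0, 0], [0.8, 0, 0]])  # below spline start 1.5 Å
        with pytest.raises(ValueError, match="outside spline domain"):
            assemble_peam(s, eam)


class TestRegularizeAndSolve:
    def test_zero_matrix_becomes_cI(self):
        P = Preconditioner(sp.csr_matrix((6, 6)))
        R = regularize(P, 0.25)
        np.testing.assert_array_equal(R.dense(), 0.25 * np.eye(6))

    def test_molecule_six_zero_modes_lifted(self, chain):
        s, ff = chain
        P = assemble_pff(s, ff)
        lam = np.sort(np.linalg.eigvalsh(P.dense()))
        assert (np.abs(lam[:6]) < 1e-8 * lam[-1]).all()
        lam_reg = np.linalg.eigvalsh(regularize(P, 0.1).dense())
        assert lam_reg.min() >= 0.1 - 1e-8

    def test_nonpositive_c_rejected(self, chain):
        s, ff = chain
        with pytest.raises(ValueError, match="c must be"):
            regularize(assemble_pff(s, ff), 0.0)

    def test_apply_inverse_scaled_identity(self):
        P = Preconditioner(2.0 * sp.identity(9, format="csr"), c=2.0)
        g = np.arange(1.0, 10.0)
        np.testing.assert_allclose(P.apply_inverse(g), g / 2)

    def test_apply_inverse_residual_contract(self, chain):
        s, ff = chain
        P = regularize(assemble_pff(s, ff), 0.1)
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = rng.normal(size=P.n)
            z = P.apply_inverse(g)
            assert np.abs(P.matrix @ z - g).max() <= 1e-8 * np.abs(g).max()

    def test_singular_matrix_raises(self, chain):
        s, ff = chain
        P = assemble_pff(s, ff)  # six zero modes, not regularised
        with pytest.raises(NumericalError, match="regularise"):
            P.apply_inverse(np.ones(P.n))


class TestBaselines:
    def test_abs_mode_spectrum(self):
        H = np.diag([-1.0, 0.0, 2.0])
        P = baseline_exact_hessian(H, shift=0.1, mode="abs")
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(P.dense())), [0.1, 1.0, 2.0])

    def test_abs_mode_identity_on_pd_input(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(5, 5))
        H = A @ A.T + np.eye(5)
        P = baseline_exact_hessian(H, shift=0.0, mode="abs")
        np.testing.assert_allclose(P.dense(), H, atol=1e-10)

    def test_shift_mode_moves_null_space_only(self):
        H = np.diag([0.0, 3.0, 7.0])
        P = baseline_exact_hessian(H, shift=0.5, mode="shift")
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(P.dense())), [0.5, 3.0, 7.0])

    def test_from_forcefield_matches_pff_plus_nullspace(self, chain):
        """Quadratic FF at its own equilibrium: |spectrum| of the Hessian is
        the Gauss–Newton metric away from the rigid-body null space."""
        s, terms = make_fixture(FixtureSpec("chain-molecule", n=6, perturbation=0.1, seed=9))
        qterms = []
        for t in terms:
            c = internal.evaluate(s, t.kind, t.atoms)
            qterms.append(FFTerm(t.kind, t.atoms, "quadratic", QuadraticParams(k=3.0, q0=c.value)))
        qff = ForceField(qterms)
        P = baseline_exact_hessian(qff, s, shift=0.05, mode="abs")
        ref = assemble_pff(s, qff).dense()
        lam_p = np.sort(np.linalg.eigvalsh(P.dense()))
        lam_r = np.sort(np.linalg.eigvalsh(ref))
        np.testing.assert_allclose(lam_p[6:], lam_r[6:], atol=1e-5)
        np.testing.assert_allclose(lam_p[:6], 0.05, atol=1e-5)


class TestBuilderFactory:
    def test_identity_is_none(self):
        assert make_precond_builder("id") is None

    def test_ff_requires_forcefield(self):
        with pytest.raises(ValueError, match="requires a force field"):
            make_precond_builder("ff")

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown preconditioner"):
            make_precond_builder("magic")

    def test_ff_builder_returns_pd_operator(self, chain):
        s, ff = chain
        P = make_precond_builder("ff", ff=ff, c=0.1)(s)
        assert np.linalg.eigvalsh(P.dense()).min() >= 0.1 - 1e-8
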