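"""Constitutive laws and nonlinear FE solver.

Oracle strategy: the stress implementations are checked against independent
routes - finite differences of the stored energy, direct matrix arithmetic,
a scalar evaluation of the activation law, a 0D constitutive inversion for
the patch test - rather than against themselves.
"""

import numpy as np
import pytest
from scipy.optimize import root
from scipy.stats import special_ortho_group

from warpstrain.mechanics import (
    ActiveParams,
    FEAssembly,
    PassiveParams,
    _second_piola,
    active_tension,
    calcium_sensitivity,
    kinematics,
    passive_stress,
    solve_equilibrium,
    strain_energy_density,
    total_stress,
    InvertedElementError,
)

PASSIVE = PassiveParams()
ACTIVE = ActiveParams()
UNIT_CUBE = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)


def _affine_disp(F):
    return UNIT_CUBE @ F.T - UNIT_CUBE


class TestKinematics:
    def test_identity_map(self):
        st = kinematics(UNIT_CUBE, np.zeros((8, 3)), np.zeros(3))
        np.testing.assert_allclose(st.F, np.eye(3), atol=1e-14)
        assert st.J == pytest.approx(1.0)
        assert st.fiber_stretch == pytest.approx(1.0)
        assert st.sarcomere_length == pytest.approx(2.04)

    def test_affine_field_exact(self):
        F = np.diag([1.1, 1.0, 1.0])
        st = kinematics(UNIT_CUBE, _affine_disp(F), np.array([0.3, -0.2, 0.7]))
        np.testing.assert_allclose(st.F, F, atol=1e-13)

    def test_fiber_stretch_matches_matrix_oracle(self, rng):
        F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
        a = rng.standard_normal(3)
        a /= np.linalg.norm(a)
        st = kinematics(UNIT_CUBE, _affine_disp(F), np.zeros(3), fiber=a)
        lam = np.sqrt(a @ (F.T @ F) @ a)
        assert st.fiber_stretch == pytest.approx(lam, abs=1e-12)

    def test_inverted_element_reported(self):
        F = np.diag([-0.5, 1.0, 1.0])
        with pytest.raises(InvertedElementError):
            kinematics(UNIT_CUBE, _affine_disp(F), np.zeros(3), element_id=7)


class TestActiveLaw:
    def test_calcium_sensitivity_closed_form(self):
        l = 1.58 + np.log(2.0) / 4.75  # exp term = 2
        assert calcium_sensitivity(l) == pytest.approx(4.35, rel=1e-12)

    def test_sensitivity_diverges_at_zero_tension_length(self):
        assert np.isinf(calcium_sensitivity(1.58))
        assert calcium_sensitivity(1.5801) > 100.0

    def test_sensitivity_strictly_decreasing(self):
        l = np.linspace(1.581, 3.0, 100)
        e = calcium_sensitivity(l)
        assert np.all(np.diff(e) < 0)

    def test_zero_tension_at_and_below_l0(self):
        assert active_tension(1.58, 5.0) == 0.0
        assert active_tension(1.2, 5.0) == 0.0

    def test_linear_in_activation_and_bounded(self):
        t1 = active_tension(2.2, 1.0)
        assert active_tension(2.2, 0.0) == 0.0
        assert active_tension(2.2, 3.0) == pytest.approx(3 * t1, rel=1e-12)
        assert t1 < ACTIVE.tmax

    def test_scalar_oracle_at_printed_constants(self):
        """Independent scalar evaluation of the elastance law at l = 2.5 um."""
        l, act = 2.5, 0.7
        eca = 4.35 / np.sqrt(np.exp(4.75 * (l - 1.58)) - 1.0)
        expected = 135.7 * 4.35**2 / (4.35**2 + eca**2) * act
        assert active_tension(l, act) == pytest.approx(expected, rel=1e-12)

    def test_continuity_at_l0(self):
        eps = 1e-9
        assert active_tension(1.58 + eps, 1.0) < 1e-6

    def test_negative_activation_rejected(self):
        with pytest.raises(ValueError):
            active_tension(2.2, -0.1)


class TestPassiveStress:
    def test_stress_free_reference(self):
        st = kinematics(UNIT_CUBE, np.zeros((8, 3)), np.zeros(3))
        np.testing.assert_allclose(passive_stress(st, [1, 0, 0]), 0.0, atol=1e-12)

    def test_transverse_isotropy_stiffer_along_fiber(self):
        a = np.array([1.0, 0.0, 0.0])
        F_along = np.diag([1.1, 1.0, 1.0])
        F_across = np.diag([1.0, 1.1, 1.0])
        st1 = kinematics(UNIT_CUBE, _affine_disp(F_along), np.zeros(3), fiber=a)
        st2 = kinematics(UNIT_CUBE, _affine_disp(F_across), np.zeros(3), fiber=a)
        s_along = passive_stress(st1, a)[0, 0]
        s_across = passive_stress(st2, a)[1, 1]
        assert s_along > s_across > 0

    def test_objectivity_under_random_rotations(self, rng):
        F = np.eye(3) + 0.12 * rng.standard_normal((3, 3))
        a = rng.standard_normal(3)
        a /= np.linalg.norm(a)
        st = kinematics(UNIT_CUBE, _affine_disp(F), np.zeros(3), fiber=a)
        sig = passive_stress(st, a)
        for seed in range(3):
            Q = special_ortho_group.rvs(3, random_state=seed)
            stQ = kinematics(UNIT_CUBE, _affine_disp(Q @ F), np.zeros(3), fiber=a)
            np.testing.assert_allclose(
                passive_stress(stQ, a), Q @ sig @ Q.T, atol=1e-10
            )

    def test_stress_is_energy_gradient(self, rng):
        """First Piola stress vs finite differences of W at 50 random
        states, 1e-5 relative."""
        for _ in range(50):
            F = np.eye(3) + 0.12 * rng.standard_normal((3, 3))
            if np.linalg.det(F) < 0.5:
                continue
            a = rng.standard_normal(3)
            a /= np.linalg.norm(a)
            S = _second_piola(F[None], a[None], PASSIVE, None, 0.0)[0]
            P = F @ S
            h = 1e-6
            Pfd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    Pfd[i, j] = (
                        strain_energy_density(Fp, a) - strain_energy_density(Fm, a)
                    ) / (2 * h)
            np.testing.assert_allclose(P, Pfd, atol=1e-5 * max(np.abs(P).max(), 1.0))

    def test_symmetry(self, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        a = rng.standard_normal(3)
        a /= np.linalg.norm(a)
        st = kinematics(UNIT_CUBE, _affine_disp(F), np.zeros(3), fiber=a)
        sig = passive_stress(st, a)
        np.testing.assert_allclose(sig, sig.T, atol=1e-12)


class TestTotalStress:
    def test_zero_active_reduces_to_passive(self, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        a0 = rng.standard_normal(3)
        a0 /= np.linalg.norm(a0)
        st = kinematics(UNIT_CUBE, _affine_disp(F), np.zeros(3), fiber=a0)
        a_cur = F @ a0
        a_cur /= np.linalg.norm(a_cur)
        np.testing.assert_allclose(
            total_stress(st, a_cur, PASSIVE, 0.0),
            passive_stress(st, np.linalg.solve(F, a_cur) / np.linalg.norm(np.linalg.solve(F, a_cur))),
            atol=1e-10,
        )

    def test_rank_one_active_term_at_identity(self):
        st = kinematics(UNIT_CUBE, np.zeros((8, 3)), np.zeros(3))
        sig = total_stress(st, np.array([1.0, 0, 0]), PASSIVE, 7.5)
        np.testing.assert_allclose(sig, np.diag([7.5, 0, 0]), atol=1e-10)

    def test_trace_identity(self, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        st = kinematics(UNIT_CUBE, _affine_disp(F), np.zeros(3))
        a = rng.standard_normal(3)
        a /= np.linalg.norm(a)
        tau = 3.3
        diff = total_stress(st, a, PASSIVE, tau) - total_stress(st, a, PASSIVE, 0.0)
        assert np.trace(diff) == pytest.approx(tau, rel=1e-10)


class TestSolver:
    def _fix_symmetry(self):
        fixed = np.zeros((8, 3), dtype=bool)
        fixed[UNIT_CUBE[:, 0] == 0, 0] = True
        fixed[UNIT_CUBE[:, 1] == 0, 1] = True
        fixed[UNIT_CUBE[:, 2] == 0, 2] = True
        return fixed

    def test_zero_load_zero_displacement(self, unit_cube_mesh):
        fib = np.tile([1.0, 0, 0], (1, 8, 1))
        u = solve_equilibrium(unit_cube_mesh, fib, PASSIVE)
        assert np.abs(u).max() == 0.0

    def test_patch_test_matches_constitutive_inversion(self, unit_cube_mesh):
        """Uniaxial dead load on one element: homogeneous F must agree with
        a 0D inversion of the constitutive law to 1e-6."""
        fib = np.tile([1.0, 0, 0], (1, 8, 1))
        a0 = np.array([1.0, 0, 0])
        load = 1.0  # total force, kPa*mm^2, on the +x face of a unit cube
        f = np.zeros((8, 3))
        f[[1, 2, 5, 6], 0] = load / 4
        u = solve_equilibrium(
            unit_cube_mesh, fib, PASSIVE, external_forces=f, fixed=self._fix_symmetry()
        )
        F = FEAssembly(unit_cube_mesh).deformation_gradients(u)
        assert np.ptp(F, axis=(0, 1)).max() < 1e-10  # homogeneous

        def eqs(lam):
            Fd = np.diag(lam)
            P = Fd @ _second_piola(Fd[None], a0[None], PASSIVE, None, 0.0)[0]
            return [P[0, 0] - load, P[1, 1], P[2, 2]]

        lam = root(eqs, [1.05, 0.98, 0.98], tol=1e-14).x
        np.testing.assert_allclose(np.diagonal(F[0, 0]), lam, atol=1e-6)

    def test_newton_superlinear_on_patch_test(self, unit_cube_mesh):
        """Residual contraction ratios shrink along the Newton path (the
        complex-step tangent is exact, so convergence is quadratic)."""
        import scipy.sparse.linalg as spla

        from warpstrain.mechanics import FEAssembly

        fib = np.tile([1.0, 0, 0], (1, 8, 1))
        f = np.zeros((8, 3))
        f[[1, 2, 5, 6], 0] = 0.5
        asm = FEAssembly(unit_cube_mesh)
        u = np.zeros((8, 3))
        free = ~self._fix_symmetry()
        mask = free.ravel()
        norms = []
        for _ in range(7):
            r = asm.internal_forces(u, fib, PASSIVE) - f
            norms.append(np.linalg.norm(r[free]))
            K = asm.tangent(u, fib, PASSIVE)
            du = np.zeros(24)
            du[mask] = spla.spsolve(K[mask][:, mask].tocsc(), -r.ravel()[mask])
            u = u + du.reshape(8, 3)
        norms = np.array(norms)
        sig = norms[norms > 1e-12]
        ratios = sig[1:] / sig[:-1]
        # asymptotically accelerating contraction (superlinear tail)
        assert np.all(np.diff(ratios[-3:]) < 0)
        assert sig[-1] < 1e-7 * sig[0]

    def test_uniform_activation_thickens_wall(self, small_mesh):
        """Pure contraction (no image forces) on the LV mesh: wall thickens
        and the cavity shrinks, from contraction along the fiber helix."""
        from warpstrain.lvmesh import assign_fibers, local_frames
        from warpstrain.strain_compare import green_lagrange
        from warpstrain.warping import base_constraints

        fib = assign_fibers(small_mesh)
        u = solve_equilibrium(
            small_mesh, fib.vectors, PASSIVE, ACTIVE,
            activation=0.05, fixed=base_constraints(small_mesh), max_step=1.0,
        )
        F = FEAssembly(small_mesh).deformation_gradients(u)
        E = green_lagrange(F)
        fr = local_frames(small_mesh)
        err = np.einsum("egx,egxy,egy->eg", fr.radial, E, fr.radial)
        ecc = np.einsum("egx,egxy,egy->eg", fr.circumferential, E, fr.circumferential)
        assert err.mean() > 0  # radial thickening
        assert ecc.mean() < 0  # circumferential shortening = smaller cavity

    def test_nonconvergence_raises(self, unit_cube_mesh):
        from warpstrain.mechanics import SolverError

        fib = np.tile([1.0, 0, 0], (1, 8, 1))
        f = np.zeros((8, 3))
        f[[1, 2, 5, 6], 0] = 1e5  # absurd load
        with pytest.raises((SolverError, InvertedElementError)):
            solve_equilibrium(
                unit_cube_mesh, fib, PASSIVE, external_forces=f,
                fixed=self._fix_symmetry(), max_iter=5,
            )
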