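"""Constrained bending-energy minimization along the elongation branch."""

import numpy as np
import pytest

from corset.errors import BranchError
from corset.geometry import AxisymmetricShape, geometry_report, make_spheroid
from corset.solver import (
    EnergyModel,
    ShapeSolution,
    SolverOptions,
    WILLMORE_BOUND,
    bending_energy,
    classify_shape,
    minimize_shape,
    shape_family,
    sphere_dAoverA,
    trial_prolate_oracle,
)
from tests.conftest import D_REF, FAMILY_TARGETS, SPHERE_AREA_500


def spheroid_energy_quadrature(a, b, n=20001):
    """Brute-force oracle: ∮J²dA of a spheroid from analytic curvatures."""
    theta = np.linspace(0.0, np.pi, n)
    r = b * np.sin(theta)
    dr, dz = b * np.cos(theta), a * np.sin(theta)
    d2r, d2z = -b * np.sin(theta), a * np.cos(theta)
    g = np.sqrt(dr**2 + dz**2)
    c_m = (dr * d2z - dz * d2r) / g**3
    with np.errstate(divide="ignore", invalid="ignore"):
        c_a = np.where(r > 1e-12, dz / np.where(r > 1e-12, r, 1.0) / g, c_m)
    J = c_m + c_a
    return np.trapezoid(J**2 * 2 * np.pi * r * g, theta)


class TestBendingEnergy:
    @pytest.mark.parametrize("R", [1.0, 250.0, 5000.0])
    def test_sphere_closed_form_and_scale_invariance(self, R):
        from corset.geometry import make_sphere

        model = EnergyModel(d=10.0, kappa=1.0)
        F = bending_energy(make_sphere(4 * np.pi * R**2, n_nodes=400), model)
        assert F == pytest.approx(16 * np.pi, rel=1e-6)

    def test_kappa_scaling(self):
        from corset.geometry import make_sphere

        shape = make_sphere(4 * np.pi * 100.0**2)
        F1 = bending_energy(shape, EnergyModel(d=10.0, kappa=1.0))
        F3 = bending_energy(shape, EnergyModel(d=10.0, kappa=3.0))
        assert F3 == pytest.approx(3 * F1, rel=1e-12)

    def test_prolate_spheroid_against_quadrature_oracle(self):
        a, b = 500.0, 250.0  # a = 2b
        F = bending_energy(make_spheroid(a, b, n_nodes=2000),
                           EnergyModel(d=10.0))
        assert F == pytest.approx(spheroid_energy_quadrature(a, b), rel=1e-3)


class TestMinimizeShape:
    def test_sphere_target_recovers_sphere(self):
        """At the sphere's own ΔA/A the sphere is the unique minimum."""
        sol = minimize_shape(SPHERE_AREA_500, 0.08, EnergyModel(d=D_REF))
        assert sol.converged
        assert sol.sphericity == pytest.approx(1.0, abs=1e-3)
        assert sol.energy == pytest.approx(WILLMORE_BOUND, rel=1e-3)
        assert sol.shape_class == "sphere"

    def test_elongation_target(self):
        sol = minimize_shape(SPHERE_AREA_500, 0.12, EnergyModel(d=D_REF))
        assert sol.converged
        assert sol.sphericity < 1.0
        assert max(sol.constraint_residuals.values()) <= 1e-4
        bound = trial_prolate_oracle(SPHERE_AREA_500, 0.12, D_REF)
        assert sol.energy <= bound * (1 + 1e-3)

    def test_oblate_branch_rejected(self):
        with pytest.raises(BranchError):
            minimize_shape(SPHERE_AREA_500, 0.05, EnergyModel(d=D_REF))


class TestShapeFamily:
    def test_monotone_sphericity_and_energy(self, reference_family):
        sph = [s.sphericity for s in reference_family]
        en = [s.energy for s in reference_family]
        assert all(b <= a + 1e-3 for a, b in zip(sph, sph[1:]))
        assert all(b >= a - 1e-6 for a, b in zip(en, en[1:]))
        assert reference_family[0].shape_class == "sphere"
        assert reference_family[-1].shape_class == "peanut"

    def test_achieved_targets(self, reference_family):
        for sol, tgt in zip(reference_family, FAMILY_TARGETS):
            assert sol.achieved_dAoverA == pytest.approx(tgt, rel=1e-4)

    def test_mesh_independence(self, reference_family):
        """Sphericity of the converged profile is stable under refinement."""
        from corset.solver import _build_full_shape

        R0 = np.sqrt(SPHERE_AREA_500 / (4 * np.pi))
        for sol in reference_family:
            coarse = geometry_report(
                _build_full_shape(sol.coefficients, R0, 200)
            )["sphericity_3d"]
            fine = geometry_report(
                _build_full_shape(sol.coefficients, R0, 400)
            )["sphericity_3d"]
            assert abs(fine - coarse) < 1e-3

    def test_seed_robustness(self, reference_family):
        """A different symmetry-breaking seed lands on the same branch."""
        other = shape_family(
            SPHERE_AREA_500, D_REF, FAMILY_TARGETS,
            EnergyModel(d=D_REF), SolverOptions(seed=1234),
        )
        for a, b in zip(reference_family, other):
            assert abs(a.sphericity - b.sphericity) < 1e-3

    def test_non_increasing_targets_rejected(self):
        from corset.errors import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            shape_family(SPHERE_AREA_500, D_REF, [0.10, 0.10],
                         EnergyModel(d=D_REF))


class TestClassifyShape:
    @staticmethod
    def _solution_with(shape, sphericity):
        return ShapeSolution(
            shape=shape, target_dAoverA=0.1, achieved_dAoverA=0.1,
            energy=100.0, constraint_residuals={"area": 0, "area_diff": 0},
            sphericity=sphericity, shape_class="", iterations=0,
            converged=True, coefficients=np.zeros(2),
        )

    def test_prolate_spheroid_is_elongated(self):
        shape = make_spheroid(500.0, 250.0)
        assert classify_shape(self._solution_with(shape, 0.95)) == "elongated"

    def test_dumbbell_is_peanut(self):
        """Two lobes bridged by a 0.8×R neck."""
        t = np.linspace(0.0, 1.0, 201)
        r = np.sin(np.pi * t) * (1 - 0.2 * np.exp(-(((t - 0.5) / 0.08) ** 2)))
        shape = AxisymmetricShape(s=t + 0.0, psi=np.zeros_like(t), r=r,
                                  z=np.zeros_like(t))
        assert classify_shape(self._solution_with(shape, 0.6)) == "peanut"

    def test_near_unit_sphericity_is_sphere(self):
        shape = make_spheroid(250.0, 250.0)
        assert classify_shape(self._solution_with(shape, 0.9995)) == "sphere"


class TestProlateOracle:
    def test_sphere_limit(self):
        sv = sphere_dAoverA(SPHERE_AREA_500, D_REF)
        assert trial_prolate_oracle(SPHERE_AREA_500, sv, D_REF) == pytest.approx(
            WILLMORE_BOUND, rel=1e-9
        )

    def test_matches_independent_quadrature(self):
        """The constraint-matched spheroid's energy agrees with brute force."""
        target = 0.12
        W = trial_prolate_oracle(SPHERE_AREA_500, target, D_REF)
        # invert: find the aspect whose reduced curvature matches, then
        # compare with the independent trapezoid oracle
        from scipy.optimize import brentq

        def reduced(c):
            shape = make_spheroid(c * 100.0, 100.0, n_nodes=3000)
            rep = geometry_report(shape)
            return (
                rep["integrated_mean_curvature"]
                / np.sqrt(16 * np.pi * rep["area"])
            )

        aspect = brentq(lambda c: reduced(c) - target / 0.08, 1.0001, 30.0)
        assert W == pytest.approx(
            spheroid_energy_quadrature(aspect * 100.0, 100.0), rel=1e-3
        )

    def test_unreachable_target(self):
        from corset.errors import UnreachableTargetError

        with pytest.raises(UnreachableTargetError):
            trial_prolate_oracle(SPHERE_AREA_500, 0.8, D_REF)
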