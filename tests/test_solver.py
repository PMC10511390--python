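"""Tests for the homogeneous compression boundary-value solver."""

import numpy as np
import pytest

import myomech as mm


@pytest.fixture(scope="module")
def combined_curves():
    """The six default-protocol simulations at the combined-fit parameter set."""
    p = mm.MaterialParameters(0.39, 0.53, 1.27)
    return {proto.name: mm.simulate_protocol(proto, p) for proto in mm.standard_protocols()}


class TestProtocols:
    def test_six_standard_protocols(self):
        names = [p.name for p in mm.standard_protocols()]
        assert names == [
            "axial_0",
            "axial_45",
            "axial_90",
            "semiconfined_I",
            "semiconfined_II",
            "semiconfined_III",
        ]

    @pytest.mark.parametrize(
        "kw",
        [
            dict(family="axial", configuration="30"),
            dict(family="confined", configuration="I"),
            dict(family="axial", configuration="0", max_nominal_strain=1.0),
            dict(family="axial", configuration="0", n_steps=0),
        ],
    )
    def test_invalid_protocols_rejected(self, kw):
        with pytest.raises(ValueError):
            mm.LoadProtocol(**kw)

    def test_strain_grid_has_reference_plus_steps(self):
        grid = mm.axial("0").strain_grid()
        assert grid.size == 51
        assert grid[0] == 0.0
        assert grid[-1] == pytest.approx(0.40)
        np.testing.assert_allclose(np.diff(grid), 0.008)


class TestAdmissibleDeformation:
    def test_reference_state(self):
        proto = mm.semiconfined("I")
        np.testing.assert_array_equal(
            mm.admissible_deformation(proto, 0.0, [1.0]), np.eye(3)
        )

    def test_confined_fibre_keeps_unit_stretch(self):
        # mode III: fibre on the blocked axis, so I4 = 1 whatever lambda_1 is
        proto = mm.semiconfined("III")
        for lam1 in (0.9, 1.2, 1.6):
            F = mm.admissible_deformation(proto, 0.4, [lam1])
            _, _, i4 = mm.invariants(F, proto.fibre)
            assert i4 == 1.0

    def test_shear_dof_enters_45_degree_kinematics(self):
        F = mm.admissible_deformation(mm.axial("45"), 0.2, [1.1, 1.05, 0.08])
        assert F[0, 2] == 0.08
        assert F[2, 0] == 0.0  # platens stay parallel: no F31

    def test_rejects_inadmissible_dofs(self):
        with pytest.raises(mm.InvalidDeformationError):
            mm.admissible_deformation(mm.semiconfined("I"), 0.1, [-1.0])


class TestEquilibrium:
    def test_reference_state_is_stress_free(self, params_combined):
        for proto in mm.standard_protocols():
            dofs, F, P = mm.equilibrium_solve(proto, 0.0, params_combined)
            np.testing.assert_array_equal(F, np.eye(3))
            np.testing.assert_allclose(P, 0.0, atol=1e-12)

    def test_free_faces_are_traction_free(self, params_combined):
        for proto in mm.standard_protocols():
            _, _, P = mm.equilibrium_solve(proto, 0.4, params_combined)
            scale = np.max(np.abs(P))
            assert abs(P[0, 0]) < 1e-6 * scale
            if proto.family == "axial":
                assert abs(P[1, 1]) < 1e-6 * scale
            if proto.configuration == "45":
                assert abs(P[0, 2]) < 1e-6 * scale

    def test_unconfined_incompressible_lateral_spread(self, params_combined):
        # near the incompressible limit both lateral stretches tend to
        # 1/sqrt(1 - eps)
        p = params_combined.replace(kvol_multiplier=50000.0)
        dofs, _, _ = mm.equilibrium_solve(mm.axial("0"), 0.4, p)
        np.testing.assert_allclose(dofs, 1.0 / np.sqrt(0.6), rtol=2e-4)

    def test_axial_0_and_90_coincide_when_isotropic(self):
        p = mm.MaterialParameters(c1=0.39, c2=0.0, c3=1.27)
        c0 = mm.simulate_protocol(mm.axial("0"), p)
        c90 = mm.simulate_protocol(mm.axial("90"), p)
        np.testing.assert_allclose(c90.stress, c0.stress, rtol=1e-10, atol=1e-12)


class TestSimulatedCurves:
    def test_curves_start_at_zero_and_decrease(self, combined_curves):
        for curve in combined_curves.values():
            assert curve.stress[0] == 0.0
            assert np.all(np.diff(curve.stress) < 0.0)  # compression stiffens

    def test_near_incompressibility_semi_confined_matrix_modes(self, combined_curves):
        # fibre-compressed and fibre-neutral modes stay within the penalty
        # formulation's volume tolerance at the default multiplier
        for name in ("semiconfined_I", "semiconfined_III"):
            assert np.max(np.abs(combined_curves[name].extras["J"] - 1.0)) < 1e-3

    def test_semi_confined_mode_ordering(self, combined_curves):
        pI = np.abs(combined_curves["semiconfined_I"].stress[1:])
        pII = np.abs(combined_curves["semiconfined_II"].stress[1:])
        pIII = np.abs(combined_curves["semiconfined_III"].stress[1:])
        assert np.all(pI < pIII)
        assert np.all(pIII < pII)

    def test_axial_orientation_ordering(self, combined_curves):
        # stiffness grows with fibre angle: fibres perpendicular to loading
        # are stretched laterally and resist most
        p0 = abs(combined_curves["axial_0"].stress[-1])
        p45 = abs(combined_curves["axial_45"].stress[-1])
        p90 = abs(combined_curves["axial_90"].stress[-1])
        assert p0 < p45 < p90

    def test_fibre_neutral_mode_ignores_anisotropy_exponent(self, params_combined):
        proto = mm.semiconfined("III")
        c_lo = mm.simulate_protocol(proto, params_combined)
        c_hi = mm.simulate_protocol(proto, params_combined.replace(c2=5.3))
        np.testing.assert_array_equal(c_lo.stress, c_hi.stress)

    def test_isotropic_collapse_within_each_family(self):
        p = mm.MaterialParameters(c1=0.39, c2=0.0, c3=1.27)
        curves = {pr.name: mm.simulate_protocol(pr, p) for pr in mm.standard_protocols()}
        for family in (("axial_0", "axial_45", "axial_90"),
                       ("semiconfined_I", "semiconfined_II", "semiconfined_III")):
            ref = curves[family[0]].stress[-1]
            for name in family[1:]:
                assert curves[name].stress[-1] == pytest.approx(ref, rel=1e-3)

    def test_step_refinement_leaves_endpoint_unchanged(self, params_combined):
        proto = mm.semiconfined("II")
        c50 = mm.simulate_protocol(proto, params_combined)
        c100 = mm.simulate_protocol(proto.replace(n_steps=100), params_combined)
        assert c100.stress[-1] == pytest.approx(c50.stress[-1], rel=1e-3)


class TestClosedFormOracle:
    def test_zero_stress_at_unit_stretch(self, params_combined):
        for mode in ("I", "II", "III"):
            assert mm.closed_form_semiconfined(mode, 1.0, params_combined) == 0.0

    @pytest.mark.parametrize("mode", ["I", "II", "III"])
    def test_matches_path_energy_differentiation(self, mode, params_combined):
        # independent 1-D central-difference of psi along the incompressible
        # constrained path F = diag(1/lam, 1, lam)
        fibre = {"I": (0, 0, 1), "II": (1, 0, 0), "III": (0, 1, 0)}[mode]
        lam, h = 0.6, 1e-6

        def psi(l):
            return mm.strain_energy(np.diag([1.0 / l, 1.0, l]), fibre, params_combined)

        fd = (psi(lam + h) - psi(lam - h)) / (2.0 * h)
        cf = mm.closed_form_semiconfined(mode, lam, params_combined)
        assert cf == pytest.approx(fd, rel=1e-7)
        assert cf < 0.0  # compressive

    def test_fibre_compression_softens_relative_to_neutral(self, params_combined):
        pI = mm.closed_form_semiconfined("I", 0.6, params_combined)
        pIII = mm.closed_form_semiconfined("III", 0.6, params_combined)
        assert abs(pI) < abs(pIII)

    def test_domain_errors(self, params_combined):
        with pytest.raises(ValueError):
            mm.closed_form_semiconfined("I", -0.1, params_combined)
        with pytest.raises(ValueError):
            mm.closed_form_semiconfined("IV", 0.6, params_combined)

    def test_penalty_solver_approaches_closed_form(self, params_combined):
        # monotone approach with growing bulk multiplier (abridged sweep)
        cf = mm.closed_form_semiconfined("III", 0.6, params_combined)
        gaps = []
        for mult in (500.0, 5000.0):
            p = params_combined.replace(kvol_multiplier=mult)
            curve = mm.simulate_protocol(mm.semiconfined("III"), p)
            gaps.append(abs(curve.stress[-1] - cf) / abs(cf))
        assert gaps[1] < gaps[0]
        assert gaps[1] < 5e-3
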