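"""The core-annulus solution: radii, velocity profile, apparent viscosity."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fleffect import (
    ContinuumValidityWarning,
    ModelParams,
    annulus_viscosity,
    apparent_relative_viscosity,
    apparent_viscosity_poiseuille_oracle,
    core_radius_closed_form,
    core_radius_numeric,
    inlet_core_radius,
    predict_vessel,
    velocity_profile,
    viscosity_curve,
)

valid_triples = st.tuples(
    st.floats(min_value=0.05, max_value=0.999),  # s0
    st.floats(min_value=1.01, max_value=10.0),   # eta_c
    st.floats(min_value=0.0, max_value=1.0),     # alpha
)


class TestInletRadius:
    def test_size_exclusion_arithmetic(self):
        assert inlet_core_radius(30.0, 1.2) == pytest.approx(0.92, rel=1e-15)

    def test_no_exclusion_layer(self):
        assert inlet_core_radius(100.0, 0.0) == 1.0

    def test_degenerate_vessel_rejected(self):
        with pytest.raises(ValueError):
            inlet_core_radius(2.4, 1.2)
        with pytest.raises(ValueError):
            inlet_core_radius(2.0, 1.2)


class TestAnnulusViscosity:
    def test_haynes_cell_free_layer(self):
        assert annulus_viscosity(3.3, 0.0) == 1.0

    def test_homogeneous_suspension(self):
        assert annulus_viscosity(3.3, 1.0) == 3.3

    def test_linear_interpolation(self):
        assert annulus_viscosity(3.3, 0.1) == pytest.approx(1.23, rel=1e-15)

    def test_guards(self):
        with pytest.raises(ValueError):
            annulus_viscosity(0.9, 0.1)
        with pytest.raises(ValueError):
            annulus_viscosity(3.3, 1.5)


class TestCoreRadius:
    def test_full_core_limit(self):
        assert core_radius_closed_form(1.0, 2.0, 1.1) == 1.0
        assert core_radius_numeric(1.0, 2.0, 1.1) == 1.0

    def test_homogeneous_reduction(self):
        # eta_A = eta_c collapses the inner radicand to 1 - s0^2
        s0 = 0.9
        expected = s0 / math.sqrt(1.0 + math.sqrt(1.0 - s0**2))
        assert core_radius_closed_form(s0, 2.5, 2.5) == pytest.approx(
            expected, rel=1e-14
        )

    def test_worked_example_against_bisection(self):
        closed = core_radius_closed_form(0.92, 2.05, 1.105)
        numeric = core_radius_numeric(0.92, 2.05, 1.105)
        assert abs(closed - numeric) < 1e-10
        assert round(closed, 5) == 0.80502

    @settings(max_examples=300, derandomize=True)
    @given(triple=valid_triples)
    def test_closed_form_matches_quartic_root(self, triple):
        s0, eta_c, alpha = triple
        eta_A = annulus_viscosity(eta_c, alpha)
        closed = core_radius_closed_form(s0, eta_c, eta_A)
        numeric = core_radius_numeric(s0, eta_c, eta_A)
        assert abs(closed - numeric) < 1e-10
        assert 0.0 < closed <= s0

    def test_guards(self):
        with pytest.raises(ValueError):
            core_radius_closed_form(0.0, 2.0, 1.1)
        with pytest.raises(ValueError):
            core_radius_closed_form(0.5, 2.0, 2.5)  # eta_A > eta_c


class TestVelocityProfile:
    def test_no_slip_at_wall(self):
        vp = velocity_profile(0.7, 3.3, 1.23)
        assert vp(1.0) == 0.0

    def test_continuous_at_core_boundary(self):
        vp = velocity_profile(0.7, 3.3, 1.23)
        eps = 1e-12
        assert vp(0.7 - eps) == pytest.approx(vp(0.7 + eps), rel=1e-9)

    def test_strictly_decreasing(self):
        vp = velocity_profile(0.6, 2.0, 1.2)
        r = np.linspace(0.0, 1.0, 500)
        v = vp(r)
        assert np.all(np.diff(v) < 0)

    def test_homogeneous_limit_is_poiseuille(self):
        vp = velocity_profile(0.5, 2.0, 2.0)
        r = np.linspace(0.0, 1.0, 50)
        assert np.allclose(vp(r), 2.0 * (1.0 - r**2), rtol=1e-13, atol=1e-13)

    def test_flux_normalization_and_core_flux(self):
        # when s_inf solves the mass-conservation quartic, the profile
        # carries unit mean speed and the core carries the inlet plug flux
        s0, eta_c, alpha = 0.92, 2.05, 0.1
        eta_A = annulus_viscosity(eta_c, alpha)
        s_inf = core_radius_closed_form(s0, eta_c, eta_A)
        vp = velocity_profile(s_inf, eta_c, eta_A)
        total = 2.0 * quad(lambda r: vp(r) * r, 0.0, 1.0,
                           points=[s_inf], epsabs=1e-13)[0]
        core = 2.0 * quad(lambda r: vp(r) * r, 0.0, s_inf, epsabs=1e-13)[0]
        assert total == pytest.approx(1.0, abs=1e-9)
        assert core == pytest.approx(s0**2, abs=1e-9)

    def test_rejects_radius_outside_unit_interval(self):
        vp = velocity_profile(0.5, 2.0, 1.1)
        with pytest.raises(ValueError):
            vp(1.5)
        with pytest.raises(ValueError):
            vp(-0.1)


class TestApparentViscosity:
    def test_degenerate_limits(self):
        assert apparent_relative_viscosity(1.0, 3.3, 1.23) == pytest.approx(3.3)
        assert apparent_relative_viscosity(0.0, 3.3, 1.23) == pytest.approx(1.23)

    def test_strictly_between_annulus_and_core(self):
        eta = apparent_relative_viscosity(0.7, 3.3, 1.23)
        assert 1.23 < eta < 3.3

    @pytest.mark.parametrize(
        "s_inf, eta_c, eta_A",
        [(0.8050206540230587, 2.05, 1.105), (0.5, 3.3, 1.23), (0.95, 6.4, 1.54)],
    )
    def test_matches_first_principles_oracle(self, s_inf, eta_c, eta_A):
        closed = apparent_relative_viscosity(s_inf, eta_c, eta_A)
        oracle = apparent_viscosity_poiseuille_oracle(s_inf, eta_c, eta_A)
        assert abs(closed - oracle) / closed < 1e-8

    def test_oracle_recovers_homogeneous_fluid(self):
        for s_inf in [0.2, 0.6, 0.9]:
            assert apparent_viscosity_poiseuille_oracle(
                s_inf, 2.5, 2.5
            ) == pytest.approx(2.5, rel=1e-9)

    def test_worked_example(self):
        assert apparent_relative_viscosity(
            0.8050206540230587, 2.05, 1.105
        ) == pytest.approx(1.3703, abs=1e-4)


class TestPredictVessel:
    def test_solution_chain_consistency(self, human_params):
        sol = predict_vessel(100.0, human_params)
        assert 0.0 < sol.s_inf < sol.s0 < 1.0
        assert 1.0 <= sol.eta_A < sol.eta_app < human_params.eta_c
        assert sol.layer_thickness_um == pytest.approx(
            50.0 * (1.0 - sol.s_inf), rel=1e-14
        )
        # the asymptotic layer is thicker than the inlet exclusion gap
        assert sol.layer_thickness_um > human_params.a_star_um

    def test_narrow_tube_thickness_example(self):
        # 30 μm tube, dilute suspension (bulk viscosity from hematocrit 0.08)
        params = ModelParams(eta_c=1.18, alpha=0.1, a_star_um=1.2)
        with pytest.warns(ContinuumValidityWarning):
            sol = predict_vessel(29.99, params)
        assert sol.layer_thickness_um == pytest.approx(3.2, abs=0.05)

    def test_continuum_warning_only_below_threshold(self, human_params):
        with pytest.warns(ContinuumValidityWarning):
            predict_vessel(20.0, human_params)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            predict_vessel(100.0, human_params)

    def test_homogeneous_alpha_one_collapses(self):
        params = ModelParams(eta_c=3.3, alpha=1.0, a_star_um=1.2)
        for d in [10.0, 50.0, 400.0]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ContinuumValidityWarning)
                sol = predict_vessel(d, params)
            assert sol.eta_app == pytest.approx(3.3, rel=1e-14)

    def test_large_vessel_limit_recovers_bulk_viscosity(self, human_params):
        # convergence is O(sqrt(a*/D)): slow, but monotone towards eta_c
        gaps = []
        for d in [1e4, 1e6, 1e8, 1e10]:
            sol = predict_vessel(d, human_params)
            gaps.append(human_params.eta_c - sol.eta_app)
        assert all(g > 0 for g in gaps)
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 1e-3

    def test_dimensional_output(self):
        params = ModelParams(eta_c=3.3, alpha=0.1, a_star_um=1.2, eta_p_mPas=1.2)
        sol = predict_vessel(100.0, params)
        assert sol.eta_app_mPas == pytest.approx(1.2 * sol.eta_app, rel=1e-14)

    def test_degenerate_geometry_rejected(self, human_params):
        with pytest.raises(ValueError):
            predict_vessel(2.0, human_params)


class TestViscosityCurve:
    def test_single_point_matches_predict(self, human_params):
        df = viscosity_curve([120.0], human_params)
        sol = predict_vessel(120.0, human_params)
        assert df.loc[0, "eta_app_rel"] == pytest.approx(sol.eta_app, rel=1e-15)
        assert df.loc[0, "layer_thickness_um"] == pytest.approx(
            sol.layer_thickness_um, rel=1e-15
        )

    def test_order_preserved(self, human_params):
        fwd = viscosity_curve([50.0, 100.0, 200.0], human_params)
        rev = viscosity_curve([200.0, 100.0, 50.0], human_params)
        assert list(rev["diameter_um"]) == [200.0, 100.0, 50.0]
        assert np.allclose(
            fwd["eta_app_rel"].to_numpy()[::-1], rev["eta_app_rel"].to_numpy()
        )

    def test_monotone_in_diameter(self, human_params):
        df = viscosity_curve(np.geomspace(31.0, 1000.0, 60), human_params)
        assert np.all(np.diff(df["eta_app_rel"]) > 0)
        assert np.all(np.diff(df["layer_thickness_um"]) > 0)

    def test_reference_configuration_curves(self):
        # bulk viscosity 3.3, a* = 1.2 μm, marginal fractions 0.05/0.1/0.15:
        # three monotone curves approaching the bulk value from below
        grid = np.geomspace(10.0, 1000.0, 40)
        last = None
        for alpha in (0.05, 0.1, 0.15):
            params = ModelParams(eta_c=3.3, alpha=alpha, a_star_um=1.2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ContinuumValidityWarning)
                df = viscosity_curve(grid, params)
            eta = df["eta_app_rel"].to_numpy()
            assert np.all(np.diff(eta) > 0)
            assert np.all(eta < 3.3)
            # approach to the bulk value is O(sqrt(a*/D)): check far out
            far = predict_vessel(1e6, params).eta_app
            assert 3.2 < far < 3.3
            if last is not None:  # larger alpha -> more viscous marginal layer
                assert np.all(eta > last)
            last = eta

    def test_thickness_decreases_with_core_viscosity(self):
        # at fixed D, alpha, a*: a more viscous core pulls in less fluid
        thicknesses = []
        for eta_c in (1.2, 1.6, 2.0, 3.0, 5.0):
            params = ModelParams(eta_c=eta_c, alpha=0.1, a_star_um=1.2)
            sol = predict_vessel(60.0, params)
            thicknesses.append(sol.layer_thickness_um)
        assert thicknesses == sorted(thicknesses, reverse=True)

    def test_invalid_diameter_reports_index(self, human_params):
        with pytest.raises(ValueError, match="index 1"):
            viscosity_curve([50.0, 2.0, 100.0], human_params)
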