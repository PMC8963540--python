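import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedlab.errors import DomainError, FitError, StateError
from sedlab.physics import (
    CONSTANTS,
    PhysicalConstants,
    Medium,
    SeawaterDensityModel,
    SphereGeometry,
    absolute_salinity,
    excess_density_from_velocity,
    fit_seawater_density_model,
    radius_from_perimeter,
    stokes_velocity,
    volume_from_radius,
)


class TestConstants:
    def test_defaults(self):
        assert CONSTANTS.dynamic_viscosity == 0.00109
        assert CONSTANTS.gravitational_acceleration == 9.780
        assert CONSTANTS.salinity_constant == 35.16504 / 35

    def test_prefactor_exact(self):
        assert CONSTANTS.stokes_prefactor == 2 * 9.780 / (9 * 0.00109)

    @pytest.mark.parametrize("kwargs", [{"dynamic_viscosity": 0}, {"gravitational_acceleration": -1}])
    def test_invalid_constants(self, kwargs):
        with pytest.raises(DomainError):
            PhysicalConstants(**kwargs)


class TestGeometry:
    def test_radius_identity(self):
        assert radius_from_perimeter(2 * np.pi) == pytest.approx(1.0)

    def test_radius_micron_scale(self):
        # 62.83 um perimeter -> 10 um radius (hand evaluation of P/(2*pi))
        assert radius_from_perimeter(6.2832e-5) == pytest.approx(1.0000e-5, rel=1e-4)

    def test_radius_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            radius_from_perimeter(0)

    def test_volume_unit_radius(self):
        assert volume_from_radius(1.0) == pytest.approx(4 * np.pi / 3)

    def test_volume_cubic_scaling(self):
        assert volume_from_radius(2.0) == pytest.approx(8 * volume_from_radius(1.0))

    def test_volume_micron_scale(self):
        assert volume_from_radius(1.0e-5) == pytest.approx(4.18879e-15, rel=1e-5)

    def test_volume_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            volume_from_radius(-1.0)

    @given(st.floats(min_value=1e-6, max_value=1e3))
    def test_geometry_consistency(self, perimeter):
        # V(R(P)) = P^3 / (6 pi^2)
        v = volume_from_radius(radius_from_perimeter(perimeter))
        assert v == pytest.approx(perimeter**3 / (6 * np.pi**2), rel=1e-12)

    def test_sphere_geometry_dataclass(self):
        geo = SphereGeometry(perimeter=2 * np.pi)
        assert geo.radius == pytest.approx(1.0)
        assert geo.volume == pytest.approx(4 * np.pi / 3)


class TestStokes:
    def test_neutral_buoyancy(self):
        assert stokes_velocity(0.0, 1e-5) == 0.0

    def test_hand_computed_value(self):
        # 2 * 9.780 * (25e-6)^2 * 78 / (9 * 0.00109) evaluated by hand
        assert stokes_velocity(78.0, 25e-6) == pytest.approx(9.7202e-5, rel=1e-4)

    def test_quadratic_in_radius(self):
        assert stokes_velocity(50.0, 2e-5) == pytest.approx(4 * stokes_velocity(50.0, 1e-5))

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(DomainError):
            stokes_velocity(10.0, 0.0)

    def test_inverse_at_zero_velocity(self):
        inv = excess_density_from_velocity(0.0, 1e-5, 1028.9)
        assert inv.particle_density == pytest.approx(1028.9)
        assert inv.excess_density == pytest.approx(28.9)

    @settings(max_examples=200)
    @given(
        drho=st.floats(min_value=-500, max_value=1500),
        radius=st.floats(min_value=1e-7, max_value=1e-2),
        pf=st.floats(min_value=1000, max_value=1060),
    )
    def test_roundtrip_property(self, drho, radius, pf):
        v = stokes_velocity(drho, radius)
        inv = excess_density_from_velocity(v, radius, pf)
        assert inv.particle_density == pytest.approx(pf + drho, rel=1e-12, abs=1e-9)

    def test_roundtrip_bulk(self):
        rng = np.random.default_rng(0)
        drho = rng.uniform(-300, 1300, 1000)
        radius = np.exp(rng.uniform(np.log(1e-7), np.log(1e-3), 1000))
        pf = rng.uniform(1010, 1040, 1000)
        v = stokes_velocity(drho, radius)
        inv = excess_density_from_velocity(v, radius, pf)
        np.testing.assert_allclose(inv.particle_density, pf + drho, rtol=1e-12)

    def test_monotone_in_density_and_radius(self):
        v = stokes_velocity(np.array([10.0, 20.0, 30.0]), 1e-5)
        assert np.all(np.diff(v) > 0)
        v = stokes_velocity(50.0, np.array([1e-6, 2e-6, 4e-6]))
        assert np.all(np.diff(v) > 0)


class TestSalinity:
    def test_zero(self):
        assert absolute_salinity(0.0) == 0.0

    def test_reference_point(self):
        assert absolute_salinity(35.0) == pytest.approx(35.16504)

    def test_assay_formulation(self):
        # 37.4 * 35.16504/35 by hand
        assert absolute_salinity(37.4) == pytest.approx(37.576, abs=5e-4)

    def test_rejects_negative(self):
        with pytest.raises(DomainError):
            absolute_salinity(-1.0)


class TestMedium:
    def test_density_bounds(self):
        with pytest.raises(DomainError):
            Medium(salinity=35.0, temperature=17.0, density=1200.0)
        Medium(salinity=35.0, temperature=17.0, density=1028.9)  # ok

    def test_negative_salinity(self):
        with pytest.raises(DomainError):
            Medium(salinity=-2.0, temperature=17.0)


class TestSeawaterModel:
    def test_exact_quadratic_recovered(self):
        coef = np.array([1000.0, 0.8, -0.1, 1e-3, -2e-3, 5e-4])
        s, t = np.meshgrid(np.linspace(5, 40, 6), np.linspace(0, 30, 6))
        s, t = s.ravel(), t.ravel()
        dens = coef[0] + coef[1] * s + coef[2] * t + coef[3] * s**2 + coef[4] * t**2 + coef[5] * s * t
        model = fit_seawater_density_model(np.column_stack([t, s, dens]))
        assert model.fit_residual_max < 1e-9
        np.testing.assert_allclose(model.coefficients, coef, rtol=1e-8)

    def test_synthetic_reference_residual(self, seawater_table, seawater_model):
        # noise sd 1e-3 -> max residual well under the 4e-3 kg/m^3 bound
        assert seawater_model.fit_residual_max < 4e-3

    def test_prediction_matches_training_rows(self, seawater_table, seawater_model):
        df, _ = seawater_table
        pred = seawater_model.predict(df["salinity"].to_numpy(), df["temp_C"].to_numpy())
        assert np.max(np.abs(pred - df["density"].to_numpy())) <= seawater_model.fit_residual_max + 1e-12

    def test_monotone_in_salinity(self, seawater_model):
        sal = np.linspace(5, 70, 100)
        dens = seawater_model.predict(sal, np.full_like(sal, 17.0))
        assert np.all(np.diff(dens) > 0)

    def test_coefficients_stable_under_reordering(self, seawater_table):
        df, _ = seawater_table
        rows = np.column_stack([df["temp_C"], df["salinity"], df["density"]])
        m1 = fit_seawater_density_model(rows)
        rng = np.random.default_rng(5)
        m2 = fit_seawater_density_model(rows[rng.permutation(len(rows))])
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, rtol=1e-6)

    def test_collinear_rows_rejected(self):
        rows = [(10.0, s, 1000 + s) for s in [5.0, 5.0, 5.0, 5.0, 5.0]]
        with pytest.raises(FitError):
            fit_seawater_density_model(rows)

    def test_too_few_rows_rejected(self):
        with pytest.raises(FitError):
            fit_seawater_density_model([(10, 5, 1004), (20, 6, 1005), (30, 7, 1006)])

    def test_unfitted_predict_raises(self):
        with pytest.raises(StateError):
            SeawaterDensityModel().predict(35.0, 17.0)

    def test_extrapolation_warns(self, seawater_model):
        with pytest.warns(UserWarning, match="training range"):
            seawater_model.predict(200.0, 17.0)
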