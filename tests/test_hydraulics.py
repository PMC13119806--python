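import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafstress.hydraulics import (
    MassLossSeries,
    PVCurve,
    VesselAnatomy,
    detect_epidermal_phase,
    epidermal_conductance,
    equivalent_radius,
    fit_pv_parameters,
    leaf_kmax,
    relative_water_content,
    single_vessel_conductivity,
    water_viscosity,
)
from leafstress.synthetic import (
    PVGenParams,
    generate_mass_loss_series,
    generate_pv_curve,
    generate_vessel_anatomy,
)


class TestVesselGeometry:
    def test_equivalent_radius_values(self):
        assert equivalent_radius(math.pi) == pytest.approx(1.0)
        assert equivalent_radius(100.0) == pytest.approx(5.6419, abs=1e-4)

    @settings(derandomize=True, max_examples=30)
    @given(a=st.floats(1.0, 1e4), b=st.floats(1.0, 1e4))
    def test_radius_monotone_in_area(self, a, b):
        if a < b:
            assert equivalent_radius(a) < equivalent_radius(b)

    def test_viscosity_correlation_anchors(self):
        # literature anchors: 1.002 mPa s at 20 C, 0.890 mPa s at 25 C
        assert water_viscosity(20.0) == pytest.approx(1.002e-3, rel=2e-3)
        assert water_viscosity(25.0) == pytest.approx(0.890e-3, rel=3e-3)

    def test_single_vessel_hand_value(self):
        # pi*(6e-6)^4 / (8 * 1.002e-3 * 0.02) = 2.5396e-17 m^3/s/Pa
        ki = single_vessel_conductivity(6e-6, 1.002e-3, 0.02)
        assert ki == pytest.approx(2.5396e-17, rel=1e-4)
        assert single_vessel_conductivity(0.0, 1.002e-3, 0.02) == 0.0
        # quartic law
        assert single_vessel_conductivity(1.2e-5, 1.002e-3, 0.02) == pytest.approx(16 * ki)


class TestLeafKmax:
    def hand_kmax(self, n, radius_m, big_n, area, length, eta):
        ki = math.pi * radius_m**4 / (8 * eta * length)
        return (big_n / n) * n * ki / area / 1.8e-5 * 1e9

    def test_identical_vessel_hand_oracle(self):
        # 50 vessels of 6 um equivalent radius, A = 0.003 m^2, l = 0.02 m,
        # water at 20 C: hand evaluation with eta = 1.002e-3 gives 23.52
        anatomy = VesselAnatomy(
            vessel_areas=np.full(50, math.pi * 36.0),
            n_total=50,
            leaf_area=0.003,
            petiole_length=0.02,
            water_temperature=20.0,
        )
        expected = self.hand_kmax(50, 6e-6, 50, 0.003, 0.02, 1.002e-3)
        assert expected == pytest.approx(23.515, abs=0.001)
        assert leaf_kmax(anatomy) == pytest.approx(expected, rel=1e-3)

    def test_total_count_scaling_and_area_inverse(self):
        areas = np.full(60, math.pi * 25.0)
        base = leaf_kmax(VesselAnatomy(areas, n_total=60, leaf_area=0.004))
        # raising the total count while counting the same subset scales Kmax
        # linearly (sampling stays at the 2/3 rule); doubling leaf area halves it
        scaled_n = leaf_kmax(VesselAnatomy(areas, n_total=90, leaf_area=0.004))
        assert scaled_n == pytest.approx(1.5 * base, rel=1e-12)
        halved = leaf_kmax(VesselAnatomy(areas, n_total=60, leaf_area=0.008))
        assert halved == pytest.approx(base / 2, rel=1e-12)

    def test_vessel_order_invariance_and_atrophy_monotonicity(self, rng):
        areas = rng.uniform(50.0, 200.0, size=40)
        k1 = leaf_kmax(VesselAnatomy(areas, n_total=40, leaf_area=0.004))
        k2 = leaf_kmax(VesselAnatomy(rng.permutation(areas), n_total=40, leaf_area=0.004))
        assert k1 == pytest.approx(k2, rel=1e-12)
        shrunk = leaf_kmax(VesselAnatomy(areas * 0.8, n_total=40, leaf_area=0.004))
        assert shrunk < k1

    def test_undersampled_vessel_count_warns(self):
        anatomy = VesselAnatomy(
            np.full(10, math.pi * 25.0), n_total=40, leaf_area=0.004
        )
        with pytest.warns(UserWarning, match="2/3"):
            leaf_kmax(anatomy)

    def test_default_synthetic_config_within_reported_span(self):
        kmax = leaf_kmax(generate_vessel_anatomy(seed=0))
        assert 9.7 <= kmax <= 22.5


class TestEpidermalConductance:
    def test_noiseless_two_phase_recovery_to_4_digits(self):
        series = generate_mass_loss_series(ge_true=231.0, noise_sd=0.0)
        phase = detect_epidermal_phase(series)
        # true tail slope = -231 * 0.01 * 20 / 2.31e6 = -2e-5 g/s
        assert phase.slope == pytest.approx(-2e-5, rel=1e-9)
        assert epidermal_conductance(series, phase) == pytest.approx(231.0, rel=1e-4)

    def test_hand_arithmetic(self):
        # |slope| 2e-5 g/s, A = 0.01 m^2, de = 20 -> ge = 231
        times = np.arange(0, 7) * 3000.0
        weights = 2.0 - 2e-5 * times
        series = MassLossSeries(times, weights, leaf_area=0.01, delta_e=20.0)
        assert epidermal_conductance(series) == pytest.approx(231.0, rel=1e-6)

    def test_flat_tail_gives_zero(self):
        # fully closed surface: constant weight implies zero conductance
        series = generate_mass_loss_series(ge_true=0.0, noise_sd=0.0)
        phase = detect_epidermal_phase(series)
        assert phase.slope == pytest.approx(0.0, abs=1e-15)
        assert epidermal_conductance(series, phase) == pytest.approx(0.0, abs=1e-9)

    def test_single_slope_series_degenerates_to_global_fit(self):
        times = np.arange(0, 10) * 3000.0
        weights = 2.0 - 3e-5 * times
        series = MassLossSeries(times, weights, leaf_area=0.01, delta_e=20.0)
        phase = detect_epidermal_phase(series)
        assert phase.slope == pytest.approx(-3e-5, rel=0.01)

    def test_area_homogeneity(self):
        s1 = generate_mass_loss_series(ge_true=200.0, leaf_area=0.01, noise_sd=0.0)
        ge1 = epidermal_conductance(s1)
        s2 = MassLossSeries(
            s1.times, s1.fresh_weights, leaf_area=0.02, delta_e=s1.delta_e
        )
        assert epidermal_conductance(s2) == pytest.approx(ge1 / 2, rel=1e-9)

    def test_noisy_recovery_within_5_percent(self):
        errors = []
        for seed in range(100):
            series = generate_mass_loss_series(ge_true=231.0, noise_sd=0.002, seed=seed)
            errors.append(abs(epidermal_conductance(series) - 231.0) / 231.0)
        assert np.median(errors) < 0.05

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            detect_epidermal_phase(
                MassLossSeries(
                    np.arange(4.0), np.array([2.0, 1.9, 1.8, 1.7]), 0.01, 20.0
                )
            )


class TestRWC:
    @pytest.mark.parametrize(
        "fresh, expected", [(2.0, 1.0), (1.0, 0.0), (1.8, 0.8)]
    )
    def test_values(self, fresh, expected):
        assert relative_water_content(fresh, 2.0, 1.0) == pytest.approx(expected)

    def test_bounds(self):
        with pytest.raises(ValueError):
            relative_water_content(1.0, 1.0, 1.0)
        with pytest.warns(UserWarning):
            assert relative_water_content(2.005, 2.0, 1.0) == 1.0
        with pytest.raises(ValueError):
            relative_water_content(2.5, 2.0, 1.0)


class TestPVCurves:
    def test_generator_saturation_limit(self):
        params = PVGenParams()
        assert params.water_potential(np.array([1.0]))[0] == pytest.approx(0.0)

    def test_closed_form_turgor_loss_point(self):
        params = PVGenParams(psi_sat=-1.2, apoplastic_fraction=0.15, rwc_tlp=0.90)
        # -1.2 * 0.85 / 0.75 = -1.36 MPa
        assert params.psi_tlp == pytest.approx(-1.36)

    def test_noiseless_round_trip(self):
        params = PVGenParams(psi_sat=-1.2, apoplastic_fraction=0.15, rwc_tlp=0.90)
        fit = fit_pv_parameters(generate_pv_curve(params, seed=1))
        assert fit.psi_sat == pytest.approx(params.psi_sat, rel=0.02)
        assert fit.rwc_tlp == pytest.approx(params.rwc_tlp, abs=0.02)
        assert fit.psi_tlp == pytest.approx(params.psi_tlp, rel=0.03)
        assert fit.apoplastic_fraction == pytest.approx(0.15, abs=0.02)

    def test_pure_osmometer_curve_accepts_all_points(self):
        # turgor identically zero: every observation lies on the osmotic line
        # turgor loss above the sampled range: every sampled point is osmotic
        params = PVGenParams(psi_sat=-1.5, apoplastic_fraction=0.10, rwc_tlp=0.99,
                             r_start=0.98)
        curve = generate_pv_curve(params, seed=2)
        fit = fit_pv_parameters(curve)
        assert fit.n_points_on_line == len(curve.observations)
        assert fit.rwc_tlp == pytest.approx(curve.rwc().max())

    def test_fit_invariants_on_noisy_curves(self):
        params = PVGenParams(noise_sd=0.02)
        for seed in range(20):
            try:
                fit = fit_pv_parameters(generate_pv_curve(params, seed=seed))
            except ValueError:
                continue
            assert fit.psi_tlp < fit.psi_sat < 0
            assert fit.apoplastic_fraction < fit.rwc_tlp

    def test_monte_carlo_recovery(self):
        params = PVGenParams(noise_sd=0.02)
        errs_sat, errs_rwc = [], []
        for seed in range(100):
            try:
                fit = fit_pv_parameters(generate_pv_curve(params, seed=seed))
            except ValueError:
                continue
            errs_sat.append(abs(fit.psi_sat - params.psi_sat))
            errs_rwc.append(abs(fit.rwc_tlp - params.rwc_tlp))
        assert len(errs_sat) >= 90
        assert np.median(errs_sat) < 0.05
        assert np.median(errs_rwc) < 0.02

    def test_invalid_curves_raise(self):
        with pytest.raises(ValueError, match="positive"):
            PVCurve(
                observations=np.array([[0.0, 1.9], [0.5, 1.8]]),
                saturated_weight=2.0,
                dry_weight=1.0,
            )
        # increasing weights violate the air-drying protocol
        with pytest.raises(ValueError):
            PVCurve(
                observations=np.array([[0.5, 1.8], [0.6, 1.9]]),
                saturated_weight=2.0,
                dry_weight=1.0,
            )
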