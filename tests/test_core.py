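"""Unit and property tests for the pairwise and population flux models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chlorosig import (
    CalibrationMeasurement,
    GeometryError,
    InvalidInputError,
    OpticalParams,
    PairwiseScene,
    PopulationScene,
    calibrate_per_cell_flux,
    contribution_radius,
    density_scan,
    fraction_within,
    pairwise_cfpfd,
    population_cfpf_closed_form,
    population_cfpf_numeric,
    population_cfpfd,
    predict_bulk_cfpfd,
)
from chlorosig.units import cells_per_ml_to_per_m3


class TestCalibration:
    def test_reference_measurement_recovers_per_cell_flux(self, reference_measurement):
        u = calibrate_per_cell_flux(reference_measurement)
        assert u == pytest.approx(9.07e-12, rel=5e-3)

    def test_zero_emission_gives_zero_flux(self, reference_measurement):
        meas = CalibrationMeasurement(0.0, reference_measurement.cell_density_n)
        assert calibrate_per_cell_flux(meas) == 0.0

    def test_flux_scales_inversely_with_density(self, reference_measurement):
        # brute-force arithmetic oracle: doubling N halves u
        doubled = CalibrationMeasurement(2.418e-2, cells_per_ml_to_per_m3(3.2e6))
        assert calibrate_per_cell_flux(doubled) == pytest.approx(4.534e-12, rel=1e-3)

    @pytest.mark.parametrize("kwargs", [
        {"measured_cfpfd": -1.0, "cell_density_n": 1e12},
        {"measured_cfpfd": 1.0, "cell_density_n": 0.0},
        {"measured_cfpfd": 1.0, "cell_density_n": 1e12, "sample_volume": 0.0},
    ])
    def test_invalid_measurements_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            CalibrationMeasurement(**kwargs)

    @given(cfpfd=st.floats(1e-6, 1e2), density_ml=st.floats(1e3, 1e9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_reproduces_measured_cfpfd(self, cfpfd, density_ml):
        meas = CalibrationMeasurement(cfpfd, cells_per_ml_to_per_m3(density_ml))
        u = calibrate_per_cell_flux(meas)
        assert predict_bulk_cfpfd(u, meas) == pytest.approx(cfpfd, rel=1e-12)


class TestPairwise:
    @pytest.mark.parametrize(
        "distance, expected, rel",
        [
            (6e-6, 1.00e-2, 1e-2),    # touching cells
            (1e-4, 3.61e-5, 5e-3),    # 100 μm separation
            (1e-5, 3.61e-3, 5e-3),    # inverse-square scaling from the 100 μm value
        ],
    )
    def test_printed_distances(self, params, distance, expected, rel):
        assert pairwise_cfpfd(PairwiseScene(distance, params)) == pytest.approx(expected, rel=rel)

    @pytest.mark.parametrize("distance", [0.0, 1e-7, 5.9e-6])
    def test_overlapping_cells_rejected(self, params, distance):
        with pytest.raises(GeometryError):
            PairwiseScene(distance, params)

    @given(distance=st.floats(6e-6, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_inverse_square_law(self, distance):
        # CFPFD·R² is constant over R
        params = OpticalParams()
        ref = pairwise_cfpfd(PairwiseScene(6e-6, params)) * (6e-6) ** 2
        value = pairwise_cfpfd(PairwiseScene(distance, params)) * distance**2
        assert value == pytest.approx(ref, rel=1e-12)


class TestPopulation:
    def test_closed_form_at_laboratory_density(self, params):
        # direct evaluation of N·u·πr²/Kd
        value = population_cfpf_closed_form(PopulationScene(1.6e12, params=params))
        assert value == pytest.approx(7.198e-10, rel=1e-3)

    def test_closed_form_zero_density(self, params):
        assert population_cfpf_closed_form(PopulationScene(0.0, params=params)) == 0.0

    def test_doubling_kd_halves_flux(self, params):
        base = population_cfpf_closed_form(PopulationScene(1e12, params=params))
        doubled = population_cfpf_closed_form(
            PopulationScene(1e12, params=params.with_(attenuation_kd=2 * params.attenuation_kd))
        )
        assert doubled == pytest.approx(base / 2, rel=1e-12)

    def test_closed_form_requires_infinite_truncation(self, params):
        with pytest.raises(InvalidInputError):
            population_cfpf_closed_form(PopulationScene(1e12, truncation_radius=5.0, params=params))

    def test_half_life_truncation(self, params):
        # Rmax = ln2/Kd captures exactly half the total
        scene = PopulationScene(1e12, math.log(2) / params.attenuation_kd, params)
        full = population_cfpf_closed_form(PopulationScene(1e12, params=params))
        assert population_cfpf_numeric(scene) == pytest.approx(full / 2, rel=1e-8)

    def test_quadrature_matches_closed_form(self, params):
        scene = PopulationScene(1.6e12, params=params)
        assert population_cfpf_numeric(scene) == pytest.approx(
            population_cfpf_closed_form(scene), rel=1e-6
        )

    def test_contribution_radius_truncation_captures_999(self, params):
        scene = PopulationScene(1e12, 12.119, params)
        full = population_cfpf_closed_form(PopulationScene(1e12, params=params))
        assert population_cfpf_numeric(scene) / full == pytest.approx(0.999, abs=1e-4)

    @pytest.mark.parametrize("rmax", [0.5, 2.0, 10.0])
    def test_truncated_ratio_is_survival_function(self, params, rmax):
        scene = PopulationScene(1e12, rmax, params)
        full = population_cfpf_closed_form(PopulationScene(1e12, params=params))
        expected = -math.expm1(-params.attenuation_kd * rmax)
        assert population_cfpf_numeric(scene) / full == pytest.approx(expected, rel=1e-6)

    def test_truncated_flux_increases_with_rmax(self, params):
        radii = [0.1, 1.0, 5.0, 20.0]
        values = [population_cfpf_numeric(PopulationScene(1e12, r, params)) for r in radii]
        full = population_cfpf_closed_form(PopulationScene(1e12, params=params))
        assert all(a < b for a, b in zip(values, values[1:]))
        assert all(v < full for v in values)


class TestPopulationCfpfd:
    def test_infinite_case_value(self, params):
        # N·u/(2Kd) at the laboratory density
        value = population_cfpfd(PopulationScene(1.6e12, params=params))
        assert value == pytest.approx(12.73, rel=1e-3)

    @pytest.mark.parametrize("r_um", [1.0, 3.0, 10.0])
    def test_plastid_radius_cancels(self, r_um):
        params = OpticalParams(plastid_radius_r=r_um * 1e-6)
        value = population_cfpfd(PopulationScene(1.6e12, params=params))
        expected = 1.6e12 * params.per_cell_flux_u / (2 * params.attenuation_kd)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_density_for_hundredth_flux_density(self, params):
        # inverting N·u/(2Kd) = 0.01 gives N ≈ 1.257e9 m⁻³
        value = population_cfpfd(PopulationScene(1.257e9, params=params))
        assert value == pytest.approx(0.01, rel=2e-3)


class TestContributionRadius:
    def test_999_percent_radius(self, params):
        radius = contribution_radius(params, 0.999)
        assert radius == pytest.approx(12.12, rel=1e-3)
        assert radius == pytest.approx(12.10, rel=1e-2)  # printed, rounded value

    def test_half_contribution_radius(self, params):
        assert contribution_radius(params, 0.5) == pytest.approx(math.log(2) / 0.57, rel=1e-12)

    def test_small_fraction_limit(self, params):
        assert contribution_radius(params, 1e-9) < 1e-8

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.5, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, params, fraction):
        with pytest.raises(InvalidInputError):
            contribution_radius(params, fraction)

    @given(fraction=st.floats(1e-6, 1 - 1e-9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_inverse_of_enclosed_fraction(self, fraction):
        params = OpticalParams()
        assert fraction_within(params, contribution_radius(params, fraction)) == pytest.approx(
            fraction, rel=1e-9
        )


class TestDensityScan:
    def test_zero_density_row(self, params):
        table = density_scan(params, [0.0])
        assert table["cfpfd"].tolist() == [0.0]

    def test_bloom_density_range(self, params):
        # 10⁶–3×10⁸ cells/L is the bloom range: CFPFD ≈ 0.008 → 2.39
        table = density_scan(params, [1e9, 3e11])
        assert table["cfpfd"].iloc[0] == pytest.approx(0.00796, rel=1e-2)
        assert table["cfpfd"].iloc[1] == pytest.approx(2.39, rel=1e-2)

    def test_linearity_in_density(self, params):
        dens = np.array([1e9, 1e10, 1e11])
        base = density_scan(params, dens)
        doubled = density_scan(params, 2 * dens)
        assert np.allclose(doubled["cfpfd"], 2 * base["cfpfd"], rtol=1e-12)

    def test_monotone_in_density(self, params):
        table = density_scan(params, [1e6, 1e9, 1e12, 1e15])
        assert table["cfpfd"].is_monotonic_increasing

    def test_negative_density_rejected(self, params):
        with pytest.raises(InvalidInputError):
            density_scan(params, [-1.0])


def test_optical_params_must_be_positive():
    for kwargs in ({"plastid_radius_r": 0.0}, {"attenuation_kd": -1.0}, {"per_cell_flux_u": 0.0}):
        with pytest.raises(InvalidInputError):
            OpticalParams(**kwargs)
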