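"""Elastic energies, force–composition fits, and mechanics calibrations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extrumech.errors import (ConfigurationError, DomainError, ExtrapolationError,
                              RankDeficiencyError)
from extrumech.mechanics import (CurvatureState, ElasticParameters, StretchState,
                                 bending_energy_density, calibrate_mechanics,
                                 estimate_bending_rigidity, estimate_tensile_strength,
                                 fit_force_vs_composition, joules_to_kbt,
                                 sphere_bending_energy, stretching_energy)
from extrumech.traces import ForceDecomposition


def decomp(f1, f6):
    return ForceDecomposition(f1, f6, f1 - f6, convergence_cycle=6)


class TestStretchingEnergy:
    def test_relaxed_membrane_has_zero_energy(self):
        assert stretching_energy(0.24, StretchState(1e-12, 1e-12)) == 0.0

    def test_two_percent_strain_worked_example(self):
        # K_A = 240 mN/m, strain 0.02 -> 0.048 mN/m
        e = stretching_energy(0.240, StretchState(1.0, 1.02))
        assert e == pytest.approx(0.048e-3)

    def test_quadratic_in_strain(self):
        e1 = stretching_energy(0.24, StretchState(1.0, 1.01))
        e2 = stretching_energy(0.24, StretchState(1.0, 1.02))
        assert e2 == pytest.approx(4.0 * e1)

    @given(strain=st.floats(1e-3, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_about_relaxed_area(self, strain):
        a0 = 1.0
        up = stretching_energy(0.24, StretchState(a0, a0 * (1 + strain)))
        down = stretching_energy(0.24, StretchState(a0, a0 * (1 - strain)))
        assert up == pytest.approx(down, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            StretchState(0.0, 1.0)
        with pytest.raises(DomainError):
            stretching_energy(-1.0, StretchState(1.0, 1.0))


class TestBendingEnergy:
    def test_flat_membrane_zero(self):
        p = ElasticParameters(1e-19)
        assert bending_energy_density(p, CurvatureState(0.0, 0.0)) == 0.0

    def test_sphere_density(self):
        p = ElasticParameters(1e-19, gaussian_modulus_J=0.0)
        r = 50e-9
        expected = 2.0 * p.bending_rigidity_J / r ** 2
        assert bending_energy_density(p, CurvatureState(1 / r, 1 / r)) == pytest.approx(expected)

    def test_saddle_picks_out_gaussian_term(self):
        p = ElasticParameters(1e-19, gaussian_modulus_J=-0.5e-19)
        c = 1e7
        assert bending_energy_density(p, CurvatureState(c, -c)) == pytest.approx(
            -p.gaussian_modulus_J * c * c)

    def test_sphere_energy_scale_invariant(self):
        p = ElasticParameters(1e-19, gaussian_modulus_J=-0.3e-19)
        expected = 8 * math.pi * p.bending_rigidity_J + 4 * math.pi * p.gaussian_modulus_J
        for r in (25e-9, 100e-9, 1e-6):
            assert sphere_bending_energy(p, r) == pytest.approx(expected, rel=1e-12)

    def test_unit_rigidity_gives_eight_pi(self):
        assert sphere_bending_energy(ElasticParameters(1.0), 1.0) == pytest.approx(8 * math.pi)

    def test_spontaneous_curvature_matching_sphere(self):
        r = 80e-9
        p = ElasticParameters(1e-19, gaussian_modulus_J=0.7e-19,
                              spontaneous_curvature_per_m=2.0 / r)
        assert sphere_bending_energy(p, r) == pytest.approx(4 * math.pi * p.gaussian_modulus_J)

    def test_kbt_conversion(self):
        assert joules_to_kbt(1.380649e-23 * 298.15) == pytest.approx(1.0)


class TestForceCompositionFit:
    def test_exact_line_recovered(self):
        pts = [(x, 3.0 * x + 1.0) for x in (0.0, 0.1, 0.2, 0.3)]
        fit = fit_force_vs_composition(pts)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_slope_within_standard_errors(self, rng):
        true_slope = 20.0
        x = np.linspace(0.0, 0.4, 12)
        recovered = 0
        for _ in range(50):
            y = true_slope * x + 5.0 + rng.normal(0, 0.5, x.size)
            fit = fit_force_vs_composition(list(zip(x, y)))
            if abs(fit.slope - true_slope) <= 3.0 * fit.slope_se:
                recovered += 1
        assert recovered >= 47  # 3 SE covers ~99.7% per replicate

    def test_constant_response(self):
        fit = fit_force_vs_composition([(0.0, 5.0), (0.1, 5.0), (0.2, 5.0)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(RankDeficiencyError):
            fit_force_vs_composition([(0.1, 1.0), (0.1, 2.0), (0.1, 3.0)])


class TestCalibration:
    def test_two_anchors_interpolate_exactly(self):
        cal = calibrate_mechanics([(5.0, 20.0), (10.0, 40.0)], target="bending_rigidity")
        assert cal.fit.r_squared == pytest.approx(1.0)
        value, se = estimate_bending_rigidity(5.0, cal)
        assert value == pytest.approx(20.0)
        value, _ = estimate_bending_rigidity(10.0, cal)
        assert value == pytest.approx(40.0)

    def test_midpoint_interpolation_closed_form(self):
        cal = calibrate_mechanics([(5.0, 20.0), (10.0, 40.0)], target="bending_rigidity")
        value, _ = estimate_bending_rigidity(7.5, cal)
        assert value == pytest.approx(30.0)

    def test_noisy_anchor_recovery(self, rng):
        x = np.linspace(4.0, 12.0, 20)
        y = 3.5 * x + 2.0 + rng.normal(0, 0.2, x.size)
        cal = calibrate_mechanics(list(zip(x, y)), target="bending_rigidity")
        assert abs(cal.fit.slope - 3.5) <= 3.0 * cal.fit.slope_se

    def test_extrapolation_refused_then_overridable(self):
        cal = calibrate_mechanics([(5.0, 20.0), (10.0, 40.0)], target="bending_rigidity")
        with pytest.raises(ExtrapolationError):
            estimate_bending_rigidity(15.0, cal)
        value, _ = estimate_bending_rigidity(15.0, cal, allow_extrapolation=True)
        assert value == pytest.approx(60.0)

    def test_target_mode_contracts(self):
        cal_kb = calibrate_mechanics([(5.0, 20.0), (10.0, 40.0)], target="bending_rigidity")
        with pytest.raises(ConfigurationError):
            estimate_tensile_strength(decomp(16.4, 6.7), cal_kb)
        with pytest.raises(ConfigurationError):
            calibrate_mechanics([(5.0, 1.0), (10.0, 2.0)], target="tensile_strength",
                                mode="stabilized")
        cal_s = calibrate_mechanics([(5.0, 1.0), (20.0, 4.0)], target="tensile_strength",
                                    mode="first_cycle")
        with pytest.raises(ConfigurationError):
            estimate_tensile_strength(decomp(16.4, 6.7), cal_s, mode="difference")

    def test_rank_deficient_anchors_rejected(self):
        with pytest.raises(RankDeficiencyError):
            calibrate_mechanics([(5.0, 20.0)], target="bending_rigidity")
        with pytest.raises(RankDeficiencyError):
            calibrate_mechanics([(5.0, 20.0), (5.0, 30.0)], target="bending_rigidity")


def test_anchor_template_reader(tmp_path):
    from pathlib import Path

    from extrumech.mechanics import read_calibration_anchors

    template = Path(__file__).resolve().parents[1] / "examples" / "calibration_anchors_template.csv"
    anchors = read_calibration_anchors(template, "bending_rigidity")
    assert len(anchors) == 2
    cal = calibrate_mechanics(anchors, target="bending_rigidity")
    assert cal.fit.r_squared == pytest.approx(1.0)


class TestTensileStrength:
    def test_identity_calibration_difference_mode(self):
        cal = calibrate_mechanics([(0.0, 0.0), (20.0, 20.0)], target="tensile_strength",
                                  mode="difference")
        out = estimate_tensile_strength(decomp(16.4, 6.7), cal, mode="difference")
        assert out["value"] == pytest.approx(9.7)
        assert out["caveat_anomalous_trend"] is True

    def test_first_cycle_mode_maps_f1(self):
        cal = calibrate_mechanics([(0.0, 0.0), (20.0, 20.0)], target="tensile_strength",
                                  mode="first_cycle")
        out = estimate_tensile_strength(decomp(16.4, 6.7), cal, mode="first_cycle")
        assert out["value"] == pytest.approx(16.4)
        assert out["caveat_anomalous_trend"] is False

    def test_modes_use_distinct_calibrations(self):
        d = decomp(16.4, 6.7)
        cal_f1 = calibrate_mechanics([(10.0, 2.0), (20.0, 6.0)], target="tensile_strength",
                                     mode="first_cycle")
        cal_diff = calibrate_mechanics([(5.0, 1.0), (12.0, 5.0)], target="tensile_strength",
                                       mode="difference")
        v1 = estimate_tensile_strength(d, cal_f1, mode="first_cycle")["value"]
        v2 = estimate_tensile_strength(d, cal_diff, mode="difference")["value"]
        assert v1 == pytest.approx(2.0 + 4.0 / 10.0 * 6.4)
        assert v2 == pytest.approx(1.0 + 4.0 / 7.0 * 4.7)
        assert v1 != pytest.approx(v2)
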