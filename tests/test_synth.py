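"""Generator contracts: determinism, conservation laws, scenario behaviour."""

import numpy as np
import pytest

from extrumech.errors import DomainError, InsufficientSampleError
from extrumech.populations import build_histogram
from extrumech.synth import (PopulationSpec, ScenarioModel, SpectrumSpec, TraceSpec,
                             generate_force_trace, generate_population,
                             simulate_extrusion_cycles, simulate_fret_spectrum,
                             simulate_recalibration)


class TestDeterminism:
    def test_trace_bit_identical_under_same_seed(self):
        t1, g1 = generate_force_trace(TraceSpec(seed=9))
        t2, g2 = generate_force_trace(TraceSpec(seed=9))
        assert np.array_equal(t1.force_N, t2.force_N)
        assert np.array_equal(g1.plateau_forces_N, g2.plateau_forces_N)

    def test_population_bit_identical_under_same_seed(self):
        p1 = generate_population(PopulationSpec(seed=9))
        p2 = generate_population(PopulationSpec(seed=9))
        assert np.array_equal(p1.diameters_nm, p2.diameters_nm)
        assert np.array_equal(p1.donor_frac, p2.donor_frac)

    def test_recalibration_bit_identical_under_same_seed(self):
        pop = generate_population(PopulationSpec(seed=9))
        r1 = simulate_recalibration(pop, ScenarioModel("B", 50.0, seed=9))
        r2 = simulate_recalibration(pop, ScenarioModel("B", 50.0, seed=9))
        assert np.array_equal(r1.diameters_nm, r2.diameters_nm)

    def test_different_seeds_differ(self):
        t1, _ = generate_force_trace(TraceSpec(seed=1))
        t2, _ = generate_force_trace(TraceSpec(seed=2))
        assert not np.array_equal(t1.force_N, t2.force_N)


class TestTraceGenerator:
    def test_noiseless_instant_rise_is_piecewise_constant(self):
        spec = TraceSpec(seed=0, noise_sd_N=0.0, rise_time_s=0.0)
        trace, truth = generate_force_trace(spec)
        for (i0, i1), level in zip(truth.cycle_bounds, truth.plateau_forces_N):
            assert np.all(trace.force_N[i0:i1] == pytest.approx(level))

    def test_instant_decline_limit(self):
        spec = TraceSpec(seed=0, noise_sd_N=0.0, rise_time_s=0.0,
                         decline_constant_cycles=0.0)
        _, truth = generate_force_trace(spec)
        total_floor = spec.stabilized_force_N + spec.baseline_force_N
        assert truth.plateau_forces_N[0] == pytest.approx(
            spec.first_cycle_force_N + spec.baseline_force_N)
        assert np.all(truth.plateau_forces_N[1:] == pytest.approx(total_floor))

    def test_decline_law_matches_closed_form(self):
        spec = TraceSpec(seed=0)
        expected = [spec.stabilized_force_N
                    + (spec.first_cycle_force_N - spec.stabilized_force_N)
                    * np.exp(-(i - 1) / spec.decline_constant_cycles)
                    + spec.baseline_force_N
                    for i in range(1, 8)]
        _, truth = generate_force_trace(spec)
        assert truth.plateau_forces_N == pytest.approx(expected)

    def test_invalid_spec_rejected(self):
        with pytest.raises(DomainError):
            TraceSpec(first_cycle_force_N=5.0, stabilized_force_N=6.0)


class TestPopulationGenerator:
    def test_single_component_mean_within_clt_tolerance(self):
        spec = PopulationSpec(n_vesicles=2000, seed=3)
        pop = generate_population(spec)
        se = 15.0 / np.sqrt(2000)
        assert abs(pop.diameters_nm.mean() - 137.0) < 3 * se + 0.2  # +truncation slack

    def test_degenerate_weight_equals_single_component(self):
        single = generate_population(PopulationSpec(seed=4))
        double = generate_population(PopulationSpec(
            seed=4, size_means_nm=(137.0, 500.0), size_sds_nm=(15.0, 50.0),
            weights=(1.0, 0.0)))
        assert np.array_equal(single.diameters_nm, double.diameters_nm)

    def test_empty_population_propagates_insufficient_sample(self):
        pop = generate_population(PopulationSpec(n_vesicles=0, seed=0))
        with pytest.raises(InsufficientSampleError):
            build_histogram(pop)

    def test_truncation_floor(self):
        pop = generate_population(PopulationSpec(
            n_vesicles=2000, size_means_nm=(30.0,), size_sds_nm=(20.0,), seed=5))
        assert pop.diameters_nm.min() > 20.0

    def test_invalid_simplex_rejected(self):
        with pytest.raises(DomainError):
            PopulationSpec(size_means_nm=(100.0, 200.0), size_sds_nm=(10.0, 10.0),
                           weights=(0.6, 0.6))


class TestRecalibration:
    def test_scenario_a_area_conserved_exactly(self):
        pop = generate_population(PopulationSpec(seed=6))
        recal = simulate_recalibration(pop, ScenarioModel("A", 50.0, seed=6))
        assert (recal.diameters_nm ** 2).sum() == pytest.approx(
            (pop.diameters_nm ** 2).sum(), rel=1e-12)

    @pytest.mark.parametrize("scenario", ["A", "B", "C"])
    def test_area_and_dye_conserved(self, scenario):
        pop = generate_population(PopulationSpec(
            seed=6, label_fractions={"donor": 0.5, "acceptor": 0.5, "dual": 0.0, "none": 0.0}))
        recal = simulate_recalibration(pop, ScenarioModel(scenario, 50.0, seed=6))
        for frac_in, frac_out in ((pop.donor_frac, recal.donor_frac),
                                  (pop.acceptor_frac, recal.acceptor_frac)):
            dye_in = np.sum(pop.diameters_nm ** 2 * frac_in)
            dye_out = np.sum(recal.diameters_nm ** 2 * frac_out)
            assert dye_out == pytest.approx(dye_in, rel=1e-9)

    def test_scenario_a_keeps_labels_unmixed(self):
        pop = generate_population(PopulationSpec(
            seed=6, label_fractions={"donor": 0.5, "acceptor": 0.5, "dual": 0.0, "none": 0.0}))
        recal = simulate_recalibration(pop, ScenarioModel("A", 50.0, seed=6))
        assert not np.any(recal.labels == "dual")

    @pytest.mark.parametrize("scenario", ["B", "C"])
    def test_pooling_scenarios_mix_labels(self, scenario):
        pop = generate_population(PopulationSpec(
            seed=6, label_fractions={"donor": 0.5, "acceptor": 0.5, "dual": 0.0, "none": 0.0}))
        recal = simulate_recalibration(pop, ScenarioModel(scenario, 50.0, seed=6))
        assert np.mean(recal.labels == "dual") > 0.5

    def test_scenario_c_daughters_do_not_exceed_pore(self):
        pop = generate_population(PopulationSpec(seed=6))
        recal = simulate_recalibration(pop, ScenarioModel("C", 50.0, seed=6))
        # hard cap at the pore diameter (tiny slack for remainder redistribution)
        assert recal.diameters_nm.max() <= 50.0 * 1.005

    def test_multilamellar_input_rejected(self):
        pop = generate_population(PopulationSpec(
            seed=6, lamellarity_choices=(3,), lamellarity_probs=(1.0,)))
        with pytest.raises(DomainError):
            simulate_recalibration(pop, ScenarioModel("A", 50.0, seed=6))

    def test_pore_must_be_below_mean(self):
        pop = generate_population(PopulationSpec(seed=6))
        with pytest.raises(DomainError):
            simulate_recalibration(pop, ScenarioModel("A", 200.0, seed=6))


class TestExtrusionCycles:
    def mlv(self, seed=8):
        return generate_population(PopulationSpec(
            n_vesicles=60, size_means_nm=(1000.0,), size_sds_nm=(250.0,),
            lamellarity_choices=(4, 5, 6), lamellarity_probs=(0.3, 0.4, 0.3), seed=seed))

    def test_unilamellar_pore_sized_input_is_fixed_point(self):
        pop = generate_population(PopulationSpec(
            n_vesicles=200, size_means_nm=(100.0,), size_sds_nm=(10.0,), seed=8))
        pops, _ = simulate_extrusion_cycles(pop, ScenarioModel("C", 100.0, seed=8), 3)
        for p in pops:
            assert np.array_equal(p.diameters_nm, pop.diameters_nm)

    def test_area_conserved_every_cycle(self):
        mlv = self.mlv()
        a0 = mlv.membrane_area.sum()
        pops, _ = simulate_extrusion_cycles(mlv, ScenarioModel("C", 100.0, seed=8), 7)
        for p in pops:
            assert p.membrane_area.sum() == pytest.approx(a0, rel=5e-3)

    def test_homogenisation_trajectory(self):
        _, traj = simulate_extrusion_cycles(self.mlv(), ScenarioModel("C", 100.0, seed=8), 7)
        assert np.all(np.diff(traj.mean_diameter_nm) <= 1e-9)
        assert np.all(np.diff(traj.pdi_analog) <= 1e-3)  # tiny slack for daughter weight
        assert traj.pdi_analog[-1] < traj.pdi_analog[0]
        assert traj.transmitted_fraction[-1] == pytest.approx(1.0)
        assert np.all(np.diff(traj.transmitted_fraction) >= -1e-12)

    def test_transmitted_fraction_saturates_late(self):
        _, traj = simulate_extrusion_cycles(self.mlv(), ScenarioModel("C", 100.0, seed=8), 7)
        assert traj.transmitted_fraction[0] < 0.5
        assert traj.transmitted_fraction[5] > 0.9


class TestSpectrumGenerator:
    def test_zero_transfer_spectrum_independent_of_dual_fraction(self):
        spec = SpectrumSpec(transfer_efficiency=0.0, noise_sd=0.0)
        pops = [generate_population(PopulationSpec(
            seed=1, label_fractions={"donor": 1 - f, "acceptor": 0.0, "dual": f, "none": 0.0}))
            for f in (0.0, 1.0)]
        s0 = simulate_fret_spectrum(pops[0], spec)
        s1 = simulate_fret_spectrum(pops[1], spec)
        assert np.allclose(s0.intensity, s1.intensity)

    def test_unlabelled_population_warns_and_gives_leak_only(self):
        spec = SpectrumSpec(noise_sd=0.0)
        pop = generate_population(PopulationSpec(seed=1))
        with pytest.warns(UserWarning, match="donor"):
            s = simulate_fret_spectrum(pop, spec)
        donor_peak = s.intensity[np.argmin(np.abs(s.wavelength_nm - 531.0))]
        acceptor_peak = s.intensity[np.argmin(np.abs(s.wavelength_nm - 589.0))]
        assert donor_peak < 1e-3 * spec.intensity_scale
        assert acceptor_peak == pytest.approx(spec.acceptor_leak * spec.intensity_scale,
                                              rel=1e-3)
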