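"""Synthetic-experiment generator: fixture, protocol schedule, scenarios,
noise model and determinism."""

import dataclasses
import math

import numpy as np
import pytest

from thzhdx.experiment import (
    ExperimentDesign,
    ResidueModel,
    build_schedule,
    default_ubiquitin_fixture,
    gc_scenario,
    heat_scenario,
    simulate_experiment,
    thz_scenario,
)
from thzhdx.kinetics import (
    DEFAULT_REFERENCE,
    IntrinsicRateModel,
    PhaseSchedule,
    celsius_to_kelvin,
    phase_exchange_rate,
    protonated_fraction,
    scale_kch_temperature,
)
from thzhdx.statistics import normalize_intensities


class TestFixture:
    def test_hydrophilic_set(self, ubq_residues):
        hydrophilic = {r.residue_number for r in ubq_residues if r.hydropathy_class == "hydrophilic_surface"}
        assert hydrophilic == {21, 59, 61}

    def test_interior_helix_set(self, ubq_residues):
        interior = {r.residue_number for r in ubq_residues if r.hydropathy_class == "interior_helix"}
        assert interior == {26, 30}

    def test_hydrophobic_surface_set(self, ubq_residues):
        hydrophobic = {r.residue_number for r in ubq_residues if r.hydropathy_class == "hydrophobic_surface"}
        assert hydrophobic == {3, 4, 15, 17, 41, 42, 43, 44, 69, 70}

    def test_rates_below_cutoff_at_measurement_temperature(self, ubq_residues):
        # control rates sit below ~0.1 h^-1 at the 4 degC readout temperature
        model = IntrinsicRateModel(k_ref=1.0, ea_kj_mol=DEFAULT_REFERENCE.ea_kj_mol)
        factor = scale_kch_temperature(model, celsius_to_kelvin(4.0))
        for r in ubq_residues:
            assert r.K_op * r.k_ch_ref * factor <= 0.1

    def test_fifteen_residues_named(self, ubq_residues):
        assert len(ubq_residues) == 15
        assert all(1 <= r.residue_number <= 76 for r in ubq_residues)


class TestSchedule:
    def test_x_zero_equals_control_schedule(self):
        pert = build_schedule(
            ExperimentDesign(condition="THz_low", perturbation_minutes=0, storage_hours=8.0),
            thz_scenario(),
        )
        control = build_schedule(
            ExperimentDesign(condition="GC", perturbation_minutes=0, storage_hours=8.0), None
        )
        assert pert == control

    def test_x_twelve_leaves_one_minute_hold(self):
        schedule = build_schedule(
            ExperimentDesign(condition="TC", perturbation_minutes=12, storage_hours=8.0),
            heat_scenario(),
        )
        # phases: 1 min handling, 12 min perturbed, 1 min hold, storage
        assert [p.duration_min for p in schedule.phases[:3]] == [1.0, 12.0, 1.0]

    @pytest.mark.parametrize("x", [0, 3, 6, 12])
    def test_pre_storage_duration_fixed_at_14(self, x):
        schedule = build_schedule(
            ExperimentDesign(condition="THz_low", perturbation_minutes=x, storage_hours=8.0),
            thz_scenario(),
        )
        pre_storage = sum(p.duration_min for p in schedule.phases[:-1])
        assert pre_storage == pytest.approx(14.0)

    def test_perturbation_longer_than_window_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(condition="THz_low", perturbation_minutes=14)

    def test_gc_condition_ignores_scenario(self, ubq_residues):
        residue = ubq_residues[0]
        with_scenario = build_schedule(
            ExperimentDesign(condition="GC", perturbation_minutes=12, storage_hours=8.0),
            thz_scenario(),
        )
        without = build_schedule(
            ExperimentDesign(condition="GC", perturbation_minutes=12, storage_hours=8.0), None
        )
        assert protonated_fraction(with_scenario, residue) == protonated_fraction(without, residue)


class TestScenarios:
    def test_degenerate_thz_is_pure_heating(self):
        scenario = thz_scenario(f_kop_up=1.0, f_kch_down=1.0, temp_offset_c=5.0)
        assert not any(v != 1.0 for v in scenario.kop_multiplier_by_class.values())
        assert not any(v != 1.0 for v in scenario.kch_multiplier_by_class.values())
        assert scenario.temp_offset_c == 5.0

    def test_thz_low_default_offset(self):
        assert thz_scenario().temp_offset_c == pytest.approx(0.3)

    def test_out_of_range_factors_rejected(self):
        with pytest.raises(ValueError):
            thz_scenario(f_kop_up=0.5)
        with pytest.raises(ValueError):
            thz_scenario(f_kch_down=1.5)
        with pytest.raises(ValueError):
            heat_scenario(f_kop_down=0.0)
        with pytest.raises(ValueError):
            heat_scenario(delta_t_c=-1.0)

    def test_hydrophobic_rate_increases_with_kop_factor(self, ubq_residues):
        residue = next(r for r in ubq_residues if r.hydropathy_class == "hydrophobic_surface")
        design = ExperimentDesign(condition="THz_low", perturbation_minutes=6, storage_hours=8.0)
        rates = []
        for f in (1.5, 2.0, 4.0, 8.0):
            schedule = build_schedule(design, thz_scenario(f_kop_up=f))
            rates.append(phase_exchange_rate(schedule.phases[1], residue))
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_degenerate_heat_equals_control(self, ubq_residues):
        design = ExperimentDesign(condition="TC", perturbation_minutes=6, storage_hours=8.0)
        scenario = heat_scenario(delta_t_c=0.0, f_kop_down=1.0)
        control = build_schedule(
            ExperimentDesign(condition="GC", perturbation_minutes=6, storage_hours=8.0), None
        )
        schedule = build_schedule(design, scenario)
        for r in ubq_residues:
            assert protonated_fraction(schedule, r) == pytest.approx(
                protonated_fraction(control, r), rel=1e-12
            )

    def test_pure_heating_accelerates_every_class(self, ubq_residues):
        design = ExperimentDesign(condition="TC", perturbation_minutes=6, storage_hours=8.0)
        schedule = build_schedule(design, heat_scenario(delta_t_c=5.0, f_kop_down=1.0))
        control = build_schedule(
            ExperimentDesign(condition="GC", perturbation_minutes=6, storage_hours=8.0), None
        )
        for r in ubq_residues:
            assert protonated_fraction(schedule, r) < protonated_fraction(control, r)

    def test_strong_rigidification_inverts_hydrophobic_only(self, ubq_residues):
        # f below 1/exp(Ea/R * d(1/T)) ~ 1/1.49 makes hydrophobic slower while
        # hydrophilic (Arrhenius only) stays faster
        design = ExperimentDesign(condition="TC", perturbation_minutes=12, storage_hours=8.0)
        schedule = build_schedule(design, heat_scenario(delta_t_c=5.0, f_kop_down=0.5))
        control = build_schedule(
            ExperimentDesign(condition="GC", perturbation_minutes=12, storage_hours=8.0), None
        )
        for r in ubq_residues:
            perturbed, base = protonated_fraction(schedule, r), protonated_fraction(control, r)
            if r.hydropathy_class == "hydrophilic_surface":
                assert perturbed < base
            else:
                assert perturbed > base


class TestSimulation:
    def test_zero_noise_intensities_are_exact(self, ubq_residues):
        design = ExperimentDesign(
            condition="GC", perturbation_minutes=3, storage_hours=8.0,
            nominal_snr=None, n_spectra=1, seed=0,
        )
        table = simulate_experiment(ubq_residues, design, None, concentration_jitter_sd=0.0)
        schedule = build_schedule(design, None)
        for r in ubq_residues:
            assert table.amide(r.residue_number).intensity == pytest.approx(
                protonated_fraction(schedule, r), rel=1e-12
            )

    def test_fixed_seed_reproduces_table_exactly(self, ubq_residues):
        design = ExperimentDesign(condition="THz_low", perturbation_minutes=6, seed=42)
        t1 = simulate_experiment(ubq_residues, design, thz_scenario())
        t2 = simulate_experiment(ubq_residues, design, thz_scenario())
        assert t1 == t2

    def test_different_seeds_differ(self, ubq_residues):
        base = dict(condition="THz_low", perturbation_minutes=6)
        t1 = simulate_experiment(ubq_residues, ExperimentDesign(**base, seed=1), thz_scenario())
        t2 = simulate_experiment(ubq_residues, ExperimentDesign(**base, seed=2), thz_scenario())
        assert t1 != t2
        assert {r.signal_id for r in t1.records} == {r.signal_id for r in t2.records}

    def test_concentration_jitter_cancels_after_normalization(self, ubq_residues):
        design = ExperimentDesign(
            condition="GC", perturbation_minutes=3, storage_hours=8.0, nominal_snr=None, seed=7
        )
        table = simulate_experiment(ubq_residues, design, None, concentration_jitter_sd=0.02)
        normalized = normalize_intensities(table.amides(), table.methyls())
        schedule = build_schedule(design, None)
        for r in ubq_residues:
            assert normalized[r.residue_number] == pytest.approx(
                protonated_fraction(schedule, r), abs=1e-9
            )

    def test_control_ratio_is_unity_without_noise(self, ubq_residues):
        design = dict(condition="GC", perturbation_minutes=6, storage_hours=8.0, nominal_snr=None)
        t_a = simulate_experiment(ubq_residues, ExperimentDesign(**design, seed=1), None)
        t_b = simulate_experiment(ubq_residues, ExperimentDesign(**design, seed=2), None)
        norm_a = normalize_intensities(t_a.amides(), t_a.methyls())
        norm_b = normalize_intensities(t_b.amides(), t_b.methyls())
        for res in norm_a:
            assert norm_a[res] / norm_b[res] == pytest.approx(1.0, abs=1e-12)

    def test_control_decay_small_for_slow_residues(self):
        # k_ex <= 0.1 h^-1 loses at most ~2.4% protonation over the 14 min
        # before storage, so the 3-min reference is near-plateau
        residue = ResidueModel(
            residue_number=1, amino_acid="M", hydropathy_class="hydrophobic_surface",
            K_op=1e-3, k_ch_ref=100.0,
        )
        design = ExperimentDesign(condition="GC", perturbation_minutes=12, storage_hours=0.0)
        schedule = build_schedule(design, None)
        pre_storage = PhaseSchedule(schedule.phases[:-1])
        assert 1.0 - protonated_fraction(pre_storage, residue) <= 0.024

    def test_thz_depresses_hydrophobic_intensities(self, ubq_residues):
        kwargs = dict(storage_hours=8.0, nominal_snr=None)
        gc = simulate_experiment(
            ubq_residues,
            ExperimentDesign(condition="GC", perturbation_minutes=12, seed=0, **kwargs),
            None,
        )
        thz = simulate_experiment(
            ubq_residues,
            ExperimentDesign(condition="THz_low", perturbation_minutes=12, seed=0, **kwargs),
            thz_scenario(f_kop_up=2.0),
        )
        for r in ubq_residues:
            if r.hydropathy_class in ("hydrophobic_surface", "interior_helix"):
                assert thz.amide(r.residue_number).intensity < gc.amide(r.residue_number).intensity

    def test_summed_spectra_improve_snr_by_sqrt3(self, ubq_residues):
        # Monte-Carlo over replicates: realized SNR ratio ~ sqrt(3)
        residue = [ubq_residues[0]]
        reps = 1500
        singles, summed = [], []
        for i in range(reps):
            d1 = ExperimentDesign(
                condition="GC", perturbation_minutes=3, storage_hours=8.0,
                n_spectra=1, nominal_snr=50.0, seed=10_000 + i,
            )
            d3 = dataclasses.replace(d1, n_spectra=3, seed=60_000 + i)
            singles.append(simulate_experiment(residue, d1, None, concentration_jitter_sd=0.0).amide(3).intensity)
            summed.append(simulate_experiment(residue, d3, None, concentration_jitter_sd=0.0).amide(3).intensity)
        snr_1 = np.mean(singles) / np.std(singles)
        snr_3 = np.mean(summed) / np.std(summed)
        assert snr_3 / snr_1 == pytest.approx(math.sqrt(3), rel=0.10)

    def test_storage_hours_drawn_within_range_and_recorded(self, ubq_residues):
        design = ExperimentDesign(condition="GC", perturbation_minutes=3, seed=3)
        table = simulate_experiment(ubq_residues, design, None)
        assert 6.0 <= table.design.storage_hours <= 10.0
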