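"""PBPK simulator: partitioning, clearance, mass balance, kinetics, fitting."""

from dataclasses import replace

import numpy as np
import pytest

from gentapbpk import (
    GENTAMICIN,
    DoseRegimen,
    DrugParameters,
    build_reference_dog,
    compute_clearances,
    compute_partition_coefficients,
    fit_parameters,
    simulate_profile,
)
from gentapbpk.errors import ConfigurationError
from gentapbpk.pbpk import default_grid, volume_of_distribution
from gentapbpk.validation import ObservedSeries

TINY_KP = {t: 1e-4 for t in ("muscle", "adipose", "kidney", "liver", "rest")}


class TestPartitionCoefficients:
    def test_lipid_partition_is_ten_to_the_logp(self, reference_dog):
        # logP -1.6 -> K_lipid ~ 0.0251; back the value out of the muscle Kp
        kps = compute_partition_coefficients(GENTAMICIN, reference_dog)
        muscle = reference_dog.organ("muscle")
        k_lipid = (
            kps["muscle"] / GENTAMICIN.kp_scale
            - muscle.f_water
            - 0.1 * muscle.f_protein
        ) / muscle.f_lipid
        assert k_lipid == pytest.approx(10 ** (-1.6), rel=1e-9)

    def test_override_passes_through_verbatim(self, reference_dog):
        drug = replace(GENTAMICIN, kp_overrides={"muscle": 0.3})
        assert compute_partition_coefficients(drug, reference_dog)["muscle"] == 0.3

    def test_formula_reduces_to_water_fraction(self):
        from gentapbpk.physiology import DogPhysiology, OrganSpec, load_physiology_table

        table = load_physiology_table()
        table.loc[table["name"] == "muscle", ["f_water", "f_lipid", "f_protein"]] = [0.8, 0.0, 0.0]
        dog = build_reference_dog(table=table)
        drug = replace(GENTAMICIN, kp_scale=1.0)
        assert compute_partition_coefficients(drug, dog)["muscle"] == pytest.approx(0.8)

    def test_distribution_volume_in_calibrated_band(self, reference_dog):
        assert 0.20 <= volume_of_distribution(GENTAMICIN, reference_dog) <= 0.30


class TestClearances:
    def test_renal_clearance_hand_value(self, reference_dog):
        # 0.85 x 3.3 mL/min/kg x 10.5 kg = 29.4525 mL/min = 1.767 L/h
        cl = compute_clearances(GENTAMICIN, reference_dog)
        assert cl["renal"] == pytest.approx(1.76715, rel=1e-6)

    def test_zero_gfr_zero_renal_clearance(self, reference_dog):
        anuric = replace(reference_dog, gfr=0.0)
        assert compute_clearances(GENTAMICIN, anuric)["renal"] == 0.0

    def test_healthy_total_clearance_near_reference(self, reference_dog):
        cl = compute_clearances(GENTAMICIN, reference_dog)
        per_kg = cl["total"] / reference_dog.weight
        assert per_kg == pytest.approx(0.17, rel=0.10)


class TestSimulation:
    def test_zero_dose_gives_zero_everywhere(self, reference_dog):
        prof = simulate_profile(reference_dog, GENTAMICIN, DoseRegimen(dose_per_kg=0.0))
        assert np.all(prof.plasma_concentration == 0)
        assert np.all(prof.amounts == 0)

    @pytest.mark.parametrize(
        "regimen",
        [
            DoseRegimen(dose_per_kg=4.0, infusion_duration=0.0, interval=24, n_doses=1),
            DoseRegimen(dose_per_kg=2.0),
            DoseRegimen(dose_per_kg=10.0, interval=36.0, n_doses=3),
        ],
        ids=["bolus-single", "q24x3", "q36x3"],
    )
    def test_mass_balance_within_0_1_percent(self, reference_dog, regimen):
        prof = simulate_profile(reference_dog, GENTAMICIN, regimen)
        err = prof.mass_balance_error(regimen, reference_dog.weight)
        assert np.abs(err).max() < 1e-3

    def test_dose_linearity(self, reference_dog):
        grid = default_grid(DoseRegimen(dose_per_kg=1.0))
        lo = simulate_profile(reference_dog, GENTAMICIN, DoseRegimen(dose_per_kg=2.0), grid=grid)
        hi = simulate_profile(reference_dog, GENTAMICIN, DoseRegimen(dose_per_kg=4.0), grid=grid)
        mask = lo.plasma_concentration > 1e-6 * lo.plasma_concentration.max()
        ratio = hi.plasma_concentration[mask] / lo.plasma_concentration[mask]
        assert np.allclose(ratio, 2.0, rtol=1e-6)

    def test_superposition_of_shifted_single_doses(self, reference_dog):
        multi = DoseRegimen(dose_per_kg=4.0)
        grid = default_grid(multi)
        prof3 = simulate_profile(reference_dog, GENTAMICIN, multi, grid=grid)
        total = np.zeros_like(grid)
        single = DoseRegimen(dose_per_kg=4.0, interval=72.0, n_doses=1)
        for shift in (0.0, 24.0, 48.0):
            t_local = grid[grid >= shift] - shift
            if t_local[0] > 0:
                t_local = np.insert(t_local, 0, 0.0)
            prof1 = simulate_profile(reference_dog, GENTAMICIN, single, grid=t_local)
            contrib = np.interp(grid - shift, t_local, prof1.plasma_concentration, left=0.0)
            total += contrib
        mask = prof3.plasma_concentration > 1e-9
        assert np.allclose(prof3.plasma_concentration[mask], total[mask], rtol=1e-5)

    def test_lumped_limit_matches_one_compartment_closed_form(self, reference_dog):
        drug = replace(GENTAMICIN, kp_overrides=TINY_KP)
        reg = DoseRegimen(dose_per_kg=2.0, infusion_duration=0.0, interval=24, n_doses=1)
        # fine early grid: the bolus mixing spike decays within ~1/100 h
        grid = np.unique(np.concatenate([np.arange(0, 0.2, 0.001), np.arange(0.2, 24.01, 0.05)]))
        prof = simulate_profile(reference_dog, drug, reg, grid=grid)
        v = 0.082 * reference_dog.weight * drug.blood_plasma_ratio  # plasma-referenced
        cl = compute_clearances(drug, reference_dog)["total"]
        t = prof.times
        expect = (2.0 * reference_dog.weight / v) * np.exp(-cl * t / v)
        # profile agreement where the renal arteriovenous extraction gradient
        # is negligible (concentrations span ~50x over this window) ...
        window = (t >= 0.3) & (t <= 1.5)
        assert np.allclose(prof.plasma_concentration[window], expect[window], rtol=0.01)
        # ... and the exposure identity AUCinf = dose / CL over the full range
        auc = np.trapezoid(prof.plasma_concentration, t)
        assert auc == pytest.approx(2.0 * reference_dog.weight / cl, rel=0.01)

    def test_expm_and_lsoda_solvers_agree(self, reference_dog):
        reg = DoseRegimen(dose_per_kg=4.0, n_doses=2)
        grid = np.array([0.0, 0.05, 5 / 60, 0.5, 1, 4, 12, 24 - 1e-6, 24.5, 47.9, 48.0])
        a = simulate_profile(reference_dog, GENTAMICIN, reg, grid=grid, method="lsoda")
        b = simulate_profile(reference_dog, GENTAMICIN, reg, grid=grid, method="expm")
        mask = a.plasma_concentration > 1e-12
        assert np.allclose(
            a.plasma_concentration[mask], b.plasma_concentration[mask], rtol=1e-6
        )

    def test_lower_gfr_strictly_raises_auc(self, reference_dog):
        reg = DoseRegimen(dose_per_kg=4.0, interval=72.0, n_doses=1)
        aucs = []
        for gfr in (3.3, 2.0, 1.0, 0.5):
            dog = replace(reference_dog, gfr=gfr)
            prof = simulate_profile(dog, GENTAMICIN, reg)
            aucs.append(np.trapezoid(prof.plasma_concentration, prof.times))
        assert all(a < b for a, b in zip(aucs, aucs[1:]))

    def test_bad_grid_rejected(self, reference_dog):
        reg = DoseRegimen(dose_per_kg=1.0)
        with pytest.raises(ValueError):
            simulate_profile(reference_dog, GENTAMICIN, reg, grid=np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_profile(reference_dog, GENTAMICIN, reg, grid=np.array([0.0, 100.0]))


class TestParameterIdentification:
    def _observed_from_model(self, dog, drug, dose=4.0):
        reg = DoseRegimen(dose_per_kg=dose, infusion_duration=0.0, interval=30.0, n_doses=1)
        times = np.array([0.083, 0.25, 0.5, 1, 2, 4, 6, 8, 12, 24])
        grid = np.unique(np.concatenate([default_grid(reg), times]))
        prof = simulate_profile(dog, drug, reg, grid=grid)
        conc = np.interp(times, prof.times, prof.plasma_concentration)
        return ObservedSeries("self", dose, "bolus", times, conc)

    def test_self_consistency_recovers_clearance_within_1pct(self, reference_dog):
        series = self._observed_from_model(reference_dog, GENTAMICIN)
        start = replace(GENTAMICIN, reference_plasma_clearance=0.30)
        fit = fit_parameters([series], free=("reference_plasma_clearance",), drug=start)
        truth = 0.85 * 3.3 * 60 / 1000  # fu x gfr of the generating dog
        assert fit.drug.reference_plasma_clearance == pytest.approx(truth, rel=0.01)

    def test_objective_near_zero_on_model_data(self, reference_dog):
        series = self._observed_from_model(reference_dog, GENTAMICIN)
        fit = fit_parameters(
            [series],
            free=("reference_plasma_clearance",),
            drug=replace(GENTAMICIN, reference_plasma_clearance=0.2),
        )
        assert fit.objective < 1e-4

    def test_empty_observed_set_rejected(self):
        with pytest.raises(ValueError):
            fit_parameters([], free=("reference_plasma_clearance",))

    def test_unknown_free_parameter_rejected(self, reference_dog):
        series = self._observed_from_model(reference_dog, GENTAMICIN)
        with pytest.raises(ConfigurationError):
            fit_parameters([series], free=("logp",))

    def test_no_free_parameters_is_a_noop(self, reference_dog):
        series = self._observed_from_model(reference_dog, GENTAMICIN)
        fit = fit_parameters([series], free=())
        assert fit.drug == GENTAMICIN and fit.objective == 0.0
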