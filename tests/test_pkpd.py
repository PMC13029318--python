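"""Exposure metrics, PTA/toxicity enumeration, dose picking, sensitivity."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from gentapbpk import (
    GENTAMICIN,
    DoseRegimen,
    EfficacyTarget,
    build_reference_dog,
    compute_pta,
    exposure_metrics,
    minimal_effective_dose,
    recommend_regimen,
    sensitivity_analysis,
    simulate_profile,
    toxicity_risk,
)
from gentapbpk.errors import ConfigurationError
from gentapbpk.pbpk import ConcentrationProfile


def synthetic_profile(times, conc):
    """Wrap a hand-built concentration curve in a profile object."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    return ConcentrationProfile(
        times=times,
        plasma_concentration=conc,
        amounts=np.zeros((7, times.size)),
        cumulative_eliminated=np.zeros_like(times),
        organ_names=("arterial_blood", "venous_blood", "muscle", "adipose", "kidney", "liver", "rest"),
        dose_total=1.0,
    )


class TestExposureMetrics:
    def test_lumped_auc24_matches_dose_over_clearance(self, reference_dog):
        # all-tissue Kp -> 0: one-compartment with CL 0.168 L/h/kg, t1/2 ~ 0.3 h,
        # so >99.9% of AUCinf = dose/CL falls inside the first day
        drug = replace(
            GENTAMICIN,
            kp_overrides={t: 1e-4 for t in ("muscle", "adipose", "kidney", "liver", "rest")},
        )
        reg = DoseRegimen(dose_per_kg=2.0, interval=24.0, n_doses=1)
        m = exposure_metrics(simulate_profile(reference_dog, drug, reg), reg)
        assert m.auc24_day1 == pytest.approx(2.0 / 0.17, rel=0.02)

    def test_zero_dose_zero_metrics(self, reference_dog):
        reg = DoseRegimen(dose_per_kg=0.0)
        m = exposure_metrics(simulate_profile(reference_dog, GENTAMICIN, reg), reg)
        assert (m.auc24_day1, m.auc24_final, m.cmax, m.cmin_day1, m.cmin_final) == (0,) * 5

    def test_trough_of_short_half_life_curve_is_negligible(self):
        reg = DoseRegimen(dose_per_kg=1.0, interval=24.0, n_doses=1)
        t = np.linspace(0, 24, 2000)
        prof = synthetic_profile(t, 8.0 * 2.0 ** (-t))  # Cmax 8, t1/2 = 1 h
        m = exposure_metrics(prof, reg)
        assert m.cmax == pytest.approx(8.0)
        assert m.cmin_day1 < 1e-4

    def test_final_interval_accumulates_under_slow_elimination(self, reference_dog):
        slow = replace(reference_dog, gfr=0.33)
        reg = DoseRegimen(dose_per_kg=10.0)
        m = exposure_metrics(simulate_profile(slow, GENTAMICIN, reg), reg)
        assert m.auc24_final > m.auc24_day1
        assert m.cmin_final > m.cmin_day1 > 0.5

    def test_grid_must_cover_regimen(self, reference_dog):
        reg24 = DoseRegimen(dose_per_kg=2.0)
        prof = simulate_profile(reference_dog, GENTAMICIN, reg24)
        reg36 = DoseRegimen(dose_per_kg=2.0, interval=36.0)
        with pytest.raises(ValueError, match="cover"):
            exposure_metrics(prof, reg36)


def frame(**cols):
    return pd.DataFrame(cols)


class TestPTA:
    def test_inclusive_threshold_boundary(self):
        metrics = frame(auc24_day1=[50.0] * 10, cmax=[1.0] * 10)
        target = EfficacyTarget("auc24_over_mic", 50.0)
        p = compute_pta(metrics, target, [1.0, 2.0])
        assert p["pta_pct"].tolist() == [100.0, 0.0]

    def test_equals_bruteforce_enumeration(self):
        rng = np.random.default_rng(4)
        metrics = frame(auc24_day1=rng.lognormal(3, 0.6, 501), cmax=rng.lognormal(2, 0.4, 501))
        for target in (EfficacyTarget("auc24_over_mic", 50), EfficacyTarget("cmax_over_mic", 10)):
            p = compute_pta(metrics, target, [0.25, 0.5, 1, 2, 4, 8])
            col = metrics["auc24_day1"] if target.index == "auc24_over_mic" else metrics["cmax"]
            for _, row in p.iterrows():
                expect = sum(1 for v in col if v / row["mic_ug_ml"] >= target.threshold)
                assert row["pta_pct"] == 100.0 * expect / len(col)

    def test_monotone_in_mic_and_dose(self, healthy_metrics_2000):
        target = EfficacyTarget("auc24_over_mic", 50.0)
        by_dose = {}
        for dose, grp in healthy_metrics_2000.groupby("dose_mg_kg"):
            p = compute_pta(grp, target)
            assert (np.diff(p["pta_pct"]) <= 0).all()  # non-increasing in MIC
            by_dose[dose] = p["pta_pct"].to_numpy()
        doses = sorted(by_dose)
        for lo, hi in zip(doses, doses[1:]):
            assert (by_dose[hi] >= by_dose[lo]).all()  # non-decreasing in dose

    def test_subsample_convergence_within_3_points(self, healthy_metrics_2000):
        grp = healthy_metrics_2000[healthy_metrics_2000["dose_mg_kg"] == 6.0]
        target = EfficacyTarget("auc24_over_mic", 50.0)
        full = compute_pta(grp, target)["pta_pct"].to_numpy()
        for seed in (0, 1, 2):
            sub = grp.sample(1000, random_state=seed)
            part = compute_pta(sub, target)["pta_pct"].to_numpy()
            assert np.abs(full - part).max() < 3.0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            compute_pta(frame(auc24_day1=[], cmax=[]), EfficacyTarget("cmax_over_mic", 10))


class TestToxicityRisk:
    def test_all_exceeding_gives_100(self):
        metrics = frame(auc24_final=[800.0] * 5, cmin_final=[1.0] * 5)
        assert toxicity_risk(metrics, "auc24_ge_700") == 100.0
        assert toxicity_risk(metrics, "cmin_ge_0_5") == 100.0

    def test_equals_bruteforce_enumeration(self):
        rng = np.random.default_rng(11)
        metrics = frame(
            auc24_final=rng.lognormal(6, 0.5, 333),
            cmin_final=rng.lognormal(-1, 1.0, 333),
            auc24_day1=rng.lognormal(6, 0.5, 333),
            cmin_day1=rng.lognormal(-1, 1.0, 333),
        )
        for crit, col, thr in (
            ("auc24_ge_700", "auc24_final", 700.0),
            ("cmin_ge_0_5", "cmin_final", 0.5),
        ):
            expect = 100.0 * sum(metrics[col] >= thr) / len(metrics)
            assert toxicity_risk(metrics, crit) == expect

    def test_day1_rule_uses_first_interval(self):
        metrics = frame(cmin_day1=[0.6, 0.1], cmin_final=[0.6, 0.6])
        assert toxicity_risk(metrics, "cmin_ge_0_5", day_rule="day1") == 50.0
        assert toxicity_risk(metrics, "cmin_ge_0_5", day_rule="final") == 100.0

    def test_risk_non_decreasing_in_dose(self, healthy_metrics_2000):
        risks = [
            toxicity_risk(grp, "cmin_ge_0_5")
            for _, grp in healthy_metrics_2000.groupby("dose_mg_kg")
        ]
        assert all(a <= b for a, b in zip(risks, risks[1:]))

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ConfigurationError):
            toxicity_risk(frame(cmin_final=[1.0]), "cmax_ge_12")


def pta_frame(rows):
    return pd.DataFrame(
        rows, columns=["stage", "dose_mg_kg", "interval_h", "index", "threshold", "mic_ug_ml", "pta_pct"]
    )


class TestDosePicking:
    def test_lowest_dose_already_sufficient(self):
        pta = pta_frame([("healthy", d, 24.0, "cmax_over_mic", 10.0, 0.5, 95.0) for d in (2, 4)])
        pick = minimal_effective_dose(pta, [2, 4])
        assert pick["minimal_effective_dose_mg_kg"].tolist() == [2.0]

    def test_none_marker_when_no_dose_qualifies(self):
        pta = pta_frame([("healthy", d, 24.0, "cmax_over_mic", 10.0, 8.0, 40.0) for d in (2, 4)])
        pick = minimal_effective_dose(pta, [2, 4])
        assert np.isnan(pick["minimal_effective_dose_mg_kg"].iloc[0])

    def test_inclusive_90_boundary(self):
        pta = pta_frame(
            [("healthy", 2, 24.0, "cmax_over_mic", 10.0, 1.0, 89.999),
             ("healthy", 4, 24.0, "cmax_over_mic", 10.0, 1.0, 90.0)]
        )
        pick = minimal_effective_dose(pta, [2, 4])
        assert pick["minimal_effective_dose_mg_kg"].iloc[0] == 4.0

    def test_missing_dose_rejected(self):
        pta = pta_frame([("healthy", 2, 24.0, "cmax_over_mic", 10.0, 1.0, 95.0)])
        with pytest.raises(ValueError, match="lacks doses"):
            minimal_effective_dose(pta, [2, 4])

    def test_empty_dose_list_rejected(self):
        with pytest.raises(ValueError):
            minimal_effective_dose(pta_frame([]), [])


class TestRecommendations:
    @staticmethod
    def tables(pta_pct, risk_pct):
        pta = pta_frame([("healthy", 10.0, 36.0, "auc24_over_mic", 50.0, 0.5, pta_pct)])
        tox = pd.DataFrame(
            [{"stage": "healthy", "dose_mg_kg": 10.0, "interval_h": 36.0, "risk_pct": risk_pct}]
        )
        return pta, tox

    def test_exact_thresholds_qualify(self):
        recs = recommend_regimen(*self.tables(90.0, 10.0))
        assert recs[0]["qualifying_regimens"] == [{"dose_mg_kg": 10.0, "interval_h": 36.0}]
        assert recs[0]["flagged_regimen"] == {"dose_mg_kg": 10.0, "interval_h": 36.0}

    def test_empty_qualifying_set_is_not_an_error(self):
        recs = recommend_regimen(*self.tables(80.0, 50.0))
        assert recs[0]["qualifying_regimens"] == [] and recs[0]["flagged_regimen"] is None

    def test_flag_prefers_max_dose_then_longest_interval(self):
        pta = pta_frame(
            [("healthy", d, i, "auc24_over_mic", 50.0, 0.5, 95.0) for d in (8.0, 10.0) for i in (24.0, 36.0)]
        )
        tox = pd.DataFrame(
            [{"stage": "healthy", "dose_mg_kg": d, "interval_h": i, "risk_pct": 0.0}
             for d in (8.0, 10.0) for i in (24.0, 36.0)]
        )
        recs = recommend_regimen(pta, tox)
        assert recs[0]["flagged_regimen"] == {"dose_mg_kg": 10.0, "interval_h": 36.0}

    def test_grid_mismatch_rejected(self):
        pta, tox = self.tables(95.0, 0.0)
        tox = tox.assign(interval_h=48.0)
        with pytest.raises(ValueError, match="cover"):
            recommend_regimen(pta, tox)


class TestSensitivity:
    @pytest.fixture()
    def single_dose(self):
        return DoseRegimen(dose_per_kg=4.0, interval=24.0, n_doses=1)

    def test_dose_scales_auc_one_to_one(self, reference_dog, single_dose):
        s = sensitivity_analysis(reference_dog, GENTAMICIN, single_dose, ["dose"])
        assert s["s_auc"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert s["s_cmax"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_clearance_sensitivity_approaches_minus_one(self, reference_dog, single_dose):
        # AUC ~ 1/CL: forward difference at 1% is -0.990, at 10% it is -0.909
        s_small = sensitivity_analysis(reference_dog, GENTAMICIN, single_dose, ["gfr"], perturbation=0.01)
        assert s_small["s_auc"].iloc[0] == pytest.approx(-1.0, abs=0.02)
        s_big = sensitivity_analysis(reference_dog, GENTAMICIN, single_dose, ["gfr"], perturbation=0.1)
        assert s_big["s_auc"].iloc[0] == pytest.approx((1 / 1.1 - 1) / 0.1, abs=0.02)

    def test_parameter_without_pathway_scores_zero(self, reference_dog, single_dose):
        s = sensitivity_analysis(reference_dog, GENTAMICIN, single_dose, ["pka_acid"])
        assert s["s_auc"].iloc[0] == 0.0 and s["s_cmax"].iloc[0] == 0.0

    def test_muscle_volume_lowers_cmax_not_auc(self, reference_dog, single_dose):
        s = sensitivity_analysis(reference_dog, GENTAMICIN, single_dose, ["muscle_volume"])
        assert s["s_cmax"].iloc[0] < -0.3
        assert abs(s["s_auc"].iloc[0]) < 0.05

    def test_unknown_parameter_rejected(self, reference_dog, single_dose):
        with pytest.raises(ConfigurationError):
            sensitivity_analysis(reference_dog, GENTAMICIN, single_dose, ["renal_blood_ph"])
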