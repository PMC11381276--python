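"""PBPK: partition coefficients, ODE behaviour, fold-ratio validation."""
import dataclasses
import math

import numpy as np
import pytest

from preclinpk.datamodel import (
    CompoundCard,
    ConcTimeProfile,
    DoseEvent,
    Route,
    Sample,
    Species,
)
from preclinpk.errors import ConstructionError, PairingError
from preclinpk.nca import run_nca
from preclinpk.pbpk.model import (
    DoseScenario,
    build_model,
    fit_ka_to_tmax,
    simulate,
)
from preclinpk.pbpk.partition import partition_set, rodgers_rowland_kp
from preclinpk.pbpk.physiology import Organ, TissueComposition
from preclinpk.pbpk.validate import (
    ScenarioComparison,
    human_dose_escalation,
    human_reference_model,
    rat_reference_model,
    validate_against_observed,
)


def _neutral_card(logp: float, fup: float = 1.0) -> CompoundCard:
    return CompoundCard(
        name="probe", mw=300.0, logp=logp, pka=None,
        fup={Species.rat: fup, Species.human: fup},
    )


class TestPartition:
    def test_water_only_limit(self, rat_physiology):
        """A lipid-insoluble neutral compound distributes into tissue water
        (including the 70% aqueous-equivalent fraction of neutral
        phospholipid)."""
        card = _neutral_card(logp=-12.0)
        for organ in ("muscle", "liver", "brain"):
            comp = rat_physiology.organ(organ).composition
            kp = rodgers_rowland_kp(card, rat_physiology, organ, fup=1.0)
            assert kp == pytest.approx(
                comp.f_ew + comp.f_iw + 0.7 * comp.f_np, rel=1e-6
            )

    def test_all_water_tissue_is_unity_for_neutral_nonbinding(self, rat_physiology):
        """A tissue with plasma-like (all-aqueous) composition has Kp = 1."""
        plasma_like = Organ(
            name="plasma_like", volume_l_kg=0.01, flow_ml_min_kg=1.0,
            composition=TissueComposition(f_ew=1.0, f_iw=0.0, f_nl=0.0, f_np=0.0, ap_mg_g=0.0),
        )
        phys = dataclasses.replace(
            rat_physiology,
            organs={**rat_physiology.organs, "plasma_like": plasma_like},
        )
        card = _neutral_card(logp=0.0)
        assert rodgers_rowland_kp(card, phys, "plasma_like", fup=1.0) == pytest.approx(1.0)

    def test_base_equations_match_independent_transcription(self, rat_physiology, compound):
        """Muscle Kp for the moderate-to-strong base card equals a separately
        written-out evaluation of the same equations."""
        fup, bp, hct = 0.61, 1.0, rat_physiology.hematocrit
        p = 10.0**compound.logp
        x_p = 10.0 ** (compound.pka - 7.4)
        x_iw = 10.0 ** (compound.pka - 7.0)
        x_bc = 10.0 ** (compound.pka - 7.22)
        kpu_bc = (bp - (1 - hct)) / (hct * fup)
        bc = rat_physiology.erythrocyte_composition
        ka_ap = (
            kpu_bc
            - (1 + x_bc) / (1 + x_p) * bc.f_iw
            - (p * bc.f_nl + (0.3 * p + 0.7) * bc.f_np) / (1 + x_p)
        ) * (1 + x_p) / (bc.ap_mg_g * x_bc)
        m = rat_physiology.organ("muscle").composition
        kpu = (
            m.f_ew
            + m.f_iw * (1 + x_iw) / (1 + x_p)
            + ka_ap * m.ap_mg_g * x_iw / (1 + x_p)
            + (p * m.f_nl + (0.3 * p + 0.7) * m.f_np) / (1 + x_p)
        )
        assert rodgers_rowland_kp(
            compound, rat_physiology, "muscle", fup=fup
        ) == pytest.approx(kpu * fup, rel=1e-12)

    def test_partition_set_deterministic_and_positive(self, rat_physiology, compound):
        a = partition_set(compound, rat_physiology, fup=0.61)
        b = partition_set(compound, rat_physiology, fup=0.61)
        assert a == b
        assert all(v > 0 for v in a.values())

    def test_unknown_organ_raises(self, rat_physiology, compound):
        from preclinpk.errors import LookupError_

        with pytest.raises(LookupError_, match="pancreas"):
            rodgers_rowland_kp(compound, rat_physiology, "pancreas", fup=0.61)


def _uniform_model(phys, clint=0.0, renal=0.0, flow_scale=1.0, fa=1.0, ka=5.0):
    if flow_scale != 1.0:
        organs = {
            n: dataclasses.replace(o, flow_ml_min_kg=o.flow_ml_min_kg * flow_scale)
            for n, o in phys.organs.items()
        }
        phys = dataclasses.replace(
            phys, organs=organs,
            cardiac_output_ml_min_kg=phys.cardiac_output_ml_min_kg * flow_scale,
        )
    card = _neutral_card(logp=0.0)
    return build_model(
        card, phys,
        clint_scaled_ml_min_kg=clint, renal_cl_ml_min_kg=renal,
        ka_per_h=ka, fa=fa, fup=1.0, fu_hep=1.0,
        kp_override={n: 1.0 for n in phys.organs},
    )


class TestSimulator:
    def test_zero_dose_gives_zero_trajectories(self, rat_physiology):
        model = _uniform_model(rat_physiology, clint=10.0, renal=5.0)
        sim = simulate(model, DoseScenario(route=Route.iv_bolus, dose_mg=0.0, duration_h=2))
        assert sim.cmax == 0.0
        assert np.allclose(sim.amounts.drop(columns="time_h"), 0.0)

    def test_conservation_without_clearance(self, rat_physiology):
        """With uniform Kp and no elimination, plasma equilibrates at
        dose / (total volume of the flow-connected system)."""
        model = _uniform_model(rat_physiology)
        dose = 2.5
        sim = simulate(model, DoseScenario(route=Route.iv_bolus, dose_mg=dose, duration_h=48))
        assert sim.non_eliminating
        phys = model.physiology
        v_total = (
            sum(o.volume_l_kg for o in phys.organs.values())
            + phys.arterial_volume_l_kg + phys.venous_volume_l_kg
        ) * phys.body_weight_kg
        expected_ng_ml = dose / v_total * 1000
        assert sim.plasma_conc_ng_ml[-1] == pytest.approx(expected_ng_ml, rel=1e-3)

    def test_mass_balance_within_1e6_at_all_times(self, rat_physiology, compound):
        model, _ = rat_reference_model(ka_per_h=2.0)
        for route, dose in ((Route.oral, 6.25), (Route.iv_bolus, 2.5)):
            sim = simulate(model, DoseScenario(route=route, dose_mg=dose, duration_h=12))
            assert sim.mass_balance_error < 1e-6

    def test_dose_linearity(self, rat_physiology):
        model = _uniform_model(rat_physiology, clint=20.0, renal=10.0)
        lo = simulate(model, DoseScenario(route=Route.oral, dose_mg=1.0, duration_h=12))
        hi = simulate(model, DoseScenario(route=Route.oral, dose_mg=2.0, duration_h=12))
        assert hi.cmax == pytest.approx(2 * lo.cmax, rel=1e-5)
        assert hi.auc == pytest.approx(2 * lo.auc, rel=1e-5)

    def test_solver_self_convergence(self, rat_physiology):
        model = _uniform_model(rat_physiology, clint=20.0, renal=10.0)
        scen = DoseScenario(route=Route.oral, dose_mg=2.5, duration_h=12)
        coarse = simulate(model, scen, rtol=1e-6, atol=1e-9)
        fine = simulate(model, scen, rtol=5e-7, atol=5e-10)
        assert fine.auc == pytest.approx(coarse.auc, rel=1e-3)

    def test_one_compartment_limit_recovers_cl_and_v(self, rat_physiology):
        """With flows >> clearance and uniform Kp the system collapses to one
        compartment; NCA on the simulated curve recovers CL and V within 5%."""
        clint, renal = 20.0, 10.0  # mL/min/kg; CLh ~= CLint when Q >> CLint
        model = _uniform_model(rat_physiology, clint=clint, renal=renal, flow_scale=1000.0)
        q = model.physiology.hepatic_flow_ml_min_kg
        cl_expected = (q * clint / (q + clint) + renal) * 60 / 1000  # L/h/kg
        v_expected = model.vss_l_kg()
        dose_mg_kg = 10.0
        sim = simulate(
            model,
            DoseScenario(route=Route.iv_bolus,
                         dose_mg=dose_mg_kg * model.physiology.body_weight_kg,
                         duration_h=4),
        )
        mask = sim.time_h > 0
        prof = ConcTimeProfile(
            subject_id="limit", species=Species.rat,
            dose=DoseEvent(route=Route.iv_bolus, dose_per_bw=dose_mg_kg),
            samples=[
                Sample(time=float(t), conc=float(c))
                for t, c in zip(sim.time_h[mask][::5], sim.plasma_conc_ng_ml[mask][::5])
            ],
        )
        res = run_nca(prof)
        assert res.cl == pytest.approx(cl_expected, rel=0.05)
        assert res.vz == pytest.approx(v_expected, rel=0.05)

    def test_simulation_is_deterministic(self, rat_physiology):
        model, _ = rat_reference_model(ka_per_h=2.0)
        scen = DoseScenario(route=Route.oral, dose_mg=6.25, duration_h=12)
        a = simulate(model, scen)
        b = simulate(model, scen)
        assert np.array_equal(a.plasma_conc_ng_ml, b.plasma_conc_ng_ml)
        assert a.amounts.equals(b.amounts)

    def test_inconsistent_flow_topology_rejected(self, rat_physiology):
        organs = dict(rat_physiology.organs)
        organs["lung"] = dataclasses.replace(organs["lung"], flow_ml_min_kg=100.0)
        broken = dataclasses.replace(rat_physiology, organs=organs)
        card = _neutral_card(logp=0.0)
        with pytest.raises(ConstructionError, match="cardiac output"):
            build_model(card, broken, clint_scaled_ml_min_kg=0.0,
                        renal_cl_ml_min_kg=0.0, fup=1.0,
                        kp_override={n: 1.0 for n in organs})

    def test_ka_fit_reproduces_target_tmax(self, rat_physiology):
        model, config = rat_reference_model(ka_per_h=None)
        sim = simulate(
            model,
            DoseScenario(route=Route.oral, dose_mg=6.25, duration_h=6),
        )
        # pooled observed oral peak times average ~0.39 h
        assert sim.tmax == pytest.approx(0.389, abs=0.05)


class TestValidation:
    def test_equal_prediction_passes_and_boundary_fails(self):
        assert ScenarioComparison("s", "cmax", 1.0, 1.0).passed
        assert not ScenarioComparison("s", "cmax", 2.01, 1.0).passed
        assert ScenarioComparison("s", "auc", 0.5, 1.0).passed

    def test_unmatched_scenario_raises(self, rat_physiology):
        model, _ = rat_reference_model(ka_per_h=2.0)
        sim = simulate(
            model,
            DoseScenario(route=Route.oral, dose_mg=2.5, duration_h=2, label="odd"),
        )
        with pytest.raises(PairingError):
            validate_against_observed([sim], {"other": {"cmax": 1, "auc": 1}})

    def test_rat_reference_validation_passes(self, rat_validation_report):
        """Under the recorded configuration every predicted/observed fold ratio
        for Cmax and AUC at 10/25/50 mg/kg lies within [0.5, 2.0]."""
        assert len(rat_validation_report.comparisons) == 6
        assert rat_validation_report.overall_pass
        for c in rat_validation_report.comparisons:
            assert 0.5 <= c.fold_ratio <= 2.0


class TestHumanEscalation:
    def test_seven_doses_sorted_and_linear(self):
        model, config = human_reference_model(rat_config={
            "renal_cl_ml_min_kg": 36.9, "ka_per_h": 2.0,
        })
        sims, summary = human_dose_escalation(
            model, doses_mg=[150, 5, 30, 15, 50, 120, 80], duration_h=24.0
        )
        assert list(summary["dose_mg"]) == [5, 15, 30, 50, 80, 120, 150]
        # linear model: AUC ratios equal dose ratios
        assert summary["auc_ratio_vs_lowest"].iloc[2] == pytest.approx(6.0, rel=1e-6)
        assert summary["auc_ratio_vs_lowest"].iloc[-1] == pytest.approx(30.0, rel=1e-6)

    def test_repeat_run_bit_identical(self):
        model, _ = human_reference_model(rat_config={
            "renal_cl_ml_min_kg": 36.9, "ka_per_h": 2.0,
        })
        s1, _ = human_dose_escalation(model, doses_mg=[30.0], duration_h=6.0)
        s2, _ = human_dose_escalation(model, doses_mg=[30.0], duration_h=6.0)
        assert np.array_equal(s1[0].plasma_conc_ng_ml, s2[0].plasma_conc_ng_ml)
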