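"""Hazard bridge, profile updates, treatment rules, traces and coefficient draws."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_profiles
from lifecea.microsim import (
    EventTable,
    RiskEquation,
    SimulationConfig,
    annual_event_probability,
    default_event_tables,
    default_risk_equations,
    draw_coefficients,
    equations_from_frame,
    equations_to_frame,
    simulate_cohort,
    simulate_patient,
    treatment_rule,
    update_profile,
)

BASE_VALUES = {
    "age": 60.0, "diabetes_duration": 10.0, "female": 0.0, "smoking_current": 0.0,
    "hba1c": 8.0, "sbp": 135.0, "ldl": 2.3, "hdl": 1.1, "bmi": 32.0,
    "heart_rate": 72.0, "egfr": 76.0, "on_treatment": 0.0,
    **{f"history_{e}": 0.0 for e in
       ("ischaemic_heart_disease", "myocardial_infarction", "heart_failure", "stroke",
        "amputation", "blindness", "renal_failure", "foot_ulcer")},
}

EMPTY_TABLES = EventTable({}, {}, {}, {}, 0.0, 0.0, 0.0)


class TestAnnualProbability:
    def test_exponential_closed_form(self):
        eq = RiskEquation("stroke", "exponential", {"intercept": math.log(0.05)})
        p = annual_event_probability(eq, BASE_VALUES)
        assert p == pytest.approx(1 - math.exp(-0.05))

    def test_vanishing_hazard(self):
        eq = RiskEquation("stroke", "exponential", {"intercept": -745.0})
        assert annual_event_probability(eq, BASE_VALUES) == pytest.approx(0.0, abs=1e-300)

    @pytest.mark.parametrize("duration", [0.0, 3.0, 17.5])
    def test_weibull_shape_one_nests_exponential(self, duration):
        coeffs = {"intercept": math.log(0.02), "hba1c": 0.1}
        vals = dict(BASE_VALUES, diabetes_duration=duration)
        w = RiskEquation("stroke", "weibull", coeffs, shape=1.0, centering={"hba1c": 8.0})
        e = RiskEquation("stroke", "exponential", coeffs, centering={"hba1c": 8.0})
        assert annual_event_probability(w, vals) == pytest.approx(
            annual_event_probability(e, vals)
        )

    def test_logistic_direct_probability(self):
        eq = RiskEquation("foot_ulcer", "logistic", {"intercept": 0.0})
        assert annual_event_probability(eq, BASE_VALUES) == pytest.approx(0.5)

    def test_small_hazard_bridge(self):
        for lam in (0.001, 0.01):
            eq = RiskEquation("stroke", "exponential", {"intercept": math.log(lam)})
            p = annual_event_probability(eq, BASE_VALUES)
            assert abs(p - lam) / lam < 0.01

    def test_missing_term_reported(self):
        eq = RiskEquation("stroke", "exponential", {"intercept": 0.0, "egfr": 0.1})
        with pytest.raises(ValueError, match="egfr"):
            annual_event_probability(eq, {"age": 60.0})

    def test_probability_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for eq in default_risk_equations():
            for _ in range(20):
                vals = dict(BASE_VALUES)
                for k in ("hba1c", "sbp", "egfr", "bmi", "ldl", "hdl", "age"):
                    vals[k] = vals[k] * rng.uniform(0.5, 1.5)
                p = annual_event_probability(eq, vals)
                assert 0.0 <= p <= 1.0


class TestUpdateProfile:
    def test_constant_mode(self):
        vals = dict(BASE_VALUES)
        out = vals
        for _ in range(10):
            out = update_profile(out, "constant")
        assert out["age"] == 70.0
        assert out["diabetes_duration"] == 20.0
        assert out["hba1c"] == 8.0  # held constant

    def test_linear_drift(self):
        out = dict(BASE_VALUES)
        for _ in range(10):
            out = update_profile(out, "linear-drift", {"sbp": 0.1})
        assert out["sbp"] == pytest.approx(136.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            update_profile(dict(BASE_VALUES), "warp")


class TestTreatmentRule:
    CFG = SimulationConfig(seed=1)
    TAB = EventTable({}, {}, {}, {}, 0.0, 500.0, 100.0, doses_per_year=52.0)

    def test_base_case_cost(self):
        on, cost = treatment_rule(True, "active", set(), 0, self.CFG, self.TAB, 0.8)
        assert on
        assert cost == pytest.approx(500.0 + 100.0 * 52 * 0.8)

    def test_control_gets_standard_care_only(self):
        on, cost = treatment_rule(True, "control", set(), 0, self.CFG, self.TAB, 0.8)
        assert not on and cost == 500.0

    def test_renal_failure_switches_to_standard_care(self):
        on, cost = treatment_rule(
            True, "active", {"renal_failure"}, 4, self.CFG, self.TAB, 0.8
        )
        assert not on and cost == 500.0

    def test_scenario1_stops_everyone(self):
        cfg = SimulationConfig(discontinuation_scenario="scenario1", seed=1)
        on, cost = treatment_rule(True, "active", set(), 0, cfg, self.TAB, 1.0)
        assert not on and cost == 500.0

    def test_scenario2_zero_rate_nests_base(self, small_cohort):
        """With stop rate 0 the scenario-2 trace equals the base-case trace."""
        eqs = default_risk_equations()
        tab = default_event_tables("US")
        prof = make_profiles(1, arm_split=False).assign(arm="active").iloc[0].to_dict()
        base_cfg = SimulationConfig(horizon=20, seed=9)
        s2_cfg = SimulationConfig(
            horizon=20, seed=9, discontinuation_scenario="scenario2",
            scenario2_annual_stop_rate=0.0,
        )
        tr1, tot1 = simulate_patient(prof, eqs, tab, base_cfg, np.random.default_rng(33))
        tr2, tot2 = simulate_patient(prof, eqs, tab, s2_cfg, np.random.default_rng(33))
        assert tot1 == tot2
        assert [t.events for t in tr1] == [t.events for t in tr2]


class TestSimulatePatient:
    def _zero_hazard_eqs(self):
        return [RiskEquation("death", "exponential", {"intercept": -745.0})]

    def test_event_free_accrual(self):
        cfg = SimulationConfig(
            horizon=40, discount_rate_cost=0.0, discount_rate_effect=0.0,
            seed=1, age_cap=200.0,
        )
        prof = make_profiles(1, arm_split=False).iloc[0].to_dict()
        traces, totals = simulate_patient(
            prof, self._zero_hazard_eqs(), EMPTY_TABLES, cfg, np.random.default_rng(0)
        )
        assert len(traces) == 40
        assert totals["life_years"] == pytest.approx(40.0)
        assert totals["qalys"] == pytest.approx(40.0 * 0.8)

    def test_annuity_discounted_life_years(self):
        cfg = SimulationConfig(
            horizon=40, discount_rate_cost=0.035, discount_rate_effect=0.035,
            seed=1, age_cap=200.0, discount_clock="from-trial-end",
        )
        prof = make_profiles(1, arm_split=False).iloc[0].to_dict()
        _, totals = simulate_patient(
            prof, self._zero_hazard_eqs(), EMPTY_TABLES, cfg, np.random.default_rng(0)
        )
        annuity = sum(1.035**-k for k in range(40))
        assert totals["life_years"] == pytest.approx(annuity, abs=1e-9)

    def test_discount_clock_offset(self):
        """From-randomization clock scales everything by (1+r)^-followup."""
        prof = make_profiles(1, arm_split=False).iloc[0].to_dict()
        prof["followup_years"] = 3.0
        base = SimulationConfig(
            horizon=10, discount_rate_cost=0.03, discount_rate_effect=0.03,
            seed=1, age_cap=200.0, discount_clock="from-trial-end",
        )
        offset = SimulationConfig(
            horizon=10, discount_rate_cost=0.03, discount_rate_effect=0.03,
            seed=1, age_cap=200.0, discount_clock="from-randomization",
        )
        _, t0 = simulate_patient(prof, self._zero_hazard_eqs(), EMPTY_TABLES, base,
                                 np.random.default_rng(0))
        _, t1 = simulate_patient(prof, self._zero_hazard_eqs(), EMPTY_TABLES, offset,
                                 np.random.default_rng(0))
        assert t1["life_years"] == pytest.approx(t0["life_years"] * 1.03**-3)

    def test_mortality_only_geometric_sum(self):
        lam = 0.1
        eqs = [RiskEquation("death", "exponential", {"intercept": math.log(lam)})]
        cfg = SimulationConfig(
            horizon=150, discount_rate_cost=0.0, discount_rate_effect=0.0,
            seed=2, age_cap=500.0, discount_clock="from-trial-end",
        )
        prof = make_profiles(8000, arm_split=False)
        out = simulate_cohort(prof, [eqs], EMPTY_TABLES, cfg)
        expected = sum(math.exp(-lam * k) for k in range(150))
        got = out["life_years_undiscounted"].iloc[0]
        se = 9.5 / math.sqrt(8000)  # sd of the geometric lifetime ~ 1/p
        assert abs(got - expected) < 3 * se

    def test_forced_renal_failure_stops_drug(self):
        """Certain renal failure in year 0 stops drug cost from year 1."""
        eqs = [
            RiskEquation("death", "exponential", {"intercept": -745.0}),
            RiskEquation("renal_failure", "exponential", {"intercept": 10.0}),  # p ~ 1
        ]
        tab = EventTable({}, {}, {}, {}, 0.0, 0.0, 100.0, doses_per_year=52.0)
        cfg = SimulationConfig(horizon=5, discount_rate_cost=0.0,
                               discount_rate_effect=0.0, seed=1, age_cap=200.0)
        prof = make_profiles(1, arm_split=False).assign(arm="active").iloc[0].to_dict()
        traces, totals = simulate_patient(prof, eqs, tab, cfg, np.random.default_rng(1))
        assert traces[0].on_study_drug
        assert "renal_failure" in traces[0].events
        assert all(not t.on_study_drug for t in traces[1:])
        assert totals["cost_therapy"] == pytest.approx(100.0 * 52)

    def test_monotone_in_hazard_under_coupling(self):
        """Raising the mortality intercept cannot raise expected life-years."""
        cfg = SimulationConfig(horizon=60, discount_rate_cost=0.0,
                               discount_rate_effect=0.0, seed=5, age_cap=500.0)
        prof = make_profiles(2000, arm_split=False)
        lows = simulate_cohort(
            prof, [[RiskEquation("death", "exponential", {"intercept": math.log(0.05)})]],
            EMPTY_TABLES, cfg)
        highs = simulate_cohort(
            prof, [[RiskEquation("death", "exponential", {"intercept": math.log(0.08)})]],
            EMPTY_TABLES, cfg)
        assert highs["life_years_undiscounted"].iloc[0] < lows["life_years_undiscounted"].iloc[0]

    def test_qalys_bounded_by_life_years(self, small_cohort):
        eqs = default_risk_equations()
        tab = default_event_tables("US")
        cfg = SimulationConfig(horizon=30, seed=3)
        prof = make_profiles(50)
        out = simulate_cohort(prof, [eqs], tab, cfg)
        assert (out["qalys"] <= out["life_years"] + 1e-12).all()
        assert (out["life_years"] <= out["life_years_undiscounted"] + 1e-12).all()


class TestSimulateCohort:
    def test_identical_arms_difference_exactly_zero(self):
        eqs = default_risk_equations()
        # strip the treatment effect so arms are exchangeable
        eqs = [
            RiskEquation(e.name, e.form,
                         {k: (0.0 if k == "on_treatment" else v)
                          for k, v in e.coefficients.items()},
                         shape=e.shape, centering=e.centering)
            for e in eqs
        ]
        tab = default_event_tables("US")
        tab.study_drug_price_per_dose = 0.0  # arm-identical therapy costs
        cfg = SimulationConfig(horizon=25, seed=6)
        prof = make_profiles(200)
        out = simulate_cohort(prof, [eqs], tab, cfg).set_index("arm")
        for col in ("life_years", "qalys", "cost_total"):
            assert out.loc["active", col] == pytest.approx(out.loc["control", col], abs=1e-12)

    def test_single_patient_consistency(self):
        eqs = default_risk_equations()
        tab = default_event_tables("UK")
        cfg = SimulationConfig(horizon=15, seed=8)
        prof = make_profiles(1, arm_split=False)
        out = simulate_cohort(prof, [eqs], tab, cfg)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
        _, totals = simulate_patient(prof.iloc[0].to_dict(), eqs, tab, cfg, rng)
        assert out["qalys"].iloc[0] == pytest.approx(totals["qalys"])
        assert out["cost_total"].iloc[0] == pytest.approx(totals["cost_total"])

    def test_treatment_effect_sign_stable_across_draws(self):
        lam = 0.08
        eqs = [
            RiskEquation(
                "death", "exponential",
                {"intercept": math.log(lam), "on_treatment": math.log(0.8)},
            )
        ]
        cfg = SimulationConfig(horizon=60, discount_rate_cost=0.0,
                               discount_rate_effect=0.0, seed=10, age_cap=500.0)
        cov = pd.DataFrame(
            np.diag([1e-4, 1e-4]),
            index=["death:intercept", "death:on_treatment"],
            columns=["death:intercept", "death:on_treatment"],
        )
        sets = draw_coefficients(eqs, cov, 40, seed=11)
        prof = make_profiles(5000).assign(compliance=1.0)
        tab = EMPTY_TABLES
        out = simulate_cohort(prof, sets, tab, cfg)
        wide = out.pivot(index="draw", columns="arm", values="life_years_undiscounted")
        diff = wide["active"] - wide["control"]
        assert diff.mean() > 0
        assert (diff > 0).mean() >= 0.95

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(pd.DataFrame(), [[]], EMPTY_TABLES, SimulationConfig(seed=1))


class TestDrawCoefficients:
    def test_zero_covariance_reproduces_point(self):
        eqs = default_risk_equations()
        sets = draw_coefficients(eqs, None, 5, seed=1)
        assert len(sets) == 6
        for s in sets[1:]:
            for a, b in zip(s, sets[0]):
                assert a.coefficients == b.coefficients

    def test_draw_count_contract(self):
        eqs = default_risk_equations()[:2]
        labels = [f"{e.name}:{t}" for e in eqs for t in e.coefficients]
        cov = pd.DataFrame(np.eye(len(labels)) * 1e-6, index=labels, columns=labels)
        sets = draw_coefficients(eqs, cov, 800, seed=2)
        assert len(sets) == 801

    def test_diagonal_variance_recovered(self):
        eq = [RiskEquation("death", "exponential", {"intercept": -3.0, "age": 0.1})]
        labels = ["death:intercept", "death:age"]
        cov = pd.DataFrame(np.eye(2) * 0.01, index=labels, columns=labels)
        sets = draw_coefficients(eq, cov, 10000, seed=3)
        draws = np.array([[s[0].coefficients[t] for t in ("intercept", "age")] for s in sets[1:]])
        for j in range(2):
            assert abs(draws[:, j].var() - 0.01) / 0.01 < 0.05

    def test_non_psd_rejected(self):
        eq = [RiskEquation("death", "exponential", {"intercept": -3.0, "age": 0.1})]
        labels = ["death:intercept", "death:age"]
        cov = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=labels, columns=labels)
        with pytest.raises(ValueError, match="positive semi-definite"):
            draw_coefficients(eq, cov, 10, seed=4)


def test_equation_csv_round_trip():
    eqs = default_risk_equations()
    again = equations_from_frame(equations_to_frame(eqs))
    assert len(again) == len(eqs)
    by_name = {e.name: e for e in again}
    for eq in eqs:
        other = by_name[eq.name]
        assert other.form == eq.form
        assert other.coefficients == dict(eq.coefficients)
        assert dict(other.centering) == dict(eq.centering)
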