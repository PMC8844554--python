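"""Valuation, AUC QALYs, discounting, baseline adjustment and costing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lifecea.economics import (
    CostingConfig,
    auc_qalys,
    baseline_adjust,
    ancova_difference,
    cost_within_trial,
    discount,
)
from lifecea.valuation import (
    CrosswalkMap,
    ValueSet,
    default_value_set,
    value_profile,
    value_set_from_frame,
    value_set_to_frame,
)


class TestValuation:
    def test_full_health_anchor(self):
        for country in ("US", "UK"):
            vs = default_value_set(country)
            assert value_profile((1, 1, 1, 1, 1), "EQ5D3L", vs) == 1.0
            assert value_profile((1, 1, 1, 1, 1), "EQ5D5L", vs, CrosswalkMap()) == 1.0

    def test_flat_decrement_lookup(self, flat_value_set):
        assert value_profile((2, 1, 1, 1, 1), "EQ5D3L", flat_value_set) == pytest.approx(0.9)
        assert value_profile((3, 2, 1, 1, 1), "EQ5D3L", flat_value_set) == pytest.approx(0.7)

    def test_floor_bounds_all_profiles(self):
        vs = default_value_set("UK")
        xw = CrosswalkMap()
        values = [
            value_profile(tuple(x + 1 for x in idx), "EQ5D3L", vs)
            for idx in np.ndindex(3, 3, 3, 3, 3)
        ]
        assert min(values) == pytest.approx(vs.floor)
        assert max(values) == 1.0
        assert all(vs.floor <= v <= 1.0 for v in values)
        # 5L crosswalked values stay within the 3L range
        v5 = value_profile((5, 5, 5, 5, 5), "EQ5D5L", vs, xw)
        assert v5 == pytest.approx(vs.floor)

    def test_out_of_range_levels_rejected(self):
        vs = default_value_set("US")
        with pytest.raises(ValueError):
            value_profile((4, 1, 1, 1, 1), "EQ5D3L", vs)
        with pytest.raises(ValueError):
            value_profile((6, 1, 1, 1, 1), "EQ5D5L", vs, CrosswalkMap())

    def test_csv_round_trip(self):
        vs = default_value_set("UK")
        again = value_set_from_frame(value_set_to_frame(vs), name=vs.name)
        for profile in ((1, 1, 1, 1, 1), (2, 3, 1, 2, 3), (3, 3, 3, 3, 3)):
            assert again.value(profile) == vs.value(profile)


class TestAucQalys:
    def test_constant_utility(self):
        assert auc_qalys([0.0], [0.8], 1.0) == pytest.approx(0.8)
        assert auc_qalys([0.0], [0.75], 4.0) == pytest.approx(3.0)

    def test_trapezoid_to_death(self):
        got = auc_qalys([0.0, 2.0], [1.0, 0.0], 2.0, death_time=2.0)
        assert got == pytest.approx(1.0)

    def test_carry_forward_vs_truncate(self):
        t, u = [0.0, 1.0], [0.8, 0.6]
        assert auc_qalys(t, u, 3.0, tail="carry-forward") == pytest.approx(0.7 + 2 * 0.6)
        assert auc_qalys(t, u, 3.0, tail="truncate") == pytest.approx(0.7)

    def test_death_after_last_observation_flat_then_zero(self):
        # flat at 0.5 from t=1 until death at 2.5; no interpolation across death
        got = auc_qalys([0.0, 1.0], [0.5, 0.5], 4.0, death_time=2.5)
        assert got == pytest.approx(0.5 * 2.5)

    def test_zero_utility_gives_zero(self):
        assert auc_qalys([0.0, 1.0], [0.0, 0.0], 1.0) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            auc_qalys([], [], 1.0)
        with pytest.raises(ValueError):
            auc_qalys([0.0, 3.0], [1.0, 1.0], 2.0)  # observation beyond follow-up

    @staticmethod
    def _grid_oracle(t, u, end, rate, dt=1e-4):
        """Independent fine-grid numerical integral of the same curve."""
        grid = np.arange(0.0, end, dt) + dt / 2
        tt = np.concatenate([t, [end]])
        uu = np.concatenate([u, [u[-1]]])
        vals = np.interp(grid, tt, uu)
        weights = (1.0 + rate) ** -np.floor(grid)
        return float((vals * weights).sum() * dt)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_matches_fine_grid_integral(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        k = rng.integers(2, 7)
        t = np.sort(rng.uniform(0, 6, size=k))
        t[0] = 0.0
        u = rng.uniform(0, 1, size=k)
        end = t[-1] + rng.uniform(0, 1)
        rate = float(rng.choice([0.0, 0.03, 0.035]))
        got = auc_qalys(t, u, end, discount_rate=rate)
        want = self._grid_oracle(t, u, end, rate)
        assert got == pytest.approx(want, abs=2e-4)


class TestDiscount:
    @pytest.mark.parametrize(
        "amount,year,rate,expected",
        [
            (100.0, 0, 0.035, 100.0),
            (100.0, 1, 0.035, 100 / 1.035),
            (123.0, 7, 0.0, 123.0),
        ],
    )
    def test_values(self, amount, year, rate, expected):
        assert discount(amount, year, rate) == pytest.approx(expected)

    def test_negative_year_rejected(self):
        with pytest.raises(ValueError):
            discount(1.0, -1, 0.03)


class TestBaselineAdjust:
    def test_balanced_baseline_equals_raw(self):
        rng = np.random.default_rng(2)
        n = 2000
        base = np.tile(rng.uniform(0.5, 1.0, n // 2), 2)
        arm = np.repeat(["active", "control"], n // 2)
        q = 2.0 + 0.5 * (arm == "active") + 1.5 * base + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"arm": arm, "qalys": q, "baseline_utility": base})
        res = baseline_adjust(df)
        assert res.difference == pytest.approx(res.raw_difference, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        # constructed n=6 dataset with baseline imbalance
        df = pd.DataFrame(
            {
                "arm": ["active"] * 3 + ["control"] * 3,
                "qalys": [2.0, 2.5, 3.0, 1.0, 1.5, 2.5],
                "baseline_utility": [0.9, 0.8, 0.95, 0.5, 0.6, 0.7],
            }
        )
        a = (df.arm == "active").to_numpy(float)
        b = df.baseline_utility.to_numpy()
        X = np.column_stack([np.ones(6), a, b - b.mean()])
        beta = np.linalg.solve(X.T @ X, X.T @ df.qalys.to_numpy())
        res = baseline_adjust(df)
        assert res.difference == pytest.approx(beta[1], rel=1e-10)
        assert res.adjusted_mean_control == pytest.approx(beta[0], rel=1e-10)
        assert ancova_difference(df.qalys.to_numpy(), b, a) == pytest.approx(beta[1], rel=1e-10)

    def test_unrelated_baseline_leaves_difference(self):
        rng = np.random.default_rng(5)
        n = 5000
        arm = rng.choice(["active", "control"], n)
        base = rng.uniform(0.5, 1.0, n)
        q = 2.0 + 0.3 * (arm == "active") + rng.normal(0, 0.2, n)
        df = pd.DataFrame({"arm": arm, "qalys": q, "baseline_utility": base})
        res = baseline_adjust(df)
        assert res.difference == pytest.approx(res.raw_difference, abs=0.02)

    def test_single_arm_rejected(self):
        df = pd.DataFrame(
            {"arm": ["active"] * 3, "qalys": [1.0, 2, 3], "baseline_utility": [0.5, 0.6, 0.7]}
        )
        with pytest.raises(ValueError):
            baseline_adjust(df)


class TestCosting:
    def _patients(self, ids):
        return pd.DataFrame({"patient_id": ids})

    def test_us_dose_price(self):
        cfg = CostingConfig.default("US")
        ru = pd.DataFrame(
            {
                "patient_id": ["a"],
                "period_start": [0.0],
                "period_end": [1.0],
                "inpatient_days": [0],
                "outpatient_visits": [0],
                "oral_antidiabetic_units": [0],
                "other_medication_units": [0],
                "study_drug_doses": [10],
            }
        )
        out = cost_within_trial(ru, self._patients(["a"]), cfg)
        assert out.loc[0, "therapy_cost"] == pytest.approx(1197.00)
        assert out.loc[0, "other_cost"] == 0.0

    def test_wholesale_price_inversion(self):
        cfg = CostingConfig.default("US")
        assert cfg.implied_wholesale_price == pytest.approx(119.70 / 0.769)
        assert cfg.implied_wholesale_price == pytest.approx(155.66, abs=0.01)
        assert cfg.implied_wholesale_price * (1 - cfg.wholesale_discount) == pytest.approx(
            cfg.study_drug_price_per_dose
        )

    def test_zero_resource_use(self):
        cfg = CostingConfig.default("UK")
        ru = pd.DataFrame(
            {
                "patient_id": ["a"],
                "period_start": [0.0],
                "period_end": [1.0],
                "inpatient_days": [0],
                "outpatient_visits": [0],
                "oral_antidiabetic_units": [0],
                "other_medication_units": [0],
                "study_drug_doses": [0],
            }
        )
        out = cost_within_trial(ru, self._patients(["a"]), cfg)
        assert out.loc[0, "total_cost"] == 0.0

    def test_discounting_and_additivity(self, small_cohort):
        _, data = small_cohort
        cfg = CostingConfig.default("US")
        out = cost_within_trial(data.resource_use, data.patients, cfg)
        undisc = cost_within_trial(
            data.resource_use,
            data.patients,
            CostingConfig("US", 2017, dict(cfg.unit_costs), cfg.study_drug_price_per_dose, 0.231, 0.0),
        )
        assert (out["total_cost"] <= undisc["total_cost"] + 1e-9).all()
        np.testing.assert_allclose(
            out["total_cost"], out["therapy_cost"] + out["other_cost"], rtol=1e-12
        )
        # additivity over a split of the resource table
        half = len(data.resource_use) // 2
        p1 = cost_within_trial(data.resource_use.iloc[:half], data.patients, cfg)
        p2 = cost_within_trial(data.resource_use.iloc[half:], data.patients, cfg)
        merged = (
            p1.set_index("patient_id")[["total_cost"]]
            .add(p2.set_index("patient_id")[["total_cost"]], fill_value=0.0)
        )
        np.testing.assert_allclose(
            out.set_index("patient_id")["total_cost"].sort_index(),
            merged["total_cost"].sort_index(),
            rtol=1e-12,
        )

    def test_unknown_category_rejected(self):
        cfg = CostingConfig("US", 2017, {"inpatient_days": (1.0, "other")}, 1.0, 0.0, 0.0)
        ru = pd.DataFrame(
            {
                "patient_id": ["a"],
                "period_start": [0.0],
                "period_end": [1.0],
                "inpatient_days": [1],
                "helicopter_rides": [2],
                "study_drug_doses": [0],
            }
        )
        with pytest.raises(ValueError, match="helicopter"):
            cost_within_trial(ru, self._patients(["a"]), cfg)
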