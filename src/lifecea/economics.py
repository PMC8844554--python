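"""Within-trial QALYs and costs.

QALYs follow the area-under-the-curve convention: utility is piecewise
linear between observed visit values, carried flat from the last observation
to censoring, and drops to zero at death (no interpolation across death).
Costs split into therapy costs (study drug + concomitant diabetes
medications) and other costs (other medications, visits, hospitalisations);
both are discounted annually by year of accrual, with year 0 undiscounted.

The arm comparison of QALYs is adjusted for baseline utility with a linear
model (cost comparisons are unadjusted arm means), guarding against chance
baseline imbalance in health-related quality of life.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm


def _default_unit_costs(country: str) -> dict[str, tuple[float, str]]:
    # name -> (unit cost, cost bucket: "therapy" for diabetes meds, else "other")
    if country == "US":
        return {
            "inpatient_days": (2500.0, "other"),
            "outpatient_visits": (150.0, "other"),
            "oral_antidiabetic_units": (0.55, "therapy"),
            "other_medication_units": (0.80, "other"),
        }
    return {
        "inpatient_days": (650.0, "other"),
        "outpatient_visits": (50.0, "other"),
        "oral_antidiabetic_units": (0.10, "therapy"),
        "other_medication_units": (0.25, "other"),
    }


@dataclass
class CostingConfig:
    """Country-specific prices and discounting.

    ``study_drug_price_per_dose`` is the net acquisition price per weekly
    dose after any wholesale discount (US default 119.70 USD reflecting a
    23.1% discount on the wholesale price; UK default 18.94 GBP).
    """

    country: str = "US"
    reference_year: int = 2017
    unit_costs: Mapping[str, tuple[float, str]] = field(default_factory=dict)
    study_drug_price_per_dose: float = 119.70
    wholesale_discount: float = 0.231
    discount_rate: float = 0.03

    @classmethod
    def default(cls, country: str) -> "CostingConfig":
        if country == "US":
            return cls("US", 2017, _default_unit_costs("US"), 119.70, 0.231, 0.03)
        if country == "UK":
            return cls("UK", 2016, _default_unit_costs("UK"), 18.94, 0.0, 0.035)
        raise ValueError(f"no default costing for country {country!r}")

    @property
    def implied_wholesale_price(self) -> float:
        """Pre-discount wholesale price implied by the net price."""
        return self.study_drug_price_per_dose / (1.0 - self.wholesale_discount)

    def validate(self) -> None:
        if self.study_drug_price_per_dose < 0:
            raise ValueError("prices must be non-negative")
        if not 0 <= self.wholesale_discount < 1:
            raise ValueError("wholesale discount must lie in [0, 1)")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        for name, (c, bucket) in dict(self.unit_costs).items():
            if c < 0:
                raise ValueError(f"unit cost for {name} must be non-negative")
            if bucket not in ("therapy", "other"):
                raise ValueError(f"unknown cost bucket {bucket!r} for {name}")


def discount(amount: float, year_index: int, rate: float) -> float:
    """Present value of an amount accruing in ``year_index`` (year 0 undiscounted)."""
    if year_index < 0:
        raise ValueError("year_index must be non-negative")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return amount / (1.0 + rate) ** year_index


def auc_qalys(
    times: np.ndarray,
    utilities: np.ndarray,
    followup_end: float,
    death_time: float | None = None,
    discount_rate: float = 0.0,
    tail: str = "carry-forward",
) -> float:
    """Area under the piecewise-linear utility curve over follow-up.

    Utility is interpolated linearly between observations, held flat from the
    last observation to the end of follow-up (``tail='carry-forward'``; use
    ``'truncate'`` to stop at the last observation), and is zero from
    ``death_time`` onward.  With a positive ``discount_rate`` each year's
    area is discounted at (1+r)^-k, year 0 undiscounted.
    """
    times = np.asarray(times, dtype=float)
    utilities = np.asarray(utilities, dtype=float)
    if times.size == 0:
        raise ValueError("utility series is empty")
    if np.any(np.diff(times) < 0):
        raise ValueError("utility series must be time-sorted")
    if tail not in ("carry-forward", "truncate"):
        raise ValueError(f"unknown tail rule {tail!r}")
    end = followup_end if death_time is None else min(followup_end, death_time)
    if times[0] < 0 or times[-1] > followup_end + 1e-9:
        raise ValueError("observation times must lie within follow-up")

    keep = times <= end + 1e-12
    t = times[keep]
    u = utilities[keep]
    if t.size == 0:
        return 0.0
    # Vertices of the piecewise-linear curve on [t0, end].
    vt = list(t)
    vu = list(u)
    if vt[-1] < end:
        if tail == "carry-forward" or (death_time is not None and end == death_time):
            # flat tail; death drops utility to zero *at* the death time
            vt.append(end)
            vu.append(vu[-1])
        # 'truncate': integrate only up to the last observation
    vt_arr = np.array(vt)
    vu_arr = np.array(vu)

    if discount_rate == 0.0:
        return float(np.trapezoid(vu_arr, vt_arr))
    return _discounted_trapezoid(vt_arr, vu_arr, discount_rate)


def _discounted_trapezoid(t: np.ndarray, u: np.ndarray, rate: float) -> float:
    """Trapezoidal integral with per-year discount weights (year 0 undiscounted)."""
    # insert vertices at every integer year boundary crossed by the curve
    boundaries = np.arange(np.ceil(t[0]), np.floor(t[-1]) + 1)
    grid = np.unique(np.concatenate([t, boundaries]))
    vals = np.interp(grid, t, u)
    total = 0.0
    for a, b, ua, ub in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if b <= a:
            continue
        year = int(np.floor(a + 1e-12))
        area = 0.5 * (ua + ub) * (b - a)
        total += area / (1.0 + rate) ** year
    return float(total)


@dataclass
class BaselineAdjustment:
    """Result of the baseline-utility-adjusted arm comparison."""

    adjusted_mean_active: float
    adjusted_mean_control: float
    difference: float
    raw_difference: float
    baseline_coefficient: float


def baseline_adjust(
    df: pd.DataFrame,
    outcome: str = "qalys",
    baseline: str = "baseline_utility",
    arm: str = "arm",
) -> BaselineAdjustment:
    """Adjust arm means of an outcome for baseline utility via OLS.

    Fits ``outcome ~ arm + (baseline - mean(baseline))``; the adjusted means
    are the model predictions at the overall mean baseline utility.
    """
    arms = set(df[arm].unique())
    if arms != {"active", "control"}:
        raise ValueError("baseline adjustment needs both trial arms present")
    y = df[outcome].to_numpy(dtype=float)
    a = (df[arm] == "active").to_numpy(dtype=float)
    b = df[baseline].to_numpy(dtype=float)
    if np.isnan(b).any():
        raise ValueError("baseline utilities must be complete (impute first)")
    X = sm.add_constant(np.column_stack([a, b - b.mean()]))
    fit = sm.OLS(y, X).fit()
    const, beta_arm, beta_base = fit.params
    raw = y[a == 1].mean() - y[a == 0].mean()
    return BaselineAdjustment(
        adjusted_mean_active=float(const + beta_arm),
        adjusted_mean_control=float(const),
        difference=float(beta_arm),
        raw_difference=float(raw),
        baseline_coefficient=float(beta_base),
    )


def ancova_difference(y: np.ndarray, baseline: np.ndarray, active: np.ndarray) -> float:
    """Fast closed-form arm coefficient of ``y ~ arm + centred baseline``.

    Equivalent to :func:`baseline_adjust` (verified against it in tests);
    used inside the bootstrap loop where statsmodels overhead would dominate.
    """
    X = np.column_stack([np.ones_like(y), active, baseline - baseline.mean()])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


def cost_within_trial(
    resource_use: pd.DataFrame,
    patients: pd.DataFrame,
    config: CostingConfig,
) -> pd.DataFrame:
    """Per-patient within-trial therapy and other costs, discounted by accrual year.

    Therapy cost = study-drug doses x net per-dose price + concomitant
    diabetes-medication costs; everything else (hospitalisations, visits,
    non-diabetes medications) is 'other'.  Returns one row per patient with
    therapy_cost, other_cost and total_cost (= therapy + other exactly).
    """
    config.validate()
    unit_costs = dict(config.unit_costs) or _default_unit_costs(config.country)
    count_cols = [
        c
        for c in resource_use.columns
        if c not in ("patient_id", "period_start", "period_end", "study_drug_doses")
    ]
    unknown = [c for c in count_cols if c not in unit_costs]
    if unknown:
        raise ValueError(f"no unit cost configured for resource categories {unknown}")
    for c in count_cols + ["study_drug_doses"]:
        if (resource_use[c] < 0).any():
            raise ValueError(f"negative counts in resource category {c}")

    year = np.floor(resource_use["period_start"].to_numpy() + 1e-9).astype(int)
    dfactor = 1.0 / (1.0 + config.discount_rate) ** year
    study_drug = resource_use["study_drug_doses"].to_numpy() * config.study_drug_price_per_dose
    therapy = study_drug.copy()
    other = np.zeros(len(resource_use))
    for c in count_cols:
        cost, bucket = unit_costs[c]
        contrib = resource_use[c].to_numpy() * cost
        if bucket == "therapy":
            therapy = therapy + contrib
        else:
            other = other + contrib
    frame = pd.DataFrame(
        {
            "patient_id": resource_use["patient_id"],
            "therapy_cost": therapy * dfactor,
            "other_cost": other * dfactor,
            "study_drug_cost": study_drug * dfactor,
        }
    )
    out = frame.groupby("patient_id", as_index=False).sum()
    out = (
        patients[["patient_id"]]
        .merge(out, on="patient_id", how="left")
        .fillna({"therapy_cost": 0.0, "other_cost": 0.0, "study_drug_cost": 0.0})
    )
    out["total_cost"] = out["therapy_cost"] + out["other_cost"]
    return out


def within_trial_results(
    patients: pd.DataFrame,
    utility_values: pd.DataFrame,
    resource_use: pd.DataFrame,
    config: CostingConfig,
    tail: str = "carry-forward",
) -> pd.DataFrame:
    """Per-patient within-trial QALYs, life-years and costs.

    ``utility_values`` must be complete (post-imputation): columns
    patient_id, visit_time, utility.  QALYs and life-years are discounted at
    the configured rate; costs via :func:`cost_within_trial`.
    """
    if utility_values["utility"].isna().any():
        raise ValueError("utility values contain missing entries; impute first")
    costs = cost_within_trial(resource_use, patients, config)
    pat = patients.set_index("patient_id")
    qalys = {}
    lys = {}
    base = {}
    for pid, grp in utility_values.sort_values("visit_time").groupby("patient_id"):
        fu = float(pat.at[pid, "followup_end"])
        dt = pat.at[pid, "death_time"]
        dt = None if pd.isna(dt) else float(dt)
        t = grp["visit_time"].to_numpy()
        u = grp["utility"].to_numpy()
        qalys[pid] = auc_qalys(t, u, fu, dt, config.discount_rate, tail)
        lys[pid] = auc_qalys(
            np.array([0.0]), np.array([1.0]), fu, dt, config.discount_rate, "carry-forward"
        )
        base[pid] = float(u[t == 0][0]) if (t == 0).any() else np.nan
    out = patients[["patient_id", "arm", "country_setting"]].copy()
    out["qalys"] = out["patient_id"].map(qalys)
    out["life_years"] = out["patient_id"].map(lys)
    out["baseline_utility"] = out["patient_id"].map(base)
    out = out.merge(costs, on="patient_id", how="left")
    return out


def arm_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Arm-level within-trial summary: adjusted QALY means, unadjusted cost means."""
    adj = baseline_adjust(results)
    rows = []
    for quantity in ("therapy_cost", "other_cost", "total_cost", "life_years"):
        m = results.groupby("arm")[quantity].mean()
        rows.append((quantity, m["active"], m["control"], m["active"] - m["control"]))
    rows.append(("qalys", adj.adjusted_mean_active, adj.adjusted_mean_control, adj.difference))
    return pd.DataFrame(rows, columns=["quantity", "active", "control", "difference"])
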