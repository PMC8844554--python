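"""Synthetic two-arm trial cohort generator.

Emulates the data structure of a large pragmatic cardiovascular-outcome trial
in type 2 diabetes: baseline covariates and cardiovascular risk factors,
scheduled-visit EQ-5D profiles (a mix of 3L and 5L instruments), annual
resource-use records, non-fatal complication events and deaths, with a small
mortality benefit in the active arm and arm-specific study-drug exposure.

Every stochastic quantity is driven by a single integer seed, and the exact
hazards/effects used are returned as a ground-truth record so that
parameter-recovery tests never have to re-derive them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Continuous risk factors the downstream risk equations may reference.
RISK_FACTOR_REGISTRY = ("hba1c", "sbp", "ldl", "hdl", "bmi", "heart_rate", "egfr")

#: The five EQ-5D dimensions, in instrument order.
EQ5D_DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

#: Non-fatal complications the generator can seed into the trial period.
EVENT_REGISTRY = (
    "ischaemic_heart_disease",
    "myocardial_infarction",
    "heart_failure",
    "stroke",
    "amputation",
    "blindness",
    "renal_failure",
    "foot_ulcer",
)


def _default_event_hazards() -> dict[str, tuple[float, float]]:
    # (control annual hazard, active-arm hazard ratio)
    return {
        "myocardial_infarction": (0.012, 0.95),
        "stroke": (0.006, 0.85),
        "heart_failure": (0.008, 1.00),
        "renal_failure": (0.003, 1.00),
    }


def _default_baseline_missing() -> dict[str, float]:
    return {"height": 0.02, "weight": 0.02, "smoking": 0.03, "baseline_utility": 0.05}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic trial.

    Defaults emulate a two-arm trial of an injectable add-on therapy in
    established type 2 diabetes: annual all-cause mortality ~2.2% in the
    control arm with a hazard ratio of 0.86 in the active arm, median
    follow-up around 3.2 years (maximum 6.7), annual EQ-5D visits, and 28%
    of post-baseline EQ-5D responses missing.
    """

    n_patients: int = 2000
    seed: int = 0
    mortality_hazard_control: float = 0.022
    mortality_hr_active: float = 0.86
    event_hazards: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_event_hazards
    )
    missing_utility_rate: float = 0.28
    missing_risk_factor_rate: float = 0.10
    missingness_mechanism: str = "MCAR"  # or "MAR-on-observables"
    baseline_missing_rates: Mapping[str, float] = field(
        default_factory=_default_baseline_missing
    )
    visit_schedule: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    dropout_rate: float = 0.04
    max_followup: float = 6.7
    min_admin_censor: float = 1.0
    p_us_site: float = 0.7
    compliance_mean: float = 0.76
    # Mean annual counts driving resource use (per person-year).
    inpatient_days_mean: tuple[float, float] = (0.9, 0.78)  # (control, active)
    outpatient_visits_mean: float = 6.0
    oral_antidiabetic_units_mean: float = 330.0
    other_medication_units_mean: float = 120.0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.mortality_hazard_control < 0 or self.dropout_rate < 0:
            raise ValueError("hazard rates must be non-negative")
        if self.mortality_hr_active <= 0:
            raise ValueError("mortality hazard ratio must be positive")
        if not 0 <= self.missing_utility_rate < 1:
            raise ValueError("missing_utility_rate must lie in [0, 1)")
        if not 0 <= self.missing_risk_factor_rate < 1:
            raise ValueError("missing_risk_factor_rate must lie in [0, 1)")
        if self.missingness_mechanism not in ("MCAR", "MAR-on-observables"):
            raise ValueError(f"unknown missingness mechanism {self.missingness_mechanism!r}")
        if len(self.visit_schedule) == 0 or any(t < 0 for t in self.visit_schedule):
            raise ValueError("visit_schedule must be non-empty with non-negative times")
        if sorted(self.visit_schedule) != list(self.visit_schedule):
            raise ValueError("visit_schedule must be sorted")
        for name, (lam, hr) in dict(self.event_hazards).items():
            if lam < 0 or hr <= 0:
                raise ValueError(f"invalid hazard specification for {name}")
            if name not in EVENT_REGISTRY:
                raise ValueError(f"unknown event type {name!r}")
        for k, r in dict(self.baseline_missing_rates).items():
            if not 0 <= r < 1:
                raise ValueError(f"baseline missing rate for {k} must lie in [0, 1)")


@dataclass
class TrialData:
    """The patient-level tables plus the generating ground truth.

    ``risk_factors`` holds per-visit measurements of every registry factor
    (one row per patient per scheduled visit while on study); baseline
    (time 0) measurements are always observed.
    """

    patients: pd.DataFrame
    utilities: pd.DataFrame
    resource_use: pd.DataFrame
    events: pd.DataFrame
    risk_factors: pd.DataFrame
    ground_truth: dict

    def copy(self) -> "TrialData":
        return TrialData(
            self.patients.copy(),
            self.utilities.copy(),
            self.resource_use.copy(),
            self.events.copy(),
            self.risk_factors.copy(),
            dict(self.ground_truth),
        )


def _first_event_time(rng: np.random.Generator, annual_hazard: float, n: int) -> np.ndarray:
    """Time of first event under a discrete annual clock with continuous placement.

    Each year an event fires with probability 1 - exp(-hazard); the event is
    placed uniformly inside the year.  Survival through k whole years is
    exp(-hazard * k).
    """
    if annual_hazard <= 0:
        return np.full(n, np.inf)
    p = 1.0 - np.exp(-annual_hazard)
    year = rng.geometric(p, size=n) - 1  # 0-based year of the event
    return year + rng.uniform(0.0, 1.0, size=n)


def generate_cohort(config: GeneratorConfig) -> TrialData:
    """Generate a fully observed two-arm trial dataset.

    Returns a :class:`TrialData` whose tables contain no missing values
    (missingness is applied separately by :func:`apply_missingness`) and whose
    ``ground_truth`` records the exact hazards, effects and utility model used.
    Identical configs (including seed) produce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    patient_id = np.array([f"P{i:06d}" for i in range(n)])
    arm = np.where(rng.uniform(size=n) < 0.5, "active", "control")
    country = np.where(rng.uniform(size=n) < config.p_us_site, "US", "UK")
    age = np.clip(rng.normal(62.0, 8.0, size=n), 30.0, 90.0)
    sex = np.where(rng.uniform(size=n) < 0.38, "female", "male")
    duration = np.clip(rng.gamma(3.0, 4.0, size=n), 0.0, 50.0)
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.5, 0.38, 0.12])
    height = np.where(sex == "female", rng.normal(162, 7, n), rng.normal(176, 7, n))
    weight = np.clip(rng.normal(95, 18, size=n), 45, 200)
    prior_cvd = rng.uniform(size=n) < 0.73
    compliance = np.clip(rng.beta(5.0, 1.6, size=n), 0.05, 1.0)  # mean ~0.76

    # Follow-up: administrative censoring (staggered entry) and random dropout.
    admin = rng.uniform(config.min_admin_censor, config.max_followup, size=n)
    dropout = (
        rng.exponential(1.0 / config.dropout_rate, size=n)
        if config.dropout_rate > 0
        else np.full(n, np.inf)
    )
    censor = np.minimum(admin, dropout)

    lam_death = config.mortality_hazard_control * np.where(
        arm == "active", config.mortality_hr_active, 1.0
    )
    # Per-patient death clocks (vectorised over patients via inverse sampling).
    p_death = 1.0 - np.exp(-lam_death)
    with np.errstate(divide="ignore", invalid="ignore"):
        death_year = np.floor(np.log1p(-rng.uniform(size=n)) / np.log1p(-p_death))
    death_year = np.where(p_death > 0, death_year, np.inf)
    death_time_all = death_year + rng.uniform(size=n)
    died = death_time_all <= censor
    followup_end = np.where(died, death_time_all, censor)
    death_time = np.where(died, death_time_all, np.nan)

    # Baseline risk factors.
    rf = {
        "hba1c": np.clip(rng.normal(8.0, 1.0, n), 5.0, 14.0),
        "sbp": np.clip(rng.normal(135, 15, n), 90, 210),
        "ldl": np.clip(rng.normal(2.3, 0.8, n), 0.5, 6.0),
        "hdl": np.clip(rng.normal(1.1, 0.3, n), 0.4, 3.0),
        "bmi": np.clip(weight / (height / 100.0) ** 2, 15, 60),
        "heart_rate": np.clip(rng.normal(72, 10, n), 40, 130),
        "egfr": np.clip(rng.normal(76, 18, n), 10, 140),
    }

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "arm": arm,
            "country_setting": country,
            "age": age,
            "sex": sex,
            "diabetes_duration": duration,
            "smoking": smoking,
            "height": height,
            "weight": weight,
            "prior_cvd": prior_cvd,
            "compliance": compliance,
            "followup_end": followup_end,
            "death_time": death_time,
        }
    )
    for name in RISK_FACTOR_REGISTRY:
        patients[f"{name}_baseline"] = rf[name]

    # Non-fatal events: independent annual clocks per event type.
    event_rows = []
    truth_events = {}
    for name, (lam0, hr) in dict(config.event_hazards).items():
        lam = lam0 * np.where(arm == "active", hr, 1.0)
        truth_events[name] = {"control_hazard": lam0, "active_hr": hr}
        for lam_value in np.unique(lam):
            idx = np.where(lam == lam_value)[0]
            times = _first_event_time(rng, lam_value, len(idx))
            for i, t in zip(idx, times):
                if t <= followup_end[i]:
                    event_rows.append((patient_id[i], name, float(t)))
    if died.any():
        for i in np.where(died)[0]:
            event_rows.append((patient_id[i], "death", float(death_time_all[i])))
    events = pd.DataFrame(event_rows, columns=["patient_id", "event", "time"]).sort_values(
        ["patient_id", "time"], kind="stable", ignore_index=True
    )

    # EQ-5D profiles at scheduled visits.  Severity is a per-dimension
    # Bernoulli-step process driven by age, prior CVD, time on study and a
    # patient frailty, so older/sicker patients report worse health.
    frailty = rng.normal(0.0, 0.4, size=n)
    instrument = np.where(rng.uniform(size=n) < 0.5, "EQ5D3L", "EQ5D5L")
    util_rows = []
    util_truth = {
        "latent_intercept": -2.6,
        "latent_age": 0.02,
        "latent_prior_cvd": 0.5,
        "latent_time": 0.04,
        "frailty_sd": 0.4,
    }
    for t in config.visit_schedule:
        alive_at_visit = np.where(t <= followup_end)[0]
        if len(alive_at_visit) == 0:
            continue
        lp = (
            util_truth["latent_intercept"]
            + util_truth["latent_age"] * (age[alive_at_visit] - 60.0)
            + util_truth["latent_prior_cvd"] * prior_cvd[alive_at_visit]
            + util_truth["latent_time"] * t
            + frailty[alive_at_visit]
        )
        p_sev = 1.0 / (1.0 + np.exp(-lp))
        levels = {}
        for dim in EQ5D_DIMENSIONS:
            n_steps = np.where(instrument[alive_at_visit] == "EQ5D3L", 2, 4)
            levels[dim] = 1 + rng.binomial(n_steps, p_sev)
        for j, i in enumerate(alive_at_visit):
            util_rows.append(
                (
                    patient_id[i],
                    float(t),
                    instrument[i],
                    *(int(levels[dim][j]) for dim in EQ5D_DIMENSIONS),
                )
            )
    utilities = pd.DataFrame(
        util_rows, columns=["patient_id", "visit_time", "instrument", *EQ5D_DIMENSIONS]
    )
    utilities[list(EQ5D_DIMENSIONS)] = utilities[list(EQ5D_DIMENSIONS)].astype(float)

    # Per-visit risk-factor measurements: baseline + small linear drift + noise.
    rf_drift = {"hba1c": 0.05, "sbp": 0.3, "ldl": -0.01, "hdl": 0.0,
                "bmi": 0.05, "heart_rate": 0.0, "egfr": -0.8}
    rf_rows = []
    for t in config.visit_schedule:
        alive_at_visit = np.where(t <= followup_end)[0]
        if len(alive_at_visit) == 0:
            continue
        row_block = {"patient_id": patient_id[alive_at_visit], "visit_time": float(t)}
        for name in RISK_FACTOR_REGISTRY:
            noise = rng.normal(0.0, 0.05 * np.std(rf[name]), size=len(alive_at_visit))
            row_block[name] = rf[name][alive_at_visit] + rf_drift[name] * t + noise
        rf_rows.append(pd.DataFrame(row_block))
    risk_factors = pd.concat(rf_rows, ignore_index=True)

    # Annual resource-use periods up to end of follow-up.
    ru_rows = []
    mean_ip = np.where(arm == "active", config.inpatient_days_mean[1], config.inpatient_days_mean[0])
    for i in range(n):
        k = 0
        while k < followup_end[i]:
            end = min(k + 1.0, followup_end[i])
            frac = end - k
            doses = (
                int(rng.binomial(round(52 * frac), compliance[i])) if arm[i] == "active" else 0
            )
            ru_rows.append(
                (
                    patient_id[i],
                    float(k),
                    float(end),
                    int(rng.poisson(mean_ip[i] * frac)),
                    int(rng.poisson(config.outpatient_visits_mean * frac)),
                    int(rng.poisson(config.oral_antidiabetic_units_mean * frac)),
                    int(rng.poisson(config.other_medication_units_mean * frac)),
                    doses,
                )
            )
            k += 1
    resource_use = pd.DataFrame(
        ru_rows,
        columns=[
            "patient_id",
            "period_start",
            "period_end",
            "inpatient_days",
            "outpatient_visits",
            "oral_antidiabetic_units",
            "other_medication_units",
            "study_drug_doses",
        ],
    )

    ground_truth = {
        "seed": config.seed,
        "mortality_hazard_control": config.mortality_hazard_control,
        "mortality_hr_active": config.mortality_hr_active,
        "event_hazards": truth_events,
        "compliance_mean": float(compliance.mean()),
        "utility_model": util_truth,
        "risk_factor_drift": rf_drift,
        "n_patients": n,
    }
    return TrialData(patients, utilities, resource_use, events, risk_factors, ground_truth)


def _solve_intercept(target: float, offset: np.ndarray) -> float:
    """Find a such that mean(sigmoid(a + offset)) == target, by bisection."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + offset)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply_missingness(
    data: TrialData, config: GeneratorConfig
) -> tuple[TrialData, dict[str, pd.DataFrame]]:
    """Null out cells according to the configured missingness mechanism.

    Post-baseline EQ-5D responses go missing at ``missing_utility_rate``
    (whole profile per visit); baseline height/weight/smoking and the
    baseline EQ-5D response are nulled at their own rates.  Returns the
    masked dataset plus boolean masks that exactly identify removed cells.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    out = data.copy()
    rate = config.missing_utility_rate

    post = out.utilities["visit_time"] > 0
    if config.missingness_mechanism == "MCAR":
        p_miss = np.full(post.sum(), rate)
    else:  # MAR-on-observables: depends on patient age (always observed)
        ages = out.utilities.loc[post, "patient_id"].map(
            out.patients.set_index("patient_id")["age"]
        )
        offset = 0.06 * (ages.to_numpy() - ages.mean())
        a = _solve_intercept(rate, offset) if rate > 0 else -np.inf
        p_miss = 1.0 / (1.0 + np.exp(-(a + offset))) if rate > 0 else np.zeros(post.sum())
    miss_profile = np.zeros(len(out.utilities), dtype=bool)
    miss_profile[np.where(post)[0]] = rng.uniform(size=post.sum()) < p_miss

    dims = list(EQ5D_DIMENSIONS)
    out.utilities.loc[miss_profile, dims] = np.nan
    util_mask = pd.DataFrame(
        {
            "patient_id": out.utilities["patient_id"],
            "visit_time": out.utilities["visit_time"],
            "profile_missing": miss_profile,
        }
    )

    # Baseline fields on the patients table (baseline EQ-5D is the t=0 visit row).
    base_mask = pd.DataFrame({"patient_id": out.patients["patient_id"]})
    rates = dict(config.baseline_missing_rates)
    for col in ("height", "weight", "smoking"):
        r = rates.get(col, 0.0)
        removed = rng.uniform(size=len(out.patients)) < r
        base_mask[col] = removed
        if removed.any():
            out.patients.loc[removed, col] = np.nan if col != "smoking" else None
    r0 = rates.get("baseline_utility", 0.0)
    is_base = (out.utilities["visit_time"] == 0).to_numpy()
    removed0 = np.zeros(len(out.utilities), dtype=bool)
    removed0[np.where(is_base)[0]] = rng.uniform(size=is_base.sum()) < r0
    out.utilities.loc[removed0, dims] = np.nan
    util_mask.loc[removed0, "profile_missing"] = True

    # Post-baseline risk-factor cells go missing element-wise.
    rf_post = (out.risk_factors["visit_time"] > 0).to_numpy()
    rf_mask = pd.DataFrame(
        {
            "patient_id": out.risk_factors["patient_id"],
            "visit_time": out.risk_factors["visit_time"],
        }
    )
    for name in RISK_FACTOR_REGISTRY:
        removed_rf = np.zeros(len(out.risk_factors), dtype=bool)
        removed_rf[np.where(rf_post)[0]] = (
            rng.uniform(size=rf_post.sum()) < config.missing_risk_factor_rate
        )
        rf_mask[name] = removed_rf
        out.risk_factors.loc[removed_rf, name] = np.nan

    masks = {"utilities": util_mask, "patients": base_mask, "risk_factors": rf_mask}
    return out, masks
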