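"""Annual-cycle patient-level extrapolation to death.

Each surviving trial participant enters the simulation with their
end-of-trial risk-factor profile.  Every cycle (1 year) the engine evaluates
parametric annual hazards for eight diabetes complications and death
(exponential, Weibull on diabetes duration, Gompertz on age, or logistic
forms), draws event occurrences from per-patient random streams, applies
utility decrements and complication costs, accrues discounted life-years /
QALYs / costs, and updates age, diabetes duration and event history.  All
other risk factors are held constant in the base case (optionally drifted
linearly).

Active-arm patients continue study drug at their last-trial-year compliance
until death or renal failure, after which (and for control patients
throughout) both arms accrue the same standard-care therapy cost.  Two
discontinuation scenarios are supported: stop-at-trial-end (scenario 1) and
a constant annual stopping rate during the first 10 extrapolation years
(scenario 2).

The shipped default risk equations, decrements and complication costs are
synthetic placeholders with the structure of published diabetes outcome
models; any coefficient file following the documented CSV schema can be
substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import EVENT_REGISTRY, RISK_FACTOR_REGISTRY

OUTCOMES = EVENT_REGISTRY + ("death",)
_FORMS = ("exponential", "weibull", "gompertz", "logistic")


@dataclass(frozen=True)
class RiskEquation:
    """Parametric annual hazard for one outcome.

    ``coefficients`` maps term names to estimates.  Recognised terms:
    ``intercept``, ``female``, ``on_treatment``, ``smoking_current``,
    ``history_<event>`` flags, ``age``, ``diabetes_duration``, and any risk
    factor in the registry.  ``centering`` holds reference values subtracted
    from continuous terms before multiplying.  Weibull cumulative hazards run
    on diabetes duration, Gompertz on age.
    """

    name: str
    form: str
    coefficients: Mapping[str, float]
    shape: float = 1.0
    centering: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.name!r}")
        if self.form not in _FORMS:
            raise ValueError(f"unknown functional form {self.form!r}")
        if self.form in ("weibull", "gompertz") and self.shape <= 0:
            raise ValueError("shape must be positive")
        for term in self.coefficients:
            if not _term_is_known(term):
                raise ValueError(f"coefficient term {term!r} not in the registry")

    def linear_predictor(self, values: Mapping[str, float]) -> float:
        lp = 0.0
        for term, beta in self.coefficients.items():
            x = 1.0 if term == "intercept" else values[term]
            lp += beta * (x - self.centering.get(term, 0.0))
        if not math.isfinite(lp):
            raise ValueError(f"non-finite linear predictor for {self.name}")
        return lp


def _term_is_known(term: str) -> bool:
    if term in ("intercept", "female", "on_treatment", "smoking_current", "age",
                "diabetes_duration"):
        return True
    if term.startswith("history_"):
        return term[len("history_"):] in EVENT_REGISTRY
    return term in RISK_FACTOR_REGISTRY


def annual_event_probability(
    equation: RiskEquation, values: Mapping[str, float]
) -> float:
    """One-cycle event probability from the hazard specification.

    Exponential: p = 1 - exp(-exp(lp)).  Weibull / Gompertz integrate the
    cumulative hazard over [t, t+1] on their time scale (diabetes duration,
    age).  Logistic returns the fitted probability directly.
    """
    try:
        lp = equation.linear_predictor(values)
    except KeyError as exc:
        raise ValueError(
            f"profile is missing term {exc.args[0]!r} required by {equation.name}"
        ) from None
    if equation.form == "logistic":
        return 1.0 / (1.0 + math.exp(-lp))
    if equation.form == "exponential":
        dh = math.exp(lp)
    elif equation.form == "weibull":
        t = max(float(values["diabetes_duration"]), 0.0)
        s = equation.shape
        dh = math.exp(lp) * ((t + 1.0) ** s - t**s)
    else:  # gompertz
        t = max(float(values["age"]), 0.0)
        s = equation.shape
        dh = math.exp(lp) / s * (math.exp(s * (t + 1.0)) - math.exp(s * t))
    return 1.0 - math.exp(-dh)


def update_profile(
    values: dict[str, float],
    trajectory_mode: str = "constant",
    drift: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Advance the profile one cycle: age and duration +1, risk factors per mode."""
    if trajectory_mode not in ("constant", "linear-drift"):
        raise ValueError(f"unknown trajectory mode {trajectory_mode!r}")
    out = dict(values)
    out["age"] = out["age"] + 1.0
    out["diabetes_duration"] = out["diabetes_duration"] + 1.0
    if trajectory_mode == "linear-drift":
        for name, slope in (drift or {}).items():
            if name not in RISK_FACTOR_REGISTRY:
                raise ValueError(f"cannot drift unknown risk factor {name!r}")
            out[name] = out[name] + slope
    return out


@dataclass
class EventTable:
    """Per-complication one-off (event-year) and ongoing utility decrements / costs."""

    utility_event: Mapping[str, float]
    utility_ongoing: Mapping[str, float]
    cost_event: Mapping[str, float]
    cost_ongoing: Mapping[str, float]
    background_annual_cost: float = 0.0
    standard_care_therapy_cost: float = 0.0
    study_drug_price_per_dose: float = 0.0
    doses_per_year: float = 52.0

    def validate(self) -> None:
        for table in (self.utility_event, self.utility_ongoing, self.cost_event,
                      self.cost_ongoing):
            for name, v in dict(table).items():
                if name not in EVENT_REGISTRY:
                    raise ValueError(f"unknown complication {name!r}")
                if v < 0:
                    raise ValueError("decrements and costs must be non-negative")


@dataclass
class SimulationConfig:
    """Extrapolation settings (annual cycle)."""

    horizon: int = 40
    age_cap: float = 100.0
    discount_rate_cost: float = 0.03
    discount_rate_effect: float = 0.03
    trajectory_mode: str = "constant"
    drift: Mapping[str, float] = field(default_factory=dict)
    discontinuation_scenario: str = "base"  # base | scenario1 | scenario2
    scenario2_annual_stop_rate: float = 0.05
    scenario2_window: int = 10
    compliance_default: float = 1.0
    n_coefficient_draws: int = 800
    seed: int = 0
    discount_clock: str = "from-randomization"  # or "from-trial-end"
    utility_floor: float = 0.0
    half_cycle_correction: bool = False

    def validate(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if min(self.discount_rate_cost, self.discount_rate_effect) < 0:
            raise ValueError("discount rates must be non-negative")
        if self.discontinuation_scenario not in ("base", "scenario1", "scenario2"):
            raise ValueError(
                f"unknown discontinuation scenario {self.discontinuation_scenario!r}"
            )
        if not 0 <= self.scenario2_annual_stop_rate <= 1:
            raise ValueError("scenario-2 stop rate must lie in [0, 1]")
        if self.discount_clock not in ("from-randomization", "from-trial-end"):
            raise ValueError(f"unknown discount clock {self.discount_clock!r}")


@dataclass
class YearTrace:
    """State and accruals of one simulated post-trial year."""

    year: int
    age: float
    diabetes_duration: float
    events: tuple[str, ...]
    alive_at_end: bool
    on_study_drug: bool
    therapy_cost: float
    complication_cost: float
    background_cost: float
    utility: float
    discounted_cost: float
    discounted_qalys: float
    discounted_life_years: float


def treatment_rule(
    on_drug: bool,
    arm: str,
    history: set[str],
    year: int,
    config: SimulationConfig,
    tables: EventTable,
    compliance: float,
    stop_rng: np.random.Generator | None = None,
) -> tuple[bool, float]:
    """Drug status for this year and the therapy cost accrued.

    Returns (on_study_drug this year, therapy cost).  All patients accrue the
    standard-care therapy cost; on-drug patients additionally accrue study
    drug at their last-trial-year compliance.  Renal failure switches the
    patient to standard care permanently (base case and scenario 2);
    scenario 1 stops study drug at extrapolation year 0; scenario 2 applies a
    constant annual stopping probability during its window.
    """
    on = on_drug and arm == "active" and "renal_failure" not in history
    if config.discontinuation_scenario == "scenario1":
        on = False
    elif config.discontinuation_scenario == "scenario2" and on and year < config.scenario2_window:
        # the stop draw is consumed from a dedicated stream so that the
        # event streams stay aligned across scenarios (common random numbers)
        if stop_rng is not None and stop_rng.uniform() < config.scenario2_annual_stop_rate:
            on = False
    cost = tables.standard_care_therapy_cost
    if on:
        cost += tables.study_drug_price_per_dose * tables.doses_per_year * compliance
    return on, cost


def simulate_patient(
    profile: Mapping[str, object],
    equations: Sequence[RiskEquation],
    tables: EventTable,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[YearTrace], dict[str, float]]:
    """Simulate one patient from end of trial to death, horizon or age cap.

    ``profile`` needs: the registry risk factors, age, diabetes_duration,
    sex, arm, base_utility, compliance, followup_years (for the discount
    clock) and an optional ``history`` iterable of complications already
    experienced in the trial.  A year's life-year and utility accrue to
    everyone alive at the start of that year; death is evaluated after the
    complication draws so that a same-year event can raise mortality risk.
    """
    config.validate()
    tables.validate()
    event_eqs = [e for e in equations if e.name != "death"]
    death_eqs = [e for e in equations if e.name == "death"]
    if len(death_eqs) != 1:
        raise ValueError("exactly one death equation is required")
    death_eq = death_eqs[0]

    values: dict[str, float] = {
        name: float(profile[name]) for name in RISK_FACTOR_REGISTRY if name in profile
    }
    values["age"] = float(profile["age"])
    values["diabetes_duration"] = float(profile["diabetes_duration"])
    values["female"] = 1.0 if profile.get("sex") == "female" else 0.0
    values["smoking_current"] = 1.0 if profile.get("smoking") == "current" else 0.0
    history: set[str] = set(profile.get("history", ()))
    for ev in OUTCOMES:
        values[f"history_{ev}"] = 1.0 if ev in history else 0.0
    arm = str(profile.get("arm", "control"))
    base_utility = float(profile.get("base_utility", 1.0))
    compliance = float(profile.get("compliance", config.compliance_default))
    offset = (
        float(profile.get("followup_years", 0.0))
        if config.discount_clock == "from-randomization"
        else 0.0
    )

    stop_rng = rng.spawn(1)[0]
    on_drug = arm == "active"
    traces: list[YearTrace] = []
    totals = {
        "life_years": 0.0,
        "qalys": 0.0,
        "cost_therapy": 0.0,
        "cost_study_drug": 0.0,
        "cost_complication": 0.0,
        "cost_background": 0.0,
        "cost_total": 0.0,
        "life_years_undiscounted": 0.0,
    }

    for k in range(config.horizon):
        if values["age"] > config.age_cap:
            break
        order = rng.permutation(len(event_eqs)) if event_eqs else []
        uniforms = rng.uniform(size=len(event_eqs) + 1)
        on_drug, therapy_cost = treatment_rule(
            on_drug, arm, history, k, config, tables, compliance, stop_rng
        )
        values["on_treatment"] = 1.0 if on_drug else 0.0

        events_this_year: list[str] = []
        for idx in order:
            eq = event_eqs[idx]
            if eq.name in history:
                continue  # first-event indicators only
            p = annual_event_probability(eq, values)
            if uniforms[idx] < p:
                events_this_year.append(eq.name)
        # death last, seeing this year's events
        for ev in events_this_year:
            values[f"history_{ev}"] = 1.0
        p_death = annual_event_probability(death_eq, values)
        died = uniforms[len(event_eqs)] < p_death
        if died:
            events_this_year.append("death")

        utility = base_utility
        for ev in events_this_year:
            if ev != "death":
                utility -= tables.utility_event.get(ev, 0.0)
        for ev in history:
            utility -= tables.utility_ongoing.get(ev, 0.0)
        utility = max(config.utility_floor, utility)

        comp_cost = sum(tables.cost_event.get(ev, 0.0) for ev in events_this_year if ev != "death")
        comp_cost += sum(tables.cost_ongoing.get(ev, 0.0) for ev in history)
        accrual = 0.5 if (config.half_cycle_correction and died) else 1.0

        dc = (1.0 + config.discount_rate_cost) ** -(offset + k)
        de = (1.0 + config.discount_rate_effect) ** -(offset + k)
        year_cost = therapy_cost + comp_cost + tables.background_annual_cost
        traces.append(
            YearTrace(
                year=k,
                age=values["age"],
                diabetes_duration=values["diabetes_duration"],
                events=tuple(events_this_year),
                alive_at_end=not died,
                on_study_drug=on_drug,
                therapy_cost=therapy_cost,
                complication_cost=comp_cost,
                background_cost=tables.background_annual_cost,
                utility=utility,
                discounted_cost=year_cost * dc,
                discounted_qalys=utility * accrual * de,
                discounted_life_years=accrual * de,
            )
        )
        totals["life_years"] += accrual * de
        totals["life_years_undiscounted"] += accrual
        totals["qalys"] += utility * accrual * de
        totals["cost_therapy"] += therapy_cost * dc
        totals["cost_study_drug"] += (therapy_cost - tables.standard_care_therapy_cost) * dc
        totals["cost_complication"] += comp_cost * dc
        totals["cost_background"] += tables.background_annual_cost * dc

        if died:
            break
        history.update(events_this_year)
        values = update_profile(values, config.trajectory_mode, config.drift)

    totals["cost_total"] = (
        totals["cost_therapy"] + totals["cost_complication"] + totals["cost_background"]
    )
    return traces, totals


def draw_coefficients(
    equations: Sequence[RiskEquation],
    covariance: pd.DataFrame | None,
    n_draws: int,
    seed: int,
) -> list[list[RiskEquation]]:
    """Multivariate-normal coefficient sets around the point estimates.

    Returns ``n_draws + 1`` equation sets; index 0 is the reserved point
    estimate.  ``covariance`` is indexed by "equation:term" labels; None (or
    an all-zero matrix) reproduces the point estimates in every draw.
    """
    labels = [f"{eq.name}:{term}" for eq in equations for term in eq.coefficients]
    point = np.array(
        [beta for eq in equations for beta in eq.coefficients.values()], dtype=float
    )
    if covariance is None:
        cov = np.zeros((len(labels), len(labels)))
    else:
        missing = [l for l in labels if l not in covariance.index]
        if missing or covariance.shape[0] != covariance.shape[1]:
            raise ValueError(f"covariance does not cover coefficient terms {missing}")
        cov = covariance.loc[labels, labels].to_numpy(dtype=float)
        eigmin = float(np.linalg.eigvalsh(cov).min())
        if eigmin < -1e-8 * max(1.0, float(np.abs(cov).max())):
            raise ValueError("covariance matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    draws_matrix = (
        rng.multivariate_normal(point, cov, size=n_draws, method="eigh")
        if cov.any()
        else np.tile(point, (n_draws, 1))
    )
    all_sets = [point] + list(draws_matrix)
    out = []
    for vec in all_sets:
        new_eqs = []
        i = 0
        for eq in equations:
            coefs = {term: float(vec[i + j]) for j, term in enumerate(eq.coefficients)}
            i += len(eq.coefficients)
            new_eqs.append(replace(eq, coefficients=coefs))
        out.append(new_eqs)
    return out


def simulate_cohort(
    profiles: pd.DataFrame,
    equation_sets: Sequence[Sequence[RiskEquation]],
    tables: EventTable,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-coefficient-draw, per-arm means of discounted post-trial outcomes.

    ``profiles`` has one row per trial participant (columns: the profile
    fields of :func:`simulate_patient`, plus ``alive`` and optionally
    ``crn_id``).  Patients dead at end of trial contribute zeros.  Random
    streams are keyed by (config.seed, crn_id), so the same patient sees the
    same randomness in every draw and scenario (common random numbers);
    cloned cohorts therefore difference to exactly zero.
    """
    config.validate()
    if len(profiles) == 0:
        raise ValueError("empty cohort")
    prof = profiles.copy()
    if "crn_id" not in prof.columns:
        prof["crn_id"] = prof.groupby("arm").cumcount()
    rows = []
    record_cols = [
        "life_years",
        "qalys",
        "cost_therapy",
        "cost_study_drug",
        "cost_complication",
        "cost_background",
        "cost_total",
        "life_years_undiscounted",
    ]
    profile_dicts = prof.to_dict("records")
    for d, equations in enumerate(equation_sets):
        for p in profile_dicts:
            if not p.get("alive", True):
                rows.append((d, p["arm"], *([0.0] * len(record_cols))))
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed & 0x7FFFFFFF, int(p["crn_id"])])
            )
            _, totals = simulate_patient(p, equations, tables, config, rng)
            rows.append((d, p["arm"], *(totals[c] for c in record_cols)))
    frame = pd.DataFrame(rows, columns=["draw", "arm", *record_cols])
    return frame.groupby(["draw", "arm"], as_index=False).mean()


# ---------------------------------------------------------------------------
# Default synthetic risk equations and event tables


def default_risk_equations() -> list[RiskEquation]:
    """Synthetic placeholder equations for the eight complications and death.

    Magnitudes are chosen to give plausible annual event rates in an
    established type 2 diabetes population (e.g. ~2% annual mortality at age
    65, rising with age on a Gompertz curve); they are NOT the published
    coefficients of any outcomes model.
    """
    c = {"hba1c": 8.0, "sbp": 135.0, "ldl": 2.3, "hdl": 1.1, "bmi": 32.0, "egfr": 76.0}
    return [
        RiskEquation(
            "death", "gompertz",
            {"intercept": -9.76, "hba1c": 0.05, "on_treatment": math.log(0.86),
             "history_myocardial_infarction": 0.6, "history_stroke": 0.5,
             "history_heart_failure": 0.7, "history_renal_failure": 0.9,
             "history_amputation": 0.4},
            shape=0.09, centering={"hba1c": c["hba1c"]},
        ),
        RiskEquation(
            "myocardial_infarction", "weibull",
            {"intercept": -5.12, "sbp": 0.012, "hba1c": 0.10, "female": -0.3,
             "history_ischaemic_heart_disease": 0.5},
            shape=1.2, centering={"sbp": c["sbp"], "hba1c": c["hba1c"]},
        ),
        RiskEquation(
            "stroke", "exponential",
            {"intercept": math.log(0.006), "age": 0.05, "sbp": 0.015},
            centering={"age": 65.0, "sbp": c["sbp"]},
        ),
        RiskEquation(
            "heart_failure", "exponential",
            {"intercept": math.log(0.008), "bmi": 0.03, "egfr": -0.01},
            centering={"bmi": c["bmi"], "egfr": c["egfr"]},
        ),
        RiskEquation(
            "ischaemic_heart_disease", "exponential",
            {"intercept": math.log(0.008), "ldl": 0.25, "hdl": -0.3},
            centering={"ldl": c["ldl"], "hdl": c["hdl"]},
        ),
        RiskEquation(
            "renal_failure", "exponential",
            {"intercept": math.log(0.003), "egfr": -0.04, "hba1c": 0.10},
            centering={"egfr": c["egfr"], "hba1c": c["hba1c"]},
        ),
        RiskEquation(
            "amputation", "exponential",
            {"intercept": math.log(0.0015), "hba1c": 0.15, "smoking_current": 0.4},
            centering={"hba1c": c["hba1c"]},
        ),
        RiskEquation(
            "blindness", "exponential",
            {"intercept": math.log(0.002), "hba1c": 0.12},
            centering={"hba1c": c["hba1c"]},
        ),
        RiskEquation(
            "foot_ulcer", "logistic",
            {"intercept": -5.52, "hba1c": 0.10},
            centering={"hba1c": c["hba1c"]},
        ),
    ]


def default_event_tables(country: str) -> EventTable:
    """Synthetic placeholder decrements and complication costs."""
    utility_event = {
        "myocardial_infarction": 0.055, "stroke": 0.164, "heart_failure": 0.108,
        "amputation": 0.28, "blindness": 0.057, "renal_failure": 0.263,
        "ischaemic_heart_disease": 0.09, "foot_ulcer": 0.17,
    }
    utility_ongoing = {
        "myocardial_infarction": 0.028, "stroke": 0.116, "heart_failure": 0.108,
        "amputation": 0.28, "blindness": 0.057, "renal_failure": 0.263,
        "ischaemic_heart_disease": 0.09, "foot_ulcer": 0.10,
    }
    if country == "US":
        scale, background, standard, price = 1.0, 2000.0, 1200.0, 119.70
    else:
        scale, background, standard, price = 0.25, 600.0, 300.0, 18.94
    cost_event = {
        "myocardial_infarction": 40000.0, "stroke": 35000.0, "heart_failure": 25000.0,
        "amputation": 50000.0, "blindness": 8000.0, "renal_failure": 90000.0,
        "ischaemic_heart_disease": 20000.0, "foot_ulcer": 12000.0,
    }
    cost_ongoing = {
        "myocardial_infarction": 3000.0, "stroke": 5000.0, "heart_failure": 4000.0,
        "amputation": 3000.0, "blindness": 2500.0, "renal_failure": 90000.0,
        "ischaemic_heart_disease": 2000.0, "foot_ulcer": 2000.0,
    }
    return EventTable(
        utility_event=utility_event,
        utility_ongoing=utility_ongoing,
        cost_event={k: v * scale for k, v in cost_event.items()},
        cost_ongoing={k: v * scale for k, v in cost_ongoing.items()},
        background_annual_cost=background,
        standard_care_therapy_cost=standard,
        study_drug_price_per_dose=price,
    )


def equations_to_frame(equations: Iterable[RiskEquation]) -> pd.DataFrame:
    """Serialise equations to the coefficient-file schema (one row per term)."""
    rows = []
    for eq in equations:
        for term, beta in eq.coefficients.items():
            rows.append(
                (eq.name, eq.form, eq.shape, term, beta, eq.centering.get(term, 0.0))
            )
    return pd.DataFrame(
        rows, columns=["equation", "form", "shape", "term", "estimate", "reference"]
    )


def equations_from_frame(frame: pd.DataFrame) -> list[RiskEquation]:
    required = {"equation", "form", "shape", "term", "estimate"}
    if not required.issubset(frame.columns):
        raise ValueError(f"coefficient file needs columns {sorted(required)}")
    out = []
    for name, grp in frame.groupby("equation", sort=False):
        forms = grp["form"].unique()
        shapes = grp["shape"].unique()
        if len(forms) != 1 or len(shapes) != 1:
            raise ValueError(f"inconsistent form/shape rows for equation {name!r}")
        centering = {}
        if "reference" in grp.columns:
            centering = {
                str(t): float(r)
                for t, r in zip(grp["term"], grp["reference"])
                if r not in (None,) and float(r) != 0.0
            }
        out.append(
            RiskEquation(
                str(name),
                str(forms[0]),
                {str(t): float(b) for t, b in zip(grp["term"], grp["estimate"])},
                shape=float(shapes[0]),
                centering=centering,
            )
        )
    return out
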