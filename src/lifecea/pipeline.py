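"""End-to-end pipeline: generate -> impute -> within-trial -> extrapolate -> CEA.

One configuration object drives all stages; every source of randomness is
derived from its seeds, so a re-run with the same configuration reproduces
all outputs.  `run_scenarios` re-executes the downstream stages under named
configuration deltas (price discounts, discount-rate variants,
discontinuation scenarios, subgroup filters) with the same random streams,
so scenario contrasts are exact where the delta is deterministic (e.g. a
price change).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cea import (
    CEAOutput,
    DEFAULT_THRESHOLDS,
    Scenario,
    bootstrap_within_trial,
    combine_periods,
    lifetime_table,
    summarize_replicates,
)
from .cohort import GeneratorConfig, TrialData, apply_missingness, generate_cohort
from .economics import CostingConfig, baseline_adjust, within_trial_results
from .imputation import (
    CompletedDataset,
    ImputationConfig,
    average_risk_factor_imputations,
    impute_baseline,
    mice_impute,
)
from .microsim import (
    EventTable,
    SimulationConfig,
    default_event_tables,
    default_risk_equations,
    draw_coefficients,
    simulate_cohort,
)
from .valuation import CrosswalkMap, ValueSet, default_value_set, value_utility_table
from .cohort import RISK_FACTOR_REGISTRY


@dataclass
class PipelineConfig:
    """All knobs of a full analysis run.

    Defaults mirror the base case: m=28 imputations, 800 bootstrap
    replicates and coefficient draws, 3% (US) / 3.5% (UK) discounting, and
    the 23.1% wholesale discount baked into the US net drug price.
    """

    country: str = "US"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    costing: CostingConfig | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    bootstrap_replicates: int = 800
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    utility_tail: str = "carry-forward"

    def __post_init__(self) -> None:
        if self.costing is None:
            self.costing = CostingConfig.default(self.country)
        # one seed drives every stage's own stream
        self.generator = replace(self.generator, seed=self.generator.seed or self.seed)
        self.imputation = replace(
            self.imputation, seed=self.imputation.seed or self.seed
        )
        self.simulation = replace(self.simulation, seed=self.simulation.seed or self.seed)
        if self.simulation.discount_rate_cost == SimulationConfig.discount_rate_cost:
            self.simulation = replace(
                self.simulation,
                discount_rate_cost=self.costing.discount_rate,
                discount_rate_effect=self.costing.discount_rate,
            )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return list(obj)
            if isinstance(obj, Mapping):
                return {str(k): enc(v) for k, v in obj.items()}
            return obj

        d = {k: enc(v) for k, v in dataclasses.asdict(self).items()}
        d["thresholds"] = [float(self.thresholds[0]), float(self.thresholds[-1]), len(self.thresholds)]
        return d


_KNOWN_TOP_KEYS = {
    "country", "seed", "generator", "imputation", "costing", "simulation",
    "bootstrap_replicates", "thresholds", "utility_tail",
}


class ConfigError(ValueError):
    pass


def config_from_dict(raw: Mapping) -> PipelineConfig:
    """Build a PipelineConfig from a parsed YAML/JSON mapping.

    Unknown keys raise :class:`ConfigError` naming the offending key.
    """
    unknown = set(raw) - _KNOWN_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")

    def sub(cls, key):
        block = dict(raw.get(key, {}))
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(block) - names
        if bad:
            raise ConfigError(f"unknown configuration key(s) in '{key}': {sorted(bad)}")
        for k, v in block.items():
            if isinstance(v, list):
                block[k] = tuple(v)
        return cls(**block)

    kwargs = {}
    for key in ("country", "seed", "bootstrap_replicates", "utility_tail"):
        if key in raw:
            kwargs[key] = raw[key]
    if "thresholds" in raw:
        t = raw["thresholds"]
        kwargs["thresholds"] = tuple(np.linspace(t[0], t[1], int(t[2]))) if len(t) == 3 else tuple(t)
    kwargs["generator"] = sub(GeneratorConfig, "generator")
    kwargs["imputation"] = sub(ImputationConfig, "imputation")
    kwargs["simulation"] = sub(SimulationConfig, "simulation")
    if "costing" in raw:
        kwargs["costing"] = sub(CostingConfig, "costing")
    cfg = PipelineConfig(**kwargs)
    cfg.generator.validate()
    cfg.imputation.validate()
    cfg.costing.validate()
    cfg.simulation.validate()
    return cfg


@dataclass
class PipelineState:
    """Everything produced up to the end of the imputation stage."""

    config: PipelineConfig
    data: TrialData
    masks: dict
    value_set: ValueSet
    crosswalk: CrosswalkMap
    utility_values: pd.DataFrame  # baseline-imputed, post-baseline may be NaN
    completed: list[CompletedDataset]
    averaged_risk_factors: pd.DataFrame


@dataclass
class PipelineResult:
    state: PipelineState
    within_by_imputation: dict[int, pd.DataFrame]
    profiles: pd.DataFrame
    post_by_draw: pd.DataFrame
    replicates: pd.DataFrame
    cea: CEAOutput
    table: pd.DataFrame


def prepare_state(
    config: PipelineConfig,
    value_set: ValueSet | None = None,
    crosswalk: CrosswalkMap | None = None,
) -> PipelineState:
    """Stages 1-3: generate, apply missingness, value profiles, impute."""
    data_full = generate_cohort(config.generator)
    data, masks = apply_missingness(data_full, config.generator)
    vs = value_set or default_value_set(config.country)
    xw = crosswalk or CrosswalkMap()
    uv = value_utility_table(data.utilities, vs, xw)
    data, uv, _ = impute_baseline(data, uv)
    completed = mice_impute(data, uv, config.imputation)
    averaged = average_risk_factor_imputations(completed)
    return PipelineState(config, data, masks, vs, xw, uv, completed, averaged)


def within_trial_by_imputation(state: PipelineState) -> dict[int, pd.DataFrame]:
    """Per-patient within-trial results for each completed dataset."""
    out = {}
    for comp in state.completed:
        out[comp.imputation_index] = within_trial_results(
            state.data.patients,
            comp.utility_values,
            state.data.resource_use,
            state.config.costing,
            tail=state.config.utility_tail,
        )
    return out


def build_profiles(state: PipelineState) -> pd.DataFrame:
    """End-of-trial profiles feeding the extrapolation.

    Risk factors come from the imputation-averaged table at each patient's
    last on-study visit; age and diabetes duration are advanced to the end
    of follow-up; event history collects the complications experienced
    during the trial; the post-trial base utility is the across-imputation
    mean utility at the last visit.  Patients who died on study carry
    ``alive=False`` and contribute zeros post-trial.
    """
    pat = state.data.patients
    rf = state.averaged_risk_factors.sort_values("visit_time")
    last_rf = rf.groupby("patient_id").tail(1).set_index("patient_id")

    # across-imputation mean utility at each patient's last visit
    last_u_frames = []
    for comp in state.completed:
        uv = comp.utility_values.sort_values("visit_time")
        last_u_frames.append(uv.groupby("patient_id")["utility"].last())
    base_utility = pd.concat(last_u_frames, axis=1).mean(axis=1)

    events = state.data.events
    history_map = (
        events[events["event"] != "death"].groupby("patient_id")["event"].agg(tuple)
        if len(events)
        else pd.Series(dtype=object)
    )

    ru = state.data.resource_use
    last_period = ru.sort_values("period_start").groupby("patient_id").tail(1)
    span = (last_period["period_end"] - last_period["period_start"]).clip(lower=1e-6)
    compliance = (
        (last_period["study_drug_doses"] / (52.0 * span))
        .clip(upper=1.0)
        .set_axis(last_period["patient_id"])
    )

    prof = pd.DataFrame(
        {
            "patient_id": pat["patient_id"],
            "arm": pat["arm"],
            "sex": pat["sex"],
            "smoking": pat["smoking"],
            "age": pat["age"] + pat["followup_end"],
            "diabetes_duration": pat["diabetes_duration"] + pat["followup_end"],
            "followup_years": pat["followup_end"],
            "alive": pat["death_time"].isna(),
        }
    )
    for name in RISK_FACTOR_REGISTRY:
        prof[name] = prof["patient_id"].map(last_rf[name])
    prof["base_utility"] = prof["patient_id"].map(base_utility)
    prof["compliance"] = prof["patient_id"].map(compliance).fillna(0.0)
    prof["history"] = prof["patient_id"].map(history_map)
    prof["history"] = prof["history"].apply(lambda h: h if isinstance(h, tuple) else ())
    prof["crn_id"] = prof.groupby("arm").cumcount()
    return prof


def extrapolate(
    state: PipelineState,
    profiles: pd.DataFrame,
    equations=None,
    tables: EventTable | None = None,
    covariance: pd.DataFrame | None = None,
    simulation: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Run the microsimulation for the point estimate and every coefficient draw."""
    cfg = simulation or state.config.simulation
    eqs = equations or default_risk_equations()
    tbl = tables or default_event_tables(state.config.country)
    if covariance is None:
        covariance = default_coefficient_covariance(eqs)
    sets = draw_coefficients(eqs, covariance, cfg.n_coefficient_draws, cfg.seed + 7)
    return simulate_cohort(profiles, sets, tbl, cfg)


def default_coefficient_covariance(equations) -> pd.DataFrame:
    """Small diagonal parameter uncertainty (5% relative SE, floored at 0.02)."""
    labels = [f"{eq.name}:{term}" for eq in equations for term in eq.coefficients]
    point = np.array([b for eq in equations for b in eq.coefficients.values()])
    sd = np.maximum(0.05 * np.abs(point), 0.02)
    return pd.DataFrame(np.diag(sd**2), index=labels, columns=labels)


def post_trial_differences(post: pd.DataFrame) -> pd.DataFrame:
    """Per-draw active-control differences of the discounted post-trial means."""
    wide = post.set_index(["draw", "arm"]).unstack("arm")
    out = pd.DataFrame(index=wide.index)
    for col, name in [
        ("cost_total", "d_cost_post"),
        ("qalys", "d_qaly_post"),
        ("life_years", "d_ly_post"),
        ("cost_study_drug", "d_drug_cost_post"),
    ]:
        out[name] = wide[(col, "active")] - wide[(col, "control")]
    return out.reset_index()


def run_all(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    state: PipelineState | None = None,
) -> PipelineResult:
    """Execute the full pipeline and assemble the cost-effectiveness outputs."""
    state = state or prepare_state(config)
    within = within_trial_by_imputation(state)
    profiles = build_profiles(state)
    post = extrapolate(state, profiles)
    result = analyse(state, within, profiles, post)
    if out_dir is not None:
        write_artifacts(result, Path(out_dir))
    return result


def analyse(
    state: PipelineState,
    within: dict[int, pd.DataFrame],
    profiles: pd.DataFrame,
    post: pd.DataFrame,
    metadata: dict | None = None,
) -> PipelineResult:
    """Bootstrap, pair with coefficient draws, combine periods, summarise."""
    config = state.config
    boot = bootstrap_within_trial(within, config.bootstrap_replicates, config.seed)
    post_diff = post_trial_differences(post)
    replicates = combine_periods(boot, post_diff[["draw", "d_cost_post", "d_qaly_post"]])

    # point estimates: across-imputation means within trial + draw-0 post-trial
    d_cost_wt = np.mean(
        [r.groupby("arm")["total_cost"].mean().diff(-1)["active"] for r in within.values()]
    )
    d_qaly_wt = np.mean([baseline_adjust(r).difference for r in within.values()])
    d_ly_wt = np.mean(
        [r.groupby("arm")["life_years"].mean().diff(-1)["active"] for r in within.values()]
    )
    point_post = post_diff[post_diff["draw"] == 0].iloc[0]
    cea_out = summarize_replicates(
        replicates,
        point_delta_cost=float(d_cost_wt + point_post["d_cost_post"]),
        point_delta_qaly=float(d_qaly_wt + point_post["d_qaly_post"]),
        point_delta_ly=float(d_ly_wt + point_post["d_ly_post"]),
        thresholds=config.thresholds,
        metadata={
            "n_patients": int(len(state.data.patients)),
            "m": config.imputation.m_utility,
            "replicates": config.bootstrap_replicates,
            "n_draws": config.simulation.n_coefficient_draws,
            "country": config.country,
            **(metadata or {}),
        },
    )
    table = _lifetime_summary(within, post)
    return PipelineResult(state, within, profiles, post, replicates, cea_out, table)


def _lifetime_summary(within: dict[int, pd.DataFrame], post: pd.DataFrame) -> pd.DataFrame:
    point = post[post["draw"] == 0].set_index("arm")
    components: dict[str, dict[str, tuple[float, float]]] = {}
    qaly_adj = {}
    for arm in ("active", "control"):
        adjs = [baseline_adjust(r) for r in within.values()]
        qaly_adj[arm] = np.mean(
            [a.adjusted_mean_active if arm == "active" else a.adjusted_mean_control for a in adjs]
        )
    wt_mean = lambda col: {
        arm: np.mean([r.groupby("arm")[col].mean()[arm] for r in within.values()])
        for arm in ("active", "control")
    }
    post_other = point["cost_complication"] + point["cost_background"]
    for quantity, wt_col, post_col in [
        ("therapy_cost", "therapy_cost", "cost_therapy"),
        ("other_cost", "other_cost", None),
        ("total_cost", "total_cost", "cost_total"),
        ("qalys", None, "qalys"),
        ("life_years", "life_years", "life_years"),
    ]:
        wt = wt_mean(wt_col) if wt_col else qaly_adj
        components[quantity] = {
            arm: (
                float(wt[arm]),
                float(post_other[arm] if post_col is None else point.loc[arm, post_col]),
            )
            for arm in ("active", "control")
        }
    return lifetime_table(components, check_additivity=False)


def run_scenarios(
    state: PipelineState,
    scenarios: Sequence[Scenario],
) -> dict[str, CEAOutput]:
    """Re-run the downstream pipeline under each scenario's config delta.

    Price-discount scenarios rescale the study-drug price only; subgroup
    scenarios filter the cohort before analysis (an empty subgroup is
    reported in the output metadata rather than raising).  Random streams
    are shared with the base run.
    """
    results: dict[str, CEAOutput] = {}
    for sc in scenarios:
        sc.validate()
        sub_state = state
        config = state.config
        costing = dataclasses.replace(config.costing)
        sim = dataclasses.replace(config.simulation)
        tables = default_event_tables(config.country)
        if sc.price_discount is not None:
            costing.study_drug_price_per_dose *= 1.0 - sc.price_discount
            tables.study_drug_price_per_dose *= 1.0 - sc.price_discount
        if sc.discount_rate is not None:
            costing.discount_rate = sc.discount_rate
            sim.discount_rate_cost = sc.discount_rate
            sim.discount_rate_effect = sc.discount_rate
        if sc.trajectory_mode is not None:
            sim.trajectory_mode = sc.trajectory_mode
        if sc.discontinuation_scenario is not None:
            sim.discontinuation_scenario = sc.discontinuation_scenario
        if sc.utility_decrements is not None:
            tables.utility_event = dict(tables.utility_event) | dict(sc.utility_decrements)

        if sc.subgroup is not None:
            keep_mask = sc.subgroup(state.data.patients)
            keep = set(state.data.patients.loc[keep_mask, "patient_id"])
            if not keep:
                results[sc.name] = None  # type: ignore[assignment]
                continue
            sub_state = _filter_state(state, keep)
        sub_state = dataclasses.replace(
            sub_state, config=dataclasses.replace(config, costing=costing, simulation=sim)
        )
        within = within_trial_by_imputation(sub_state)
        profiles = build_profiles(sub_state)
        post = extrapolate(sub_state, profiles, tables=tables, simulation=sim)
        res = analyse(sub_state, within, profiles, post, metadata={"scenario": sc.name})
        res.cea.metadata["subgroup_n"] = int(len(sub_state.data.patients))
        results[sc.name] = res.cea
    return results


def _filter_state(state: PipelineState, keep: set) -> PipelineState:
    def f(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["patient_id"].isin(keep)].reset_index(drop=True)

    data = TrialData(
        f(state.data.patients),
        f(state.data.utilities),
        f(state.data.resource_use),
        f(state.data.events),
        f(state.data.risk_factors),
        dict(state.data.ground_truth),
    )
    completed = [
        CompletedDataset(
            c.imputation_index,
            f(c.utility_values),
            f(c.risk_factors),
            f(c.utility_imputed),
            f(c.risk_factor_imputed),
        )
        for c in state.completed
    ]
    return PipelineState(
        state.config,
        data,
        state.masks,
        state.value_set,
        state.crosswalk,
        f(state.utility_values),
        completed,
        f(state.averaged_risk_factors),
    )


def write_artifacts(result: PipelineResult, out_dir: Path) -> dict:
    """Write the plot-ready CSV artifacts and the run manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lifetime_table.csv": result.table,
        "ce_plane.csv": result.cea.plane,
        "ceac.csv": result.cea.ceac,
        "summary.csv": result.cea.summary(),
        "replicates.csv": result.replicates,
    }
    hashes = {}
    for name, frame in paths.items():
        p = out_dir / name
        frame.to_csv(p, index=False)
        hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "version": __version__,
        "config": result.state.config.to_dict(),
        "seeds": {
            "pipeline": result.state.config.seed,
            "generator": result.state.config.generator.seed,
            "imputation": result.state.config.imputation.seed,
            "simulation": result.state.config.simulation.seed,
        },
        "artifact_sha256": hashes,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "metadata": result.cea.metadata,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
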