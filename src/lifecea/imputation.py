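"""Missing-data handling.

Three layers, mirroring common trial-analysis practice:

1. Deterministic baseline imputation — baseline EQ-5D utility, height and
   weight by sex-stratified means of observed values; smoking status by the
   per-country mode.
2. Chained-equations multiple imputation of post-baseline EQ-5D utilities
   and per-visit risk-factor values, run *separately* for the two variable
   groups.  The default continuous method is predictive mean matching (PMM,
   5 donors), so every imputed value equals some observed donor value and
   stays inside the observed range; a Bayesian linear alternative is
   available.  Regression coefficients are drawn from their posterior before
   each imputation, giving positive between-imputation variance.
3. Across-imputation averaging of imputed risk-factor values (observed cells
   pass through untouched), producing the single complete risk-factor table
   that feeds the extrapolation engine.

Visits after a patient's end of follow-up are structurally absent, never
imputed.  Observed cells are preserved bitwise by every operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import RISK_FACTOR_REGISTRY, TrialData

logger = logging.getLogger(__name__)

_DEFAULT_PREDICTORS = ("arm", "age", "sex", "diabetes_duration", "prior_cvd", "u@0")


@dataclass
class ImputationConfig:
    m_utility: int = 28
    chained_iterations: int = 10
    predictor_sets: Mapping[str, Sequence[str]] = field(default_factory=dict)
    seed: int = 0
    continuous_method: str = "predictive-mean-matching"  # or "linear"
    n_donors: int = 5

    def validate(self) -> None:
        if self.m_utility < 2:
            raise ValueError("at least 2 imputations are required")
        if self.chained_iterations < 1:
            raise ValueError("at least 1 chained iteration is required")
        if self.continuous_method not in ("predictive-mean-matching", "linear"):
            raise ValueError(f"unknown continuous method {self.continuous_method!r}")
        if self.n_donors < 1:
            raise ValueError("PMM needs at least one donor")


@dataclass
class CompletedDataset:
    """One completed copy of the imputed tables plus per-cell provenance."""

    imputation_index: int
    utility_values: pd.DataFrame  # patient_id, visit_time, utility (complete)
    risk_factors: pd.DataFrame  # patient_id, visit_time, <factors> (complete)
    utility_imputed: pd.DataFrame  # same keys, bool 'imputed'
    risk_factor_imputed: pd.DataFrame  # same keys, bool per factor


def impute_baseline(
    data: TrialData, utility_values: pd.DataFrame
) -> tuple[TrialData, pd.DataFrame, list[str]]:
    """Deterministic baseline imputation.

    Fills missing height/weight with the sex-stratified mean of observed
    values (falling back to the overall mean for an empty stratum, logged),
    missing smoking with the per-country mode, and missing baseline (time 0)
    utility with the sex mean.  No other cells are touched.
    """
    out = data.copy()
    uv = utility_values.copy()
    log: list[str] = []
    pat = out.patients

    for col in ("height", "weight"):
        if pat[col].isna().any():
            overall = pat[col].mean()
            for sex, grp in pat.groupby("sex"):
                fill = grp[col].mean()
                if np.isnan(fill):
                    fill = overall
                    msg = f"no observed {col} for sex={sex}; using overall mean"
                    log.append(msg)
                    logger.warning(msg)
                idx = grp.index[grp[col].isna()]
                pat.loc[idx, col] = fill

    if pat["smoking"].isna().any():
        overall_mode = pat["smoking"].mode().iloc[0]
        for country, grp in pat.groupby("country_setting"):
            modes = grp["smoking"].mode()
            fill = modes.iloc[0] if len(modes) else overall_mode
            idx = grp.index[grp["smoking"].isna()]
            pat.loc[idx, "smoking"] = fill

    base = uv["visit_time"] == 0
    if uv.loc[base, "utility"].isna().any():
        sex_map = pat.set_index("patient_id")["sex"]
        sexes = uv.loc[base, "patient_id"].map(sex_map)
        observed = uv.loc[base & uv["utility"].notna()]
        means = observed.groupby(observed["patient_id"].map(sex_map))["utility"].mean()
        overall = observed["utility"].mean()
        for sex in sexes.unique():
            fill = means.get(sex, np.nan)
            if np.isnan(fill):
                fill = overall
                msg = f"no observed baseline utility for sex={sex}; using overall mean"
                log.append(msg)
                logger.warning(msg)
            idx = uv.index[base & uv["utility"].isna() & (sexes == sex).reindex(uv.index, fill_value=False)]
            uv.loc[idx, "utility"] = fill
    return out, uv, log


# ---------------------------------------------------------------------------
# Chained-equations engine on a wide numeric frame


def _posterior_beta(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Least-squares fit plus an approximate posterior draw of the coefficients."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    XtX = X.T @ X
    try:
        cov = np.linalg.pinv(XtX) * sigma**2
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
        beta_draw = beta + L @ rng.standard_normal(p)
    except np.linalg.LinAlgError:
        beta_draw = beta
    return beta_draw, sigma


def _pmm_match(
    yhat_mis: np.ndarray,
    yhat_obs: np.ndarray,
    y_obs: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each missing prediction pick one of the k nearest observed donors."""
    order = np.argsort(yhat_obs, kind="stable")
    sorted_pred = yhat_obs[order]
    sorted_y = y_obs[order]
    n = len(sorted_pred)
    k = min(k, n)
    pos = np.searchsorted(sorted_pred, yhat_mis)
    out = np.empty(len(yhat_mis))
    for i, (p0, target) in enumerate(zip(pos, yhat_mis)):
        lo = max(0, p0 - k)
        hi = min(n, p0 + k)
        cand = np.arange(lo, hi)
        dist = np.abs(sorted_pred[cand] - target)
        nearest = cand[np.argsort(dist, kind="stable")[:k]]
        out[i] = sorted_y[rng.choice(nearest)]
    return out


def _chained_impute(
    wide: pd.DataFrame,
    predictor_map: Mapping[str, Sequence[str]],
    target_mask: pd.DataFrame,
    rng: np.random.Generator,
    config: ImputationConfig,
) -> pd.DataFrame:
    """One chained-equations completion of ``wide``.

    ``target_mask`` marks the cells to impute (True); cells that are NaN but
    unmarked are structurally absent and left alone.  Columns without any
    marked cell act as predictors only.
    """
    data = wide.copy()
    targets = [c for c in target_mask.columns if target_mask[c].any()]
    # initialise target cells with random draws from the observed values
    for col in targets:
        mis = target_mask[col].to_numpy()
        obs_vals = data.loc[~mis, col].dropna().to_numpy()
        if obs_vals.size == 0:
            raise ValueError(f"variable {col!r} has no observed values to impute from")
        data.loc[mis, col] = rng.choice(obs_vals, size=int(mis.sum()))

    for _ in range(config.chained_iterations):
        for col in targets:
            mis = target_mask[col].to_numpy()
            applicable = (~data[col].isna()).to_numpy() | mis
            preds = list(predictor_map.get(col, ())) or [
                c for c in data.columns if c != col
            ]
            preds = [p for p in preds if p != col]
            sub = data.loc[applicable, preds].to_numpy(dtype=float)
            if np.isnan(sub).any():
                raise ValueError(
                    f"predictors {preds} contain structurally missing values for {col}"
                )
            X = np.column_stack([np.ones(len(sub)), sub])
            y = data.loc[applicable, col].to_numpy(dtype=float)
            mis_sub = mis[applicable]
            obs_sub = ~mis_sub
            if obs_sub.sum() <= X.shape[1]:
                # too few observed rows for a regression: fall back to mean + noise
                logger.warning("variable %s: too few observed rows, mean imputation", col)
                fill = y[obs_sub].mean()
                data.loc[mis, col] = fill
                continue
            beta, sigma = _posterior_beta(X[obs_sub], y[obs_sub], rng)
            yhat_mis = X[mis_sub] @ beta
            if config.continuous_method == "predictive-mean-matching":
                imputed = _pmm_match(
                    yhat_mis, X[obs_sub] @ beta, y[obs_sub], config.n_donors, rng
                )
            else:
                imputed = yhat_mis + rng.normal(0.0, sigma, size=len(yhat_mis))
            data.loc[mis, col] = imputed
    return data


def _utility_wide(utility_values: pd.DataFrame, patients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[float]]:
    """Pivot utilities to one column per visit, plus always-observed predictors."""
    times = sorted(utility_values["visit_time"].unique())
    wide = utility_values.pivot(index="patient_id", columns="visit_time", values="utility")
    wide.columns = [f"u@{t:g}" for t in wide.columns]
    scheduled = utility_values.pivot_table(
        index="patient_id", columns="visit_time", values="utility", aggfunc="size"
    ).notna()
    scheduled.columns = [f"u@{t:g}" for t in scheduled.columns]
    pat = patients.set_index("patient_id")
    wide["arm"] = (pat["arm"] == "active").astype(float)
    wide["age"] = pat["age"]
    wide["sex"] = (pat["sex"] == "female").astype(float)
    wide["diabetes_duration"] = pat["diabetes_duration"]
    wide["prior_cvd"] = pat["prior_cvd"].astype(float)
    mask = scheduled & wide[scheduled.columns].isna()
    return wide, mask, times


def mice_impute(
    data: TrialData, utility_values: pd.DataFrame, config: ImputationConfig
) -> list[CompletedDataset]:
    """Chained-equations multiple imputation of utilities and risk factors.

    Runs the two chained models separately (utilities; per-visit risk
    factors) and returns ``m`` completed datasets.  Observed cells are
    identical across all copies; different seeds change only the imputed
    cells.  Default predictors: arm, age, sex, diabetes duration, prior CVD,
    baseline utility and the variable's own previous-visit value.
    """
    config.validate()
    if utility_values.loc[utility_values["visit_time"] == 0, "utility"].isna().any():
        raise ValueError("baseline utilities incomplete: run impute_baseline first")
    root = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x1CE])
    seeds = root.spawn(config.m_utility)

    wide_u, mask_u, times = _utility_wide(utility_values, data.patients)
    ucols = [f"u@{t:g}" for t in times]
    upred: dict[str, list[str]] = {}
    for i, t in enumerate(times):
        if t == 0:
            continue
        col = f"u@{t:g}"
        preds = list(config.predictor_sets.get(col, _DEFAULT_PREDICTORS))
        lag = f"u@{times[i - 1]:g}"
        if lag not in preds and lag != col:
            preds.append(lag)
        upred[col] = preds

    rf = data.risk_factors
    rf_times = sorted(rf["visit_time"].unique())
    wide_rf = rf.pivot(index="patient_id", columns="visit_time", values=list(RISK_FACTOR_REGISTRY))
    wide_rf.columns = [f"{name}@{t:g}" for name, t in wide_rf.columns]
    scheduled_rf = rf.pivot_table(index="patient_id", columns="visit_time", aggfunc="size").notna()
    mask_rf = pd.DataFrame(index=wide_rf.index)
    for name in RISK_FACTOR_REGISTRY:
        for t in rf_times:
            col = f"{name}@{t:g}"
            mask_rf[col] = scheduled_rf[t].reindex(wide_rf.index, fill_value=False) & wide_rf[col].isna()
    pat = data.patients.set_index("patient_id")
    base_u = wide_u["u@0"] if "u@0" in wide_u.columns else None
    wide_rf["arm"] = (pat["arm"] == "active").astype(float)
    wide_rf["age"] = pat["age"]
    wide_rf["sex"] = (pat["sex"] == "female").astype(float)
    wide_rf["diabetes_duration"] = pat["diabetes_duration"]
    wide_rf["prior_cvd"] = pat["prior_cvd"].astype(float)
    if base_u is not None:
        wide_rf["u@0"] = base_u
    rfpred: dict[str, list[str]] = {}
    for name in RISK_FACTOR_REGISTRY:
        for i, t in enumerate(rf_times):
            if t == 0:
                continue
            col = f"{name}@{t:g}"
            preds = list(config.predictor_sets.get(col, _DEFAULT_PREDICTORS))
            lag = f"{name}@{rf_times[i - 1]:g}"
            if lag not in preds:
                preds.append(lag)
            rfpred[col] = preds

    out: list[CompletedDataset] = []
    for j, ss in enumerate(seeds, start=1):
        rng = np.random.default_rng(ss)
        comp_u = _chained_impute(wide_u, upred, mask_u, rng, config)
        comp_rf = _chained_impute(wide_rf, rfpred, mask_rf, rng, config)

        uv = utility_values.copy()
        key = pd.MultiIndex.from_frame(uv[["patient_id", "visit_time"]])
        long_u = comp_u[ucols].stack(future_stack=True)
        long_u.index = pd.MultiIndex.from_tuples(
            [(pid, float(c.split("@")[1])) for pid, c in long_u.index]
        )
        uv["utility"] = long_u.reindex(key).to_numpy()
        u_imp = mask_u[ucols].stack(future_stack=True)
        u_imp.index = long_u.index
        u_flags = uv[["patient_id", "visit_time"]].copy()
        u_flags["imputed"] = u_imp.reindex(key).fillna(False).to_numpy(dtype=bool)

        rf_long = rf.copy()
        rf_key = pd.MultiIndex.from_frame(rf_long[["patient_id", "visit_time"]])
        rf_flags = rf_long[["patient_id", "visit_time"]].copy()
        for name in RISK_FACTOR_REGISTRY:
            cols = [f"{name}@{t:g}" for t in rf_times]
            series = comp_rf[cols].stack(future_stack=True)
            series.index = pd.MultiIndex.from_tuples(
                [(pid, float(c.split("@")[1])) for pid, c in series.index]
            )
            rf_long[name] = series.reindex(rf_key).to_numpy()
            flags = mask_rf[cols].stack(future_stack=True)
            flags.index = series.index
            rf_flags[name] = flags.reindex(rf_key).fillna(False).to_numpy(dtype=bool)

        out.append(CompletedDataset(j, uv, rf_long, u_flags, rf_flags))
    return out


def average_risk_factor_imputations(completed: Sequence[CompletedDataset]) -> pd.DataFrame:
    """Across-imputation mean of imputed risk-factor cells; observed cells unchanged.

    Returns a complete risk-factor table (no nulls) suitable as simulation
    input.
    """
    if len(completed) == 0:
        raise ValueError("need at least one completed dataset")
    first = completed[0].risk_factors
    for c in completed[1:]:
        if c.risk_factors.shape != first.shape or not (
            c.risk_factors[["patient_id", "visit_time"]]
            .reset_index(drop=True)
            .equals(first[["patient_id", "visit_time"]].reset_index(drop=True))
        ):
            raise ValueError("completed datasets have inconsistent risk-factor tables")
    out = first.copy()
    flags = completed[0].risk_factor_imputed
    for name in RISK_FACTOR_REGISTRY:
        stacked = np.column_stack([c.risk_factors[name].to_numpy() for c in completed])
        observed = ~flags[name].to_numpy(dtype=bool)
        # observed cells must agree bitwise across imputations
        if observed.any() and not all(
            np.array_equal(stacked[observed, 0], stacked[observed, i])
            for i in range(stacked.shape[1])
        ):
            raise ValueError(f"observed cells of {name} differ across imputations")
        mean = stacked.mean(axis=1)
        out[name] = np.where(observed, stacked[:, 0], mean)
    if out[list(RISK_FACTOR_REGISTRY)].isna().any().any():
        raise ValueError("averaged risk-factor table still contains nulls")
    return out
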