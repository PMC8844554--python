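"""Uncertainty propagation and cost-effectiveness outputs.

Within-trial uncertainty comes from a patient-level bootstrap (stratified by
arm, with the baseline-utility adjustment re-fit inside every replicate) run
separately on each of the m imputed datasets; post-trial uncertainty comes
from multivariate-normal draws of the risk-equation coefficients.  Replicate
b of imputation i is paired with coefficient draw ((i-1)*B + b - 1) mod
n_draws + 1, and the paired incremental costs and QALYs are added to give
the lifetime replicate cloud, from which ICERs, percentile confidence
intervals, cost-effectiveness-plane points and acceptability curves are
computed.  Percentiles use the linear-interpolation (type-7) rule.

ICERs are never averaged across replicates with non-positive incremental
QALYs; the ratio is reported undefined there and uncertainty summarised on
the plane/CEAC instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import ancova_difference

QUADRANTS = {
    (1, 1): "NE",
    (1, -1): "SE (dominant)",
    (-1, 1): "NW (dominated)",
    (-1, -1): "SW",
}


def icer(delta_cost: float, delta_qaly: float) -> tuple[float, str]:
    """Incremental cost-effectiveness ratio with CE-plane quadrant label.

    Returns (ratio, quadrant).  The ratio is NaN (undefined) whenever the
    QALY difference is non-positive; the label then carries the information
    (dominated / SW / boundary).
    """
    sq = 1 if delta_qaly > 0 else -1
    sc = 1 if delta_cost > 0 else -1
    if delta_qaly == 0:
        label = "NW (boundary)" if delta_cost >= 0 else "SW (boundary)"
        return math.nan, label
    label = QUADRANTS[(sq, sc)]
    if delta_qaly > 0:
        return delta_cost / delta_qaly, label
    return math.nan, label


def percentile_ci(
    values: Sequence[float], lower: float = 0.025, upper: float = 0.975
) -> tuple[float, float]:
    """Empirical percentile interval (linear / type-7 interpolation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    lo, hi = np.quantile(arr, [lower, upper], method="linear")
    return float(lo), float(hi)


def ceac(
    replicates: pd.DataFrame,
    thresholds: Sequence[float],
    cost_col: str = "d_cost",
    qaly_col: str = "d_qaly",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay threshold, the fraction of replicates with
    positive net monetary benefit (threshold * dQALY - dCost > 0).
    """
    thr = np.asarray(thresholds, dtype=float)
    if (thr < 0).any():
        raise ValueError("thresholds must be non-negative")
    dq = replicates[qaly_col].to_numpy()[:, None]
    dc = replicates[cost_col].to_numpy()[:, None]
    prob = (thr[None, :] * dq - dc > 0).mean(axis=0)
    return pd.DataFrame({"threshold": thr, "probability": prob})


def bootstrap_within_trial(
    per_imputation_results: Mapping[int, pd.DataFrame],
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Patient-level bootstrap of within-trial incremental cost and QALYs.

    Resamples patients with replacement within each arm, re-fitting the
    baseline-utility adjustment of QALYs in every replicate (cost differences
    are unadjusted means).  Returns one row per (imputation, replicate) with
    columns d_cost_within / d_qaly_within.  Seeded per imputation, so the
    replicate table is reproducible regardless of iteration order.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    rows = []
    for i, results in sorted(per_imputation_results.items()):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xB0, i]))
        active = results[results["arm"] == "active"]
        control = results[results["arm"] == "control"]
        if len(active) == 0 or len(control) == 0:
            raise ValueError("both arms must be non-empty for the bootstrap")
        a_cost = active["total_cost"].to_numpy()
        c_cost = control["total_cost"].to_numpy()
        a_q = active["qalys"].to_numpy()
        c_q = control["qalys"].to_numpy()
        a_b = active["baseline_utility"].to_numpy()
        c_b = control["baseline_utility"].to_numpy()
        na, nc = len(active), len(control)
        for b in range(1, n_replicates + 1):
            ia = rng.integers(0, na, size=na)
            ic = rng.integers(0, nc, size=nc)
            d_cost = a_cost[ia].mean() - c_cost[ic].mean()
            y = np.concatenate([a_q[ia], c_q[ic]])
            base = np.concatenate([a_b[ia], c_b[ic]])
            act = np.concatenate([np.ones(na), np.zeros(nc)])
            d_qaly = ancova_difference(y, base, act)
            rows.append((i, b, d_cost, d_qaly))
    return pd.DataFrame(
        rows, columns=["imputation", "replicate", "d_cost_within", "d_qaly_within"]
    )


def combine_periods(
    within: pd.DataFrame, post: pd.DataFrame, n_draws: int | None = None
) -> pd.DataFrame:
    """Pair within-trial bootstrap replicates with post-trial coefficient draws.

    ``post`` has one row per coefficient draw with columns d_cost_post /
    d_qaly_post (draw 0 = point estimate is excluded from pairing).
    Replicates are paired with stochastic draws cyclically; lifetime values
    are the elementwise sums, so lifetime = within + post holds exactly per
    row.
    """
    post_stoch = post[post["draw"] > 0].sort_values("draw").reset_index(drop=True)
    if len(post_stoch) == 0:
        raise ValueError("post-trial table has no stochastic draws (only draw 0)")
    n_draws = n_draws or len(post_stoch)
    out = within.sort_values(["imputation", "replicate"]).reset_index(drop=True).copy()
    idx = np.arange(len(out)) % n_draws
    out["draw"] = post_stoch["draw"].to_numpy()[idx]
    out["d_cost_post"] = post_stoch["d_cost_post"].to_numpy()[idx]
    out["d_qaly_post"] = post_stoch["d_qaly_post"].to_numpy()[idx]
    out["d_cost"] = out["d_cost_within"] + out["d_cost_post"]
    out["d_qaly"] = out["d_qaly_within"] + out["d_qaly_post"]
    return out


@dataclass
class CEAOutput:
    """Point estimates, uncertainty summaries and plot-ready tables."""

    delta_cost: float
    delta_qaly: float
    delta_life_years: float
    icer: float
    icer_quadrant: str
    ci_cost: tuple[float, float]
    ci_qaly: tuple[float, float]
    ci_icer: tuple[float, float] | None
    plane: pd.DataFrame
    ceac: pd.DataFrame
    quadrant_shares: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [
            ("incremental_cost", self.delta_cost, *self.ci_cost),
            ("incremental_qalys", self.delta_qaly, *self.ci_qaly),
            ("incremental_life_years", self.delta_life_years, math.nan, math.nan),
            (
                "icer",
                self.icer,
                *(self.ci_icer if self.ci_icer else (math.nan, math.nan)),
            ),
        ]
        return pd.DataFrame(rows, columns=["quantity", "estimate", "ci_lower", "ci_upper"])


DEFAULT_THRESHOLDS = tuple(np.arange(0, 300001, 1000, dtype=float))


def summarize_replicates(
    replicates: pd.DataFrame,
    point_delta_cost: float,
    point_delta_qaly: float,
    point_delta_ly: float = math.nan,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    metadata: dict | None = None,
) -> CEAOutput:
    """Assemble the CEA output from the lifetime replicate table.

    The percentile CI on the ICER itself is reported only when every
    replicate lies in the north-east quadrant (otherwise the ratio does not
    order monotonically and the CI is left undefined).
    """
    dc = replicates["d_cost"].to_numpy()
    dq = replicates["d_qaly"].to_numpy()
    ratio, quadrant = icer(point_delta_cost, point_delta_qaly)
    all_ne = bool((dq > 0).all() and (dc > 0).all())
    ci_icer = percentile_ci(dc / dq) if all_ne else None
    shares = {
        "NE": float(((dq > 0) & (dc > 0)).mean()),
        "SE": float(((dq > 0) & (dc <= 0)).mean()),
        "NW": float(((dq <= 0) & (dc > 0)).mean()),
        "SW": float(((dq <= 0) & (dc <= 0)).mean()),
    }
    return CEAOutput(
        delta_cost=point_delta_cost,
        delta_qaly=point_delta_qaly,
        delta_life_years=point_delta_ly,
        icer=ratio,
        icer_quadrant=quadrant,
        ci_cost=percentile_ci(dc),
        ci_qaly=percentile_ci(dq),
        ci_icer=ci_icer,
        plane=replicates[["d_qaly", "d_cost"]].copy(),
        ceac=ceac(replicates, thresholds),
        quadrant_shares=shares,
        metadata=metadata or {},
    )


_PERIODS = ("within_trial", "post_trial")


def lifetime_table(
    components: Mapping[str, Mapping[str, tuple[float, float]]],
    check_additivity: bool = True,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Assemble the within/post/lifetime summary table.

    ``components[quantity][arm] = (within, post)``; arms are 'active' and
    'control'.  Lifetime = within + post per arm; the difference column is
    active - control.  If therapy_cost, other_cost and total_cost are all
    present, total = therapy + other is verified per period and arm within
    ``atol``.
    """
    rows = []
    for quantity, arms in components.items():
        if set(arms) != {"active", "control"}:
            raise ValueError(f"{quantity}: need both arms")
        for arm_name in ("active", "control"):
            within, post = arms[arm_name]
            rows.append((quantity, arm_name, within, post, within + post))
    frame = pd.DataFrame(rows, columns=["quantity", "arm", "within_trial", "post_trial", "lifetime"])
    diff = (
        frame.set_index(["quantity", "arm"])
        .unstack("arm")
        .swaplevel(axis=1)
    )
    out_rows = []
    for quantity in components:
        for period in ("within_trial", "post_trial", "lifetime"):
            a = diff.loc[quantity, ("active", period)]
            c = diff.loc[quantity, ("control", period)]
            out_rows.append((quantity, period, a, c, a - c))
    out = pd.DataFrame(out_rows, columns=["quantity", "period", "active", "control", "difference"])
    if check_additivity and {"therapy_cost", "other_cost", "total_cost"} <= set(components):
        pivot = out.set_index(["quantity", "period"])
        for period in ("within_trial", "post_trial", "lifetime"):
            for col in ("active", "control", "difference"):
                total = pivot.loc[("total_cost", period), col]
                parts = (
                    pivot.loc[("therapy_cost", period), col]
                    + pivot.loc[("other_cost", period), col]
                )
                if abs(total - parts) > atol:
                    raise ValueError(
                        f"total_cost != therapy + other for {period}/{col}: "
                        f"{total} vs {parts}"
                    )
    return out


@dataclass
class Scenario:
    """A named configuration delta for sensitivity / subgroup analysis."""

    name: str
    price_discount: float | None = None  # fraction off the study-drug price
    discount_rate: float | None = None  # applied to costs and effects
    trajectory_mode: str | None = None
    discontinuation_scenario: str | None = None
    subgroup: Callable[[pd.DataFrame], pd.Series] | None = None  # patients -> bool mask
    utility_decrements: Mapping[str, float] | None = None

    def validate(self) -> None:
        if self.price_discount is not None and not 0 <= self.price_discount <= 1:
            raise ValueError("price discount must lie in [0, 1]")


def standard_scenarios() -> list[Scenario]:
    """The canonical sensitivity grid: price discounts, discontinuation, subgroups."""
    grid = [Scenario(f"price_discount_{int(d*100)}", price_discount=d) for d in (0.2, 0.4, 0.6, 0.8)]
    grid += [
        Scenario("discontinuation_scenario1", discontinuation_scenario="scenario1"),
        Scenario("discontinuation_scenario2", discontinuation_scenario="scenario2"),
        Scenario("subgroup_age_65_plus", subgroup=lambda p: p["age"] >= 65),
        Scenario("subgroup_duration_lt_5", subgroup=lambda p: p["diabetes_duration"] < 5),
        Scenario("subgroup_prior_cvd", subgroup=lambda p: p["prior_cvd"].astype(bool)),
        Scenario("subgroup_uk_sites", subgroup=lambda p: p["country_setting"] == "UK"),
        Scenario("subgroup_us_sites", subgroup=lambda p: p["country_setting"] == "US"),
    ]
    return grid
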