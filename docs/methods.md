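# Methods

This note documents the models, defaults and numerical choices behind
`lifecea`, in the order the pipeline runs them.

## Synthetic cohort

`lifecea.cohort` generates a two-arm trial of configurable size emulating a
pragmatic cardiovascular-outcome study in established type 2 diabetes.
Defaults: entry age ~ N(62, 8²) years, 38% female, diabetes duration ~
Gamma(3, 4) (mean 12 y), 73% with prior cardiovascular disease, baseline
HbA1c ~ N(8.0, 1.0)%. Mortality is a discrete annual clock: each year a
patient dies with probability 1 − exp(−λ), λ = 0.022/y in the control arm
times a hazard ratio of 0.86 in the active arm (a small, realistic survival
benefit for a GLP-1 receptor-agonist class add-on). Non-fatal complications
run as independent annual clocks with their own control rates and
active-arm ratios. Follow-up combines staggered administrative censoring
(Uniform(1.0, 6.7) years) with exponential dropout at 0.04/y, giving a
median follow-up near 3.2 years and a maximum of 6.7.

EQ-5D responses are generated at annual visits (years 0–6, capped at
follow-up; the real visit schedule of such trials is not fixed here and is
exposed as config). Each patient answers either the 3L or the 5L instrument
(50/50). Dimension levels are 1 + Binomial(k, p) with k = 2 (3L) or 4 (5L)
and a severity p driven by age, prior CVD, time on study and a patient
frailty — so utilities worsen with age and morbidity, and profile-level
valuation (not utility noise) is what downstream stages see. Risk factors
are re-measured at every visit as baseline + small linear drift + noise.

Missingness: post-baseline EQ-5D profiles go missing wholesale at a
configured rate (default 0.28), either MCAR or MAR-on-age (the MAR intercept
is solved by bisection so the realized rate matches the target); baseline
height/weight/smoking/EQ-5D have their own small rates; post-baseline
risk-factor cells go missing element-wise at 0.10 (a chosen default — the
rate of risk-factor missingness in such trials is not published). Boolean
masks returned alongside the data identify removed cells exactly, and the
generating hazards/effects are serialized as a ground-truth record, so
recovery tests never re-derive them.

What the generator does **not** emulate: event-driven stopping, a run-in
period, correlated missingness across instruments, second events,
treatment switching during the trial. Passing tests therefore demonstrate
that the machinery is correct under the stated data-generating process, not
that any real trial's results are reproduced.

## Missing data

Baseline: missing height/weight and baseline EQ-5D utility are filled with
sex-stratified means of observed values (overall mean, logged, if a stratum
is empty); missing smoking status with the per-country mode. These are
deterministic single imputations.

Post-baseline utilities and per-visit risk factors are multiply imputed by
chained equations, **separately** for the two variable groups, with m = 28
completed datasets by default (matching the convention of one imputation per
percentage point of missingness at ~28%). The chained engine is written
in-package: the widely used library implementation draws from the global
NumPy random state, offers no per-cell provenance, and cannot express
structurally absent cells (visits after a patient's end of follow-up must
never be imputed). Each variable is regressed on its predictor set
(default: arm, age, sex, diabetes duration, prior CVD, baseline utility and
the variable's own previous-visit value); coefficients are drawn from an
approximate normal posterior before each imputation so between-imputation
variance is positive. The default continuous method is predictive mean
matching with 5 donors — imputed values are always observed donor values,
keeping bounded, skewed utilities inside their observed range — with a
Bayesian linear draw as the alternative. Ten chain iterations by default;
PMM has no convergence statistic, so the iteration count is fixed and a
too-few-observations fallback (mean imputation) is logged rather than
fatal. Observed cells are preserved bitwise by construction and asserted in
tests.

For the simulation input, imputed risk-factor values are averaged across the
m completions and combined with the observed values (observed cells pass
through untouched), yielding one complete risk-factor table per patient
visit. Rubin's rules for pooled regression inference are deliberately not
implemented: uncertainty is propagated by the bootstrap × imputation scheme
instead.

## Within-trial economics

Valuation: an additive 3L tariff
`U = 1 − c·1{any>1} − Σ d(dim,level) − n3·1{any=3}`, anchored at 1 for
11111; 5L profiles first map through a deterministic per-dimension
crosswalk (default 1,2,3,4,5 → 1,2,2,3,3). The bundled US-style and
UK-style tariffs are synthetic toys (the UK-style one reaches a negative
floor, as real tariffs do); official value sets load from the documented
CSV schema.

QALYs: trapezoidal area under the piecewise-linear utility curve from
randomization to end of follow-up. The last observed utility is carried
flat to censoring (flag `tail="truncate"` integrates only to the last
observation instead); death inserts an explicit (death time, 0) vertex with
no interpolation across death. Discounting is applied at yearly granularity
by splitting segments at integer year boundaries, year 0 undiscounted —
continuous-time discounting was rejected for simplicity; at 3–3.5% the
difference is far below the Monte-Carlo noise of any quantity reported.

Costs: therapy = study-drug doses × net per-dose price + concomitant
diabetes-medication units × unit cost; everything else is "other". The US
net price default is 119.70 per dose, i.e. a 23.1% discount off an implied
wholesale price of ~155.66; the UK default is 18.94 per dose. Costs are
discounted by accrual year (floor of the period start). total = therapy +
other holds exactly per patient by construction.

Arm contrasts: QALYs via OLS on arm + mean-centred baseline utility
(adjusted means are predictions at the overall mean baseline), guarding
against chance baseline imbalance; costs as unadjusted arm means. A
closed-form normal-equations version of the same ANCOVA is used inside the
bootstrap loop and is verified against the statsmodels fit.

## Lifetime microsimulation

Annual cycle from end of trial to death, horizon (default 40 y) or age cap
(default 100 y). Each year, every complication equation not already in the
patient's history is evaluated and an occurrence drawn; death is evaluated
last so a same-year event can raise mortality risk; event order within the
year is randomized (seeded). A patient alive at the start of a year accrues
that full year's life-year, utility and costs (no half-cycle correction;
flag available that halves the accrual in the year of death). Utility =
end-of-trial base utility − event-year decrements − ongoing decrements for
prior-year history, floored at 0 by default. Costs = therapy + complication
(event-year and ongoing) + background. History flags are first-event
indicators; second events are out of scope.

Risk factors other than age, diabetes duration and event history are held
constant at end-of-trial values in the base case (`linear-drift` mode adds
per-factor slopes). Treatment: active-arm patients continue study drug at
their last-trial-year compliance until death or renal failure, then accrue
the same standard-care therapy cost as the control arm. Scenario 1 stops
study drug at extrapolation year 0 for everyone; scenario 2 applies an
annual stopping probability (default 0.05/y, a placeholder — the observed
first-year discontinuation rate of any particular trial is not published)
during the first 10 extrapolation years. Scenario-2 stop draws come from a
dedicated random stream so event streams stay aligned across scenarios.

Hazard forms: exponential `p = 1 − exp(−exp(lp))`; Weibull and Gompertz use
the cumulative-hazard difference over [t, t+1] with t = diabetes duration
(Weibull) or age (Gompertz); logistic returns the fitted probability. A
Weibull with shape 1 reproduces the exponential exactly (tested).

Discounting clock: the default continues each patient's trial-period clock
(post-trial year k is discounted at (1+r)^−(followup + k)); the alternative
`from-trial-end` starts at extrapolation year 0. Both are implemented
because published within/post/lifetime tables in this literature are
ambiguous about the convention — in one published example the US life-year
rows do not sum while the UK rows do, consistent with differing clocks or
an erratum.

Parameter uncertainty: coefficient sets are multivariate-normal draws
around the point estimates given a covariance matrix (index 0 is reserved
for the point estimate); the default covariance is diagonal with 5%
relative standard errors (floored at 0.02) — a placeholder of the right
order for published risk-equation uncertainty. Common random numbers:
every patient's stream is keyed by (seed, patient rank within arm), so the
same patient sees identical randomness across arms, draws and scenarios;
cloned cohorts difference to exactly zero and scenario contrasts are exact
where the config delta is deterministic (e.g. a price change).

The shipped risk equations are synthetic placeholders calibrated to
plausible annual rates in this population (~2%/y mortality at age 65 rising
on a Gompertz curve; treatment coefficient ln 0.86 on mortality matching the
generator's ground truth); tests target structural correctness, not fidelity
to any published model.

## Uncertainty propagation and outputs

Within-trial: per imputed dataset, patients are resampled with replacement
stratified by arm (B = 800 default), and the baseline-adjusted QALY
difference and unadjusted cost difference are re-estimated per replicate.
Post-trial: per-draw arm differences of the discounted cohort means.
Pairing: replicate b of imputation i is paired cyclically with stochastic
coefficient draw ((i−1)B + b − 1) mod n_draws + 1 and added elementwise —
the replicate identity lifetime = within + post holds exactly per row.

Point estimates are across-imputation means (within) plus the draw-0
simulation (post). Percentile intervals use linear (type-7) interpolation.
ICER = ΔCost/ΔQALY with CE-plane quadrant labels; ratios are never averaged
over replicates, and the percentile CI on the ICER itself is reported only
when every replicate lies in the north-east quadrant (otherwise the ratio
does not order monotonically and uncertainty is summarised by the plane and
CEAC). CEAC(λ) = fraction of replicates with λ·ΔQALY − ΔCost > 0, on a
default grid 0–300,000 in steps of 1,000. The scenario grid re-runs the
downstream stages under config deltas: price discounts rescale the drug
price only; subgroup filters restrict the cohort (empty subgroups are
reported, not fatal); discontinuation and trajectory scenarios swap the
simulation config.

## Problem sizes and tolerances

Defaults match the base case (m = 28, B = 800, 800 draws); the demo
configuration and the reproduction script use scaled-down sizes chosen as a
sensible demonstration workload (n = 1,500–2,000 patients, m = 4–5,
B = 200, 80–100 draws, 40-year horizon). Closed-form checks are exact to
1e−9 (annuity), 1e−6 (AUC vs fine-grid integral); stochastic checks use
3 Monte-Carlo standard errors at 20,000–50,000 patients. Degenerate inputs
(empty series, empty arms, zero observed values for an imputed variable,
non-PSD covariance, unknown resource categories) raise informative errors;
mean-imputation and utility-flooring fallbacks are logged.

## Known limitations

- The microsimulation is a single-equation-per-outcome, first-event model:
  no second events, no treatment escalation, no hypoglycaemia or adverse
  events, no model-structure uncertainty.
- Post-trial standard errors reflect coefficient uncertainty only, not
  uncertainty in end-of-trial risk-factor values or in cost/utility inputs.
- No currency conversion or inflation adjustment between reference years;
  no value-of-information analysis; no societal perspective.
- The per-patient Python simulation loop favours auditability over speed:
  roughly 0.5 s per 1,000 patient-draws at a 40-year horizon on one CPU.
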