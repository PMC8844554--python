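# lifecea

Trial-based **lifetime cost-utility analysis** for two-arm studies in type 2
diabetes: from patient-level trial tables to incremental cost-effectiveness
ratios (ICERs), cost-effectiveness planes and acceptability curves (CEACs),
with the within-trial period extrapolated to death by an annual-cycle
microsimulation of diabetes complications.

The package is aimed at health economists and biostatisticians who want a
fully seeded, inspectable re-implementation of the standard within-trial +
extrapolation workflow used in economic evaluations alongside large
cardiovascular-outcome trials of glucose-lowering therapy — including the
machinery (multiple imputation, patient bootstrap, coefficient draws) needed
to propagate uncertainty correctly. Because individual patient data from such
trials are not public, the package ships a synthetic-cohort generator that
emulates their statistical structure with known ground truth, so every stage
can be tested by parameter recovery.

## The analysis in brief

For each patient the within-trial period contributes

- **QALYs** by the area-under-the-curve rule: EQ-5D profiles valued with a
  3L tariff (5L responses pass through a crosswalk), utility interpolated
  linearly between visits, carried flat to censoring, dropped to zero at
  death; arm contrast adjusted for baseline utility,
  `QALY ~ arm + (u0 − ū0)`;
- **costs** split into therapy costs (study drug at the net per-dose price +
  concomitant diabetes medication) and other costs (hospitalisations,
  visits, other medication), discounted annually (3% US / 3.5% UK).

Surviving patients then enter an annual-cycle microsimulation to death:
parametric annual hazards for eight complications (myocardial infarction,
stroke, heart failure, ischaemic heart disease, renal failure, amputation,
blindness, foot ulcer) and death — exponential, Weibull (on diabetes
duration), Gompertz (on age) or logistic forms,
`p = 1 − exp(−[H(t+1) − H(t)])` — with risk factors held constant at their
end-of-trial values, age/duration/event history updated every cycle, utility
decrements and complication costs applied, and study drug continued at the
last trial-year compliance until death or renal failure.

Uncertainty: per imputed dataset (m = 28 by default), 800 patient-level
bootstrap replicates of within-trial Δcost/ΔQALY are added to post-trial
differences under 800 multivariate-normal draws of the risk-equation
coefficients; ICER CIs are the 2.5th/97.5th percentiles of the pooled cloud,
and the CEAC is the fraction of replicates with positive net monetary benefit
`λ·ΔQALY − ΔCost` across thresholds λ.

Official EQ-5D tariffs and published risk-equation coefficients are licensed
artefacts and are **not** bundled: the defaults are clearly labelled
synthetic placeholders with the correct structure, and any coefficient file
following the documented CSV schemas can be supplied.

## Worked example

```bash
lifecea all --config examples/demo.yaml --out-dir demo-out
```

or equivalently in Python:

```python
import pathlib, yaml
from lifecea.pipeline import config_from_dict, run_all

cfg = config_from_dict(yaml.safe_load(pathlib.Path("examples/demo.yaml").read_text()))
result = run_all(cfg, out_dir="demo-out")
print(result.cea.summary().to_string(index=False))
```

On the packaged 2,000-patient demo configuration (m=5, 200 bootstrap
replicates, 100 coefficient draws, 40-year horizon, US costing) this prints

```
              quantity      estimate     ci_lower     ci_upper
      incremental_cost  73618.668382 54016.312174 87877.114401
     incremental_qalys      0.253190     0.068426     0.559106
incremental_life_years      0.350048          NaN          NaN
                  icer 290764.016699          NaN          NaN
```

Read: adding the weekly injectable to usual care in this synthetic cohort
gains 0.25 QALYs (95% percentile CI 0.07–0.56) at an extra lifetime cost of
$73,619 per patient, an ICER of ~$291k/QALY; the CEAC value at a
$100,000/QALY threshold is 0.007, i.e. the intervention is almost never
cost-effective at that willingness to pay under these synthetic prices. The
ICER CI is reported only when every replicate lies in the north-east
quadrant of the CE plane. `demo-out/` contains the lifetime summary table,
CE-plane points, CEAC curve and a manifest with all seeds and artifact
hashes; re-running with the same config reproduces the hashes exactly.

Scenario machinery (price discounts 20–80%, discontinuation scenarios,
subgroups such as age ≥ 65 or diabetes duration < 5 years):

```bash
lifecea scenarios --config examples/demo.yaml --out-dir demo-scenarios
```

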