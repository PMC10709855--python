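# bfgrowth

Growth standards for exclusively breastfed infants aged 0–6 months,
built from household-survey microdata: case selection, Box-Cox GAMLSS
curve fitting, model selection, centile tables and comparison with an
external reference chart.

## Who this is for

Constructing weight-for-age (W/A) and height-for-age (H/A) reference
centiles for young infants requires a sample that satisfies strict
WHO-style eligibility rules — exclusively breastfed, singleton, full
term, birth order ≤ 4, non-smoking mother, no severe illness, adequate
housing. National nutrition surveys such as UNICEF's Multiple Indicator
Cluster Survey (MICS) measure the anthropometry but do not publish
these eligibility indicators directly; they must be derived from the
raw feeding-recall, illness-recall and household-composition items.
`bfgrowth` implements that derivation chain, the distributional curve
fitting, and the validation machinery as a tested, reusable pipeline,
together with a synthetic-survey generator with known ground truth so
every stage can be verified without access to restricted survey files.

## The statistical core

Each measurement `y > 0` at age `t` is modeled with a Box-Cox family in
the GAMLSS framework. The Box-Cox z-score is

    z = ((y/μ)^ν − 1) / (ν σ)        (ν ≠ 0)
    z = log(y/μ) / σ                 (ν = 0)

and the three candidate families place a symmetric kernel on `z`:
**BCCG** (normal kernel — the LMS method), **BCPE** (power-exponential
kernel with kurtosis power τ; τ = 2 recovers BCCG), and **BCT**
(Student-t kernel with τ degrees of freedom). Densities carry the exact
normalizing constant for the truncation to `y > 0`. In chart notation
L = ν, M = μ, S = σ.

Each of μ, σ, ν is a smooth function of age — penalized B-spline
(`ps`), natural cubic smoothing spline (`cs`), or polynomial (`poly`)
— with effective degrees of freedom counted beyond the intercept
(df = 0 constant, df = 1 linear, df ≥ 2 a smooth of trace df + 1);
τ is a fitted constant. Fitting is penalized maximum likelihood via an
RS-type backfitting cycle with deviance-guarded steps. Model selection
mirrors the two-stage published procedure: a BIC search over the
L/M/S df grid (0–3 each, 64 fits, LMS family), then a 3 family ×
3 smoother AIC grid at the chosen df, in which polynomial smoothing
with any df = 0 is structurally not applicable (NA). Selected models
are validated with a week-stratified 70:30 split, scoring held-out
deviance and empirical centile coverage.

## Worked example

```python
import numpy as np
from bfgrowth import (
    default_truth, generate, select_children, drop_incomplete, flag_outliers,
    fit_gamlss, make_centile_table, RunConfig,
)

truth = default_truth()                      # anchored synthetic truth
survey = generate(11_478, truth, seed=1)     # MICS-like child table
selected, report = select_children(survey, RunConfig(seed=1))
print(report.n_selected)                     # 3592 of 11478 meet all criteria

weight = flag_outliers(drop_incomplete(selected, "weight"), "weight")[0]
boys = weight[weight.sex == "male"]
model = fit_gamlss(boys.age_days, boys.weight_kg,
                   family="BCPE", smoother="ps", df_spec=(0, 1, 0))
print(round(model.quantile(np.array([0.0]), 0.5)[0], 2))    # 3.23 (kg, birth median)
print(round(model.quantile(np.array([180.0]), 0.5)[0], 2))  # 6.94 (kg, 6-month median)
table = make_centile_table(model, measure="weight", sex="male")
```

The selection report logs how many records each criterion removes (and
confirms the final set is order-invariant); the fitted model carries
the four parameter curves, global deviance, AIC and BIC; the centile
table holds λ/μ/σ/τ and the requested percentiles per week of age.

The same pipeline is available from the shell:

```
bfgrowth --seed 1 simulate --n 11478 --out survey.csv
bfgrowth --seed 1 select   --in survey.csv --out selected.csv --report report.json
bfgrowth --seed 1 clean    --in selected.csv --measure weight --out weight.csv
bfgrowth --seed 1 grid     --in weight.csv --measure weight --sex male --out grid.csv
bfgrowth --seed 1 fit      --in weight.csv --measure weight --sex male --out model.yaml
bfgrowth --seed 1 charts   --model model.yaml --measure weight --sex male --out centiles.csv
```

## Layout

| module | role |
|---|---|
| `bfgrowth.distributions` | BCCG/BCPE/BCT densities, cdf/quantile, sampling, LMS centiles |
| `bfgrowth.smoothers` | ps/cs/poly bases, penalties, effective-df resolution |
| `bfgrowth.fitting` | RS-type GAMLSS fitting, BIC/AIC selection, cross-validation |
| `bfgrowth.selection` | EBF / severe-illness / congestion algorithms, inclusion chain |
| `bfgrowth.cleaning` | plausibility windows and provisional-fit outlier flagging |
| `bfgrowth.synthetic` | MICS-like survey generator with known ground truth |
| `bfgrowth.charts` | centile tables, reference interpolation and comparison, plots |
| `bfgrowth.io_config` | CSV/YAML I/O, survey variable mapping, run configuration |

See `docs/methods.md` for the modeling assumptions, parameter
conventions and known limitations.
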