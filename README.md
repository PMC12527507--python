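# esconvert

Automatic computation, conversion and reconciliation of meta-analytic
effect sizes.

## The problem

Meta-analysts extract whatever statistics primary studies happen to
report: group means with SDs, SEs or CIs; medians with quartiles or
ranges; *t*, *F*, *p* or η²; 2×2 tables, proportions, reported ORs/RRs/IRRs
with CIs; correlations; pre/post change scores; ANCOVA-adjusted means.
Turning this heterogeneous material into one effect size per study is
slow and error-prone, and when a study reports *several* overlapping
statistics for the same estimand, the analyst silently picks one — a
known source of inconsistency between meta-analyses.

`esconvert` addresses this with a registry-driven engine.  A single call
computes, for every row of a tidy dataset, **every** effect size the
row's input data allow (143 registered formulas over 22 input-data
combinations, producing 11 measures: *d*, *g*, MD, OR, RR, IRR, *r*,
Fisher's *z*, VR, CVR, NNT), selects one main estimate by an explicit
rule, and quantifies the agreement of the rest.  Around the engine sit a
template generator, a dependent-effect-size aggregator, and a cell-level
diff tool for double-extracted datasets.

## The core statistics

Standardized mean difference (pooled-SD form), with Hedges'
small-sample correction:

    S_p = sqrt(((n1-1) s1² + (n2-1) s2²) / (n1+n2-2))
    d   = (x̄1 - x̄2) / S_p,   Var(d) = (n1+n2)/(n1 n2) + d²/(2(n1+n2))
    g   = J·d,  J = 1 - 3/(4·df - 1),  df = n1+n2-2

Ratio measures are analysed on the log scale (lnOR with
SE = √(1/a+1/b+1/c+1/d), lnRR, lnIRR, lnVR, lnCVR), correlations on the
Fisher-*z* scale with Var(z) = 1/(n-3), and NNT through the absolute risk
difference.  Cross-measure conversions include the Hasselblad–Hedges
logistic link lnOR = πd/√3, six OR→RR approaches (Zhang–Yu
RR = OR/(1-p₀+p₀·OR) by default), Furukawa's d→NNT, and the
Wan/Luo order-statistic estimators recovering means and SDs from
medians, quartiles and ranges.  Every estimate carries a 95% CI built as
value ± 1.96·SE on its transform scale.

When two or more routes overlap, five consistency indicators are
reported on the comparison scale (smallest, largest, their difference,
the SD of all candidates, and the % overlap of the extreme candidates'
CIs), and rows are flagged for sign flips (forgotten direction
reversals) and large divergences (extraction typos).

Dependent effect sizes are collapsed per cluster with the Borenstein
composite (`outcomes`/`times` modes, user-supplied correlation *r*) or
fixed-effect inverse-variance pooling (`subgroups` mode).

## Worked example

```python
import pandas as pd
import esconvert as ec

data = pd.DataFrame([
    {"study_id": "Avery 2019", "n1": 50, "n2": 50, "m1": 103.0, "m2": 100.0,
     "sd1": 10.0, "sd2": 10.0, "t_value": 1.5, "es_direction": "positive"},
    {"study_id": "Baron 2021", "a": 20, "b": 80, "c": 10, "d_cell": 90},
    {"study_id": "Cole 2020", "r_value": 0.5, "n_r": 103},
])
out = ec.convert_df(data, "G")   # Hedges' g from whatever each row offers
print(out[["study_id", "route_used", "routes_available", "es_value",
           "es_se", "es_ci_lo", "es_ci_up", "es_diff",
           "ci_overlap_pct"]].round(4).to_string(index=False))
```

```
  study_id route_used routes_available  es_value  es_se  es_ci_lo  es_ci_up  es_diff  ci_overlap_pct
Avery 2019   means_sd       means_sd;t    0.2977 0.1996   -0.0935    0.6889      0.0           100.0
Baron 2021        2x2              2x2    0.4454 0.2288   -0.0032    0.8939      NaN             NaN
 Cole 2020        r_n              r_n    1.1461 0.2270    0.7013    1.5910      NaN             NaN
```

Avery 2019 reports both raw moments and a *t* statistic: both routes are
computed (`routes_available`), they agree exactly (`es_diff` 0, CI
overlap 100%), and the pre-defined hierarchy picks the raw-moments route
as the main estimate (g = 0.2977).  Baron 2021's 2×2 table is converted
through the logistic lnOR→d link; Cole 2020's correlation through the
algebraic r→d conversion.  The selection rule is explicit: pass
`es_selected="hierarchy"` with your own route ranking, or
`"smallest"`/`"largest"` for sensitivity analyses.

The same workflow is available from a shell:

```bash
esconvert template --measures G,OR --out sheet.csv
esconvert convert --in data.csv --measure G --es-selected auto --out results.csv
esconvert aggregate --in results.csv --dependence outcomes --r 0.6 --out agg.csv
esconvert compare --a rater1.csv --b rater2.csv --key study_id --out diff.html
```

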