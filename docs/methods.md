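# Methods

This note documents the statistical content of `esconvert`: the formulas
behind each module, the conventions chosen where several are defensible,
what the synthetic-data generator does and does not emulate, and the
package's known limitations.

## Input schema

A dataset is tidy and rectangular: one row per effect size, columns from
a fixed snake_case dictionary of 67 recognized statistics (group sizes,
moments, precision statistics, quantiles, test statistics, 2×2 cells,
proportions, reported ratios with CIs, person-time rates, correlations,
pre/post and ANCOVA summaries, and a control-group baseline risk).  A
small alias map (`d`→`d_cell`, `mean1`→`m1`, ...) is applied at read
time.  Blank cells and NA tokens are missing; `0` is always a value.
The 2×2 orientation is fixed: rows are groups (group 1 =
exposed/treated), columns event/non-event, and `es_direction =
positive` means group 1 is favoured.  p-values are two-tailed; one-tailed
values must be doubled before entry.  Validation returns violations as
data (row and column named) rather than failing on first error.

## Effect size formulas

**SMD family.**  d = (m1−m2)/S_p with the pooled SD and
Var(d) = (n1+n2)/(n1·n2) + d²/(2(n1+n2)).  Hedges' g = J·d with the
rational approximation J = 1 − 3/(4df − 1) (within 1e−4 of the exact
gamma ratio for df ≥ 10); the exact gamma form was deliberately not used
so that J is cheap, monotone and matches common practice.  Group SDs are
reconstructed from SEs (sd = se·√n) or 95% CIs (se = width/3.92).  From
test statistics: d = t·√(1/n1+1/n2); t = √F for two groups; t is the
two-tailed Student-t quantile of a reported p; d = 2√(η²/(1−η²)).  F, p
and η² carry no sign, so an explicit direction is required — a silent
positive would be exactly the extraction error the consistency flags
exist to catch.  The η² and F conversions assume a two-group one-way
design.

**Quantile routes.**  Means use the optimized weights of Luo et
al. (2018); SDs the order-statistic estimators of Wan et al. (2014):
range/(2·Φ⁻¹((n−0.375)/(n+0.25))), IQR/(2·Φ⁻¹((0.75n−0.125)/(n+0.25))),
and their average for the combined scenario.  These assume approximate
normality; the resulting estimates carry a "median-based normal
approximation" note and rank below every other route in the shipped
hierarchies.

**Change scores and ANCOVA.**  The per-group change SD is
√(sd_pre²+sd_post²−2r·sd_pre·sd_post); the pre-post correlation must be
supplied (no default — r is rarely reported and silently assuming 0.5
would be invisible).  A numerically zero change variance (r→1 with equal
SDs) is a degenerate-input error.  The ANCOVA route divides the adjusted
mean difference by a *user-supplied* unadjusted-scale pooled SD rather
than back-computing it from the model error SD and R²; this trades
convenience for one fewer silent assumption.  Both routes use the
standard d variance above; their d² term therefore uses the same df
convention as the raw-moments route.

**Binary family.**  lnOR = ln(ad/bc) with SE = √(Σ1/cell); lnRR with
SE = √(1/a−1/n1+1/c−1/n2); lnIRR = ln of the rate ratio with
SE = √(1/e1+1/e2).  Zero cells: 0.5 is added to all four cells if and
only if at least one cell is zero (Gart correction); for rates only the
zero count is replaced by 0.5.  Reported ratios with CIs use
SE = log-width/3.92 and require the CI to contain the point estimate.
Person-time units are the user's responsibility and must match between
groups (unvalidatable).

**Cross-measure conversions.**  d↔lnOR uses the Hasselblad–Hedges
logistic constant π/√3 (Cox's 1.65 is selectable); the conversion is an
exact algebraic bijection.  Six OR→RR approaches are registered:
rare-disease identity, Zhang–Yu with the row's control risk, Zhang–Yu
with a dataset-median risk, 2×2 reconstruction from OR + margins, a
probit chain through d, and the √OR approximation; SEs propagate by the
delta method on the log scale.  r = d/√(d²+a) with a = (n1+n2)²/(n1n2)
(a = 4 when sizes are unknown); the inverse uses
Var(r) = (1−r²)²/(n−1).  OR→r offers the two logistic chains plus the
tetrachoric approximation cos(π/(1+√OR)).  NNT comes from the absolute
risk difference (1/ARD), from Furukawa's Φ(d+Φ⁻¹(CER))−CER, or from a
reported OR/RR with a baseline risk; it is reported unrounded (round up
for clinical use) to preserve invertibility.

**Dispersion family.**  lnVR and lnCVR with the 1/(2(n−1)) bias
corrections; the CVR variance omits the mean–SD correlation term because
the schema carries no within-study raw data to estimate it — a
documented approximation that slightly overstates the variance when mean
and SD are positively correlated.

## Scales and intervals

Each measure has one transform scale on which its SE lives and its Wald
interval is formed with the fixed multiplier 1.96 (uniform across
measures; no t-quantiles): identity for d/g/MD/z, log for
OR/RR/IRR/VR/CVR, Fisher-z for r (CI back-transformed through tanh; no
natural-scale variance is ever reported), and the risk difference for
NNT (when the ARD interval spans zero the NNT CI is undefined and noted,
not fabricated).  A second *comparison* scale — identical except that
NNT maps to its reciprocal — is used wherever candidates must be
compared, so that the null is always 0 and differences are additive.

## Route registry and selection

Every (measure, input-route) pair is a registered formula: 143 formulas
over 22 distinct input combinations for the 11 measures.  Registry order
is the shipped pre-defined hierarchy and always ranks raw inputs over
reported estimates over test statistics over approximations/conversions;
the same ordering ships as editable text files (`data/hierarchies/`),
which the `auto` strategy reads at run time.  Selection offers three
approaches: a custom hierarchy, the pre-defined one, or the
smallest/largest candidate.  "Smallest/largest" compares the *absolute*
deviation from the null on the comparison scale — a plain min/max would
make the sensitivity analysis meaningless for negative effects.  Ties
break by registry order, so selection is a pure, deterministic function
of (candidates, strategy, hierarchy).  Per-route failures (domain
errors, missing direction) become per-row notes, never row failures.

## Consistency indicators

With ≥ 2 candidates: smallest, largest, their difference, the sample SD
(n−1 denominator) of all candidate values, and the % overlap of the 95%
CIs of the smallest and largest candidates — all on the comparison
scale, with a column naming that scale.  Overlap divides the
intersection length by the *shorter* interval's width, so it is bounded
in [0, 100] and containment reads as 100%; a union (Jaccard) denominator
is available as an option.  Flags: `sign_flip` when two candidates have
opposite signs and |x+y| ≤ 0.01(|x|+|y|); `large_divergence` when
overlap < 25% or, optionally, when the difference exceeds a
user-configured threshold.  These defaults are heuristics for catching
extraction errors, not calibrated tests.

## Aggregation

`outcomes` and `times` share the Borenstein composite — mean of the
estimates with Var = (ΣV + r·Σ_{i≠j}√(V_iV_j))/m² — differing only in
what the required correlation r means (inter-outcome vs across-time).
`subgroups` uses fixed-effect inverse-variance pooling.  All arithmetic
happens on the transform scale.  For equal-variance inputs the composite
variance is exactly V/m at r = 0 and V at r = 1.  This is aggregation
only, not multilevel modelling: between-estimate heterogeneity within a
cluster is averaged away, not modelled.

## Dataset comparison

Rows are realigned on a user-chosen key tuple (duplicates fatal),
compared cell-by-cell on the column intersection; numeric cells are
parsed first ("2.0" equals "2") with an optional absolute tolerance
(default 0 — extraction values should match exactly), text cells trimmed.
Only differences are reported, plus rows present in one dataset only.
Writers: csv, txt, xlsx, and a minimal HTML rendering with grey context
and highlighted discrepant cells.

## Synthetic-data generator

Rows cycle through six input families (continuous with full test
statistics, pre/post + ANCOVA, quantile summaries, binary, person-time
rates, correlations), so six rows cover every registered route.  All
overlapping inputs within a row are derived from the same generating
parameters — t from the simulated moments, OR and CI from the simulated
2×2, quantiles at the estimators' own plotting positions — so candidate
estimates agree exactly up to formula approximation error (the η² route
differs by a factor √(n/(n−1)); the quantile estimators are exact at the
plotting positions by construction).  Defaults: standardized difference
0.4, OR 2.0, IRR 1.5, group sizes 30–80 (continuous, equal per arm) and
150–250 (binary), control risks 0.15–0.30 — magnitudes typical of
clinical and psychological intervention literatures.  The corruption
option injects forgotten direction reversals (negated t, swapped
adjusted means) and multiplicative OR typos into rows whose family
yields ≥ 2 SMD routes, with bookkeeping of the affected ids.

What the generator does **not** emulate: between-study heterogeneity,
within-row sampling noise (inputs are mutually consistent by
construction, unlike real studies where e.g. a reported t and the
reported means disagree through rounding), non-normal outcomes, rounding
of published statistics, and missingness patterns.  Passing pipeline
tests therefore demonstrate the engine's correctness and determinism,
not robustness to messy real-world reporting.

## Problem sizes and numerical choices

The Monte-Carlo calibrations use 10,000 replicates for the d and lnOR
variance checks (tolerance 5%) and 2,000 replicates of n = 1001 for the
quantile SD estimator (3%) — sizes at which the Monte-Carlo error is
several times smaller than the tolerance.  The pipeline checks use
fixtures of 30–60 rows.  Degenerate inputs raise typed errors
(`UndefinedEffectError` for mathematically undefined effects,
`InputError` for domain violations); the engine converts these to
per-row notes.  All computation is deterministic: identical inputs give
bit-identical output tables.

## Known limitations

- No Peto OR, Glass's Δ, cluster-adjusted SMDs, repeated-measures d
  beyond the change-score route, partial correlations, or single-group
  dispersion measures.
- No meta-analytic pooling, heterogeneity statistics or plots — the
  output table is the input to downstream tools.
- The d² term of Var(d) uses the same large-sample form on every SMD
  route, including change-score and ANCOVA inputs.
- The CVR variance omits the mean–SD correlation term (see above).
- Consistency thresholds (1% sign tolerance, 25% overlap) are heuristics.
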