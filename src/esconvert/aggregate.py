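"""Aggregation of dependent effect sizes into one independent estimate.

Three dependence modes are registered.  ``outcomes`` and ``times`` share
the Borenstein composite for estimates measured on the *same*
participants (several outcome measures, or the same outcome at several
time points), parameterized by a user-supplied within-study correlation
r_dep:

    y_bar = (1/m) sum(y_i)
    Var   = (1/m^2) [ sum(V_i) + sum_{i != j} r sqrt(V_i V_j) ]

``subgroups`` combines estimates from *different* participants by
fixed-effect inverse-variance pooling:

    y_bar = sum(W_i y_i) / sum(W_i),  Var = 1 / sum(W_i),  W_i = 1/V_i.

All arithmetic happens on the transform scale (log for ratio measures),
and r_dep is never defaulted — an invisible 0.5 would be an assumption
the user did not make.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .estimate import EffectEstimate, InputError

log = logging.getLogger("esconvert")

#: The three registered dependence modes.
DEPENDENCE_MODES = ("outcomes", "times", "subgroups")


@dataclass(frozen=True)
class AggregationSpec:
    """How to collapse a cluster of dependent effect sizes.

    r_dep is the within-study correlation among the dependent estimates
    (inter-outcome correlation for 'outcomes', autocorrelation across
    time points for 'times'); it is required for those two modes and
    ignored for 'subgroups'.
    """

    dependence: str
    r_dep: float | None = None
    cluster_key: str = "study_id"

    def __post_init__(self):
        if self.dependence not in DEPENDENCE_MODES:
            raise InputError(
                f"dependence must be one of {DEPENDENCE_MODES}"
            )
        if self.dependence in ("outcomes", "times"):
            if self.r_dep is None:
                raise InputError(
                    f"dependence={self.dependence!r} requires r_dep "
                    "(no silent default)"
                )
            if not 0 <= self.r_dep <= 1:
                raise InputError("r_dep must lie in [0, 1]")


def aggregate_cluster(estimates, spec: AggregationSpec) -> EffectEstimate:
    """Collapse one cluster of same-measure estimates into one.

    Singleton clusters pass through unchanged (with the aggregation route
    tag).  Ratio measures are aggregated on the log scale and
    back-transformed.
    """
    ests = list(estimates)
    if not ests:
        raise InputError("empty cluster")
    measures = {e.measure for e in ests}
    scales = {e.scale for e in ests}
    if len(measures) > 1 or len(scales) > 1:
        raise InputError(
            f"cannot aggregate mixed measures/scales: {sorted(measures)}"
        )
    route = f"aggregated_{spec.dependence}"
    if len(ests) == 1:
        e = ests[0]
        return EffectEstimate.from_transform(
            e.measure, e.transform_value, e.se, route,
            df_like=e.df_like, note=e.note,
        )
    ys = [e.transform_value for e in ests]
    vs = [e.se**2 for e in ests]
    m = len(ests)
    if spec.dependence in ("outcomes", "times"):
        r = spec.r_dep
        cross = sum(
            math.sqrt(vs[i] * vs[j])
            for i in range(m) for j in range(m) if i != j
        )
        value = sum(ys) / m
        var = (sum(vs) + r * cross) / m**2
    else:
        ws = [1 / v for v in vs]
        value = sum(w * y for w, y in zip(ws, ys)) / sum(ws)
        var = 1 / sum(ws)
    return EffectEstimate.from_transform(
        ests[0].measure, value, math.sqrt(var), route
    )


def aggregate_df(
    frame: pd.DataFrame,
    spec: AggregationSpec,
    value_col: str = "es_value",
    se_col: str = "es_se",
    measure_col: str = "measure",
) -> pd.DataFrame:
    """One output row per cluster, in first-appearance order.

    The frame must carry ``value_col``, ``se_col`` and the cluster key;
    a measure column (default ``measure``) determines each estimate's
    transform scale.  Non-effect columns are kept when constant within a
    cluster, otherwise blanked with a warning.
    """
    key = spec.cluster_key
    if key not in frame.columns:
        raise InputError(f"cluster key column {key!r} not in table")
    for col in (value_col, se_col, measure_col):
        if col not in frame.columns:
            raise InputError(f"required column {col!r} not in table")
    usable = frame[value_col].notna() & frame[se_col].notna()
    if not usable.all():
        log.warning(
            "dropping %d row(s) without an estimate before aggregation",
            int((~usable).sum()),
        )
        frame = frame[usable]
    effect_cols = {value_col, se_col, "es_ci_lo", "es_ci_up"}
    other_cols = [c for c in frame.columns
                  if c not in effect_cols and c != key]
    records = []
    blanked: set[str] = set()
    for cluster, sub in frame.groupby(key, sort=False):
        ests = []
        for _, rec in sub.iterrows():
            measure = rec[measure_col]
            ests.append(
                EffectEstimate.from_transform(
                    measure,
                    _to_transform(measure, float(rec[value_col])),
                    float(rec[se_col]),
                    "input",
                )
            )
        agg = aggregate_cluster(ests, spec)
        out = {
            key: cluster,
            "n_aggregated": len(ests),
            "dependence": spec.dependence,
            value_col: agg.value,
            se_col: agg.se,
            "es_ci_lo": agg.ci_lo,
            "es_ci_up": agg.ci_up,
        }
        for col in other_cols:
            vals = sub[col].to_list()
            if all(_same(v, vals[0]) for v in vals):
                out[col] = vals[0]
            else:
                out[col] = math.nan
                blanked.add(col)
        records.append(out)
    if blanked:
        log.warning(
            "column(s) not constant within cluster, blanked: %s",
            ", ".join(sorted(blanked)),
        )
    columns = [key, "n_aggregated", "dependence", value_col, se_col,
               "es_ci_lo", "es_ci_up"] + other_cols
    return pd.DataFrame.from_records(records, columns=columns)


def _to_transform(measure: str, value: float) -> float:
    """Natural-scale value -> transform-scale value for a measure code."""
    from .estimate import LOG_MEASURES

    if measure in LOG_MEASURES:
        return math.log(value)
    if measure == "R":
        return math.atanh(value)
    if measure == "NNT":
        return 1 / value
    return value


def _same(x, y) -> bool:
    if isinstance(x, float) and isinstance(y, float):
        return (math.isnan(x) and math.isnan(y)) or x == y
    return x == y
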