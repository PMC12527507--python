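"""Synthetic dataset generator with controlled overlapping inputs.

Each generated row carries several input routes that are *mutually
consistent by construction*: test statistics are computed from the same
simulated group moments, reported ratios and CIs from the same 2x2 table,
quantiles placed at the expected normal order-statistic positions (so the
median/quartile/range estimators recover the generating moments exactly).
Candidate estimates for one row therefore agree up to formula
approximation error, which is what makes the generator useful for
exercising the consistency indicators.

The simulation model is deliberately simple: two-group normal outcomes
(common SD, difference set by ``true_smd``), binomial events (control
risk drawn per study, odds scaled by ``true_or``), Poisson-type event
rates (ratio ``true_irr``), and plain correlations.  No between-study
heterogeneity is modelled.

A corruption option injects the two classic extraction errors — a
forgotten direction reversal (sign-flipped t or swapped adjusted means)
and a multiplicative typo in a reported OR — and records which rows were
touched.  Corruption only targets rows whose input family yields at
least two SMD routes, so every injected error is detectable from the
consistency flags of ``convert_df(..., measure="D")``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import InputError
from .schema import COLUMN_NAMES

BUNDLES = (
    "continuous",
    "continuous_pre_post",
    "continuous_quantiles",
    "binary",
    "rates",
    "correlation",
)

_CORRUPTIBLE = ("continuous", "continuous_pre_post", "binary")


@dataclass(frozen=True)
class FixtureResult:
    """A generated dataset plus generator bookkeeping."""

    frame: pd.DataFrame
    bundles: tuple[str, ...]            # input family of each row
    corrupted_ids: tuple[str, ...]      # study_ids with an injected error
    corruption_kinds: dict              # study_id -> 'sign_flip' | 'typo'


def _continuous_core(rng, true_smd):
    n = int(rng.integers(30, 81))
    sd = float(rng.uniform(5, 15))
    m2 = float(rng.uniform(20, 60))
    m1 = m2 + true_smd * sd
    return n, sd, m1, m2


def _row_continuous(rng, true_smd):
    n, sd, m1, m2 = _continuous_core(rng, true_smd)
    df = 2 * n - 2
    se = sd / math.sqrt(n)
    t = (m1 - m2) / (sd * math.sqrt(2 / n))
    md_se = sd * math.sqrt(2 / n)
    return {
        "es_direction": "positive" if m1 >= m2 else "negative",
        "n1": n, "n2": n, "m1": m1, "m2": m2, "sd1": sd, "sd2": sd,
        "se1": se, "se2": se,
        "m1_ci_lo": m1 - 1.96 * se, "m1_ci_up": m1 + 1.96 * se,
        "m2_ci_lo": m2 - 1.96 * se, "m2_ci_up": m2 + 1.96 * se,
        "t_value": t, "f_value": t * t,
        "p_value": float(2 * stats.t.sf(abs(t), df)) if t != 0 else 1.0,
        "eta_sq": t * t / (t * t + df),
        "md_value": m1 - m2, "md_se": md_se,
        "md_ci_lo": (m1 - m2) - 1.96 * md_se,
        "md_ci_up": (m1 - m2) + 1.96 * md_se,
    }


def _row_pre_post(rng, true_smd):
    n, sd, m1, m2 = _continuous_core(rng, true_smd)
    # equal pre/post SDs with r = 0.5 make the change-score SD equal the
    # post SD, so all three SMD routes agree exactly
    return {
        "es_direction": "positive" if m1 >= m2 else "negative",
        "n1": n, "n2": n, "m1": m1, "m2": m2, "sd1": sd, "sd2": sd,
        "pre_m1": m2, "pre_m2": m2, "pre_sd1": sd, "pre_sd2": sd,
        "r_prepost": 0.5,
        "adj_m1": m1, "adj_m2": m2, "adj_sd_pooled": sd,
    }


def _row_quantiles(rng, true_smd):
    n, sd, m1, m2 = _continuous_core(rng, true_smd)
    z_range = float(stats.norm.ppf((n - 0.375) / (n + 0.25)))
    z_iqr = float(stats.norm.ppf((0.75 * n - 0.125) / (n + 0.25)))
    row = {
        "es_direction": "positive" if m1 >= m2 else "negative",
        "n1": n, "n2": n, "m1": m1, "m2": m2, "sd1": sd, "sd2": sd,
    }
    for i, m in ((1, m1), (2, m2)):
        row[f"med{i}"] = m
        row[f"q1_{i}"] = m - z_iqr * sd
        row[f"q3_{i}"] = m + z_iqr * sd
        row[f"min{i}"] = m - z_range * sd
        row[f"max{i}"] = m + z_range * sd
    return row


def _row_binary(rng, true_or):
    n1 = int(rng.integers(150, 251))
    n2 = int(rng.integers(150, 251))
    p2 = float(rng.uniform(0.15, 0.30))
    odds1 = true_or * p2 / (1 - p2)
    p1 = odds1 / (1 + odds1)
    a = min(max(int(round(p1 * n1)), 1), n1 - 1)
    c = min(max(int(round(p2 * n2)), 1), n2 - 1)
    b, d_cell = n1 - a, n2 - c
    lnor = math.log(a * d_cell / (b * c))
    se_or = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d_cell)
    lnrr = math.log((a / n1) / (c / n2))
    se_rr = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
    return {
        "n1": n1, "n2": n2, "a": a, "b": b, "c": c, "d_cell": d_cell,
        "p_event1": a / n1, "p_event2": c / n2,
        "or_value": math.exp(lnor),
        "or_ci_lo": math.exp(lnor - 1.96 * se_or),
        "or_ci_up": math.exp(lnor + 1.96 * se_or),
        "logor_value": lnor, "logor_se": se_or,
        "rr_value": math.exp(lnrr),
        "rr_ci_lo": math.exp(lnrr - 1.96 * se_rr),
        "rr_ci_up": math.exp(lnrr + 1.96 * se_rr),
        "baseline_risk": c / n2,
    }


def _row_rates(rng, true_irr):
    time1 = float(rng.uniform(80, 120))
    time2 = float(rng.uniform(80, 120))
    e2 = int(rng.integers(20, 61))
    e1 = max(int(round(true_irr * (e2 / time2) * time1)), 1)
    lnirr = math.log((e1 / time1) / (e2 / time2))
    se = math.sqrt(1 / e1 + 1 / e2)
    return {
        "e1": e1, "time1": time1, "e2": e2, "time2": time2,
        "irr_value": math.exp(lnirr),
        "irr_ci_lo": math.exp(lnirr - 1.96 * se),
        "irr_ci_up": math.exp(lnirr + 1.96 * se),
    }


def _row_correlation(rng):
    return {
        "r_value": float(rng.uniform(0.2, 0.5)),
        "n_r": int(rng.integers(50, 201)),
    }


def generate_fixture(
    n_studies: int = 50,
    seed: int = 0,
    true_smd: float = 0.4,
    true_or: float = 2.0,
    true_irr: float = 1.5,
    corruption_rate: float = 0.0,
) -> FixtureResult:
    """Generate a schema-valid dataset of ``n_studies`` rows.

    Rows cycle through the six input families in :data:`BUNDLES`, so any
    fixture with at least six rows covers every registered input route.
    With ``corruption_rate`` > 0, that fraction of the corruptible rows
    receives one injected extraction error each (see module docstring).
    """
    if n_studies < 1:
        raise InputError("n_studies must be >= 1")
    if not 0 <= corruption_rate <= 1:
        raise InputError("corruption_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records, bundles = [], []
    for i in range(n_studies):
        bundle = BUNDLES[i % len(BUNDLES)]
        if bundle == "continuous":
            row = _row_continuous(rng, true_smd)
        elif bundle == "continuous_pre_post":
            row = _row_pre_post(rng, true_smd)
        elif bundle == "continuous_quantiles":
            row = _row_quantiles(rng, true_smd)
        elif bundle == "binary":
            row = _row_binary(rng, true_or)
        elif bundle == "rates":
            row = _row_rates(rng, true_irr)
        else:
            row = _row_correlation(rng)
        row["study_id"] = f"study_{i + 1:04d}"
        records.append(row)
        bundles.append(bundle)

    corrupted, kinds = [], {}
    eligible = [i for i, b in enumerate(bundles) if b in _CORRUPTIBLE]
    n_corrupt = int(round(corruption_rate * len(eligible)))
    if n_corrupt:
        targets = rng.choice(len(eligible), size=n_corrupt, replace=False)
        for j in sorted(int(t) for t in targets):
            i = eligible[j]
            row, bundle = records[i], bundles[i]
            if bundle == "continuous":
                row["t_value"] = -row["t_value"]  # forgotten reversal
                kinds[row["study_id"]] = "sign_flip"
            elif bundle == "continuous_pre_post":
                row["adj_m1"], row["adj_m2"] = row["adj_m2"], row["adj_m1"]
                kinds[row["study_id"]] = "sign_flip"
            else:  # binary: multiplicative typo in the reported OR
                for col in ("or_value", "or_ci_lo", "or_ci_up"):
                    row[col] *= 4.0
                row["logor_value"] += math.log(4.0)
                kinds[row["study_id"]] = "typo"
            corrupted.append(row["study_id"])

    frame = pd.DataFrame.from_records(records)
    frame = frame.reindex(
        columns=[c for c in COLUMN_NAMES if c in frame.columns]
    )
    return FixtureResult(
        frame=frame,
        bundles=tuple(bundles),
        corrupted_ids=tuple(corrupted),
        corruption_kinds=kinds,
    )
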