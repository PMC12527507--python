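"""Consistency indicators for overlapping input data.

When one row yields two or more candidate estimates of the same measure,
five indicators quantify their agreement, all computed on the measure's
comparison scale (additive for D/G/MD/Z, log for ratio measures, atanh(r)
for R, absolute risk difference for NNT):

    es_min          smallest candidate
    es_max          largest candidate
    es_diff         es_max - es_min
    es_sd           sample SD (n-1 denominator) of the candidate values
    ci_overlap_pct  percentage overlap of the 95% CIs of the smallest and
                    largest candidates

The overlap denominator is the *shorter* interval's width, so overlap is
bounded in [0, 100] and containment reads as 100%; a union denominator is
available for sensitivity.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

#: The five registered consistency indicators.
INDICATORS = ("es_min", "es_max", "es_diff", "es_sd", "ci_overlap_pct")

FLAG_SIGN_FLIP = "sign_flip"
FLAG_LARGE_DIVERGENCE = "large_divergence"


@dataclass(frozen=True)
class ConsistencyReport:
    es_min: float
    es_max: float
    es_diff: float
    es_sd: float
    ci_overlap_pct: float
    scale: str  # comparison scale the indicators live on


def ci_overlap(
    interval_1: tuple[float, float],
    interval_2: tuple[float, float],
    denominator: str = "shorter",
) -> float:
    """Percentage overlap of two intervals (symmetric in its arguments).

    ``denominator='shorter'`` divides the intersection length by the
    shorter width (containment = 100); ``'union'`` divides by the union
    length (Jaccard-style).
    """
    lo1, up1 = sorted(interval_1)
    lo2, up2 = sorted(interval_2)
    if any(math.isnan(x) for x in (lo1, up1, lo2, up2)):
        return math.nan
    inter = max(0.0, min(up1, up2) - max(lo1, lo2))
    if denominator == "shorter":
        denom = min(up1 - lo1, up2 - lo2)
    elif denominator == "union":
        denom = max(up1, up2) - min(lo1, lo2)
    else:
        raise ValueError("denominator must be 'shorter' or 'union'")
    if denom <= 0:
        return 100.0 if inter >= 0 and up1 == up2 and lo1 == lo2 else 0.0
    return 100.0 * inter / denom


def consistency_indicators(cs, denominator: str = "shorter"):
    """The five indicators for a CandidateSet; None with < 2 candidates."""
    cands = list(cs.candidates)
    if len(cands) < 2:
        return None
    values = [c.comparison_value for c in cands]
    smallest = min(cands, key=lambda c: c.comparison_value)
    largest = max(cands, key=lambda c: c.comparison_value)
    overlap = ci_overlap(
        smallest.comparison_interval, largest.comparison_interval,
        denominator=denominator,
    )
    from .engine import comparison_scale_name  # local: avoid import cycle

    return ConsistencyReport(
        es_min=min(values),
        es_max=max(values),
        es_diff=max(values) - min(values),
        es_sd=statistics.stdev(values),
        ci_overlap_pct=overlap,
        scale=comparison_scale_name(cs.measure),
    )


def flag_discrepancies(
    cs,
    report: ConsistencyReport,
    sign_tol: float = 0.01,
    overlap_threshold: float = 25.0,
    diff_threshold: float | None = None,
) -> tuple[str, ...]:
    """Discrepancy flags for a candidate set with a consistency report.

    sign_flip: two candidates of (nearly) equal magnitude but opposite
    sign — the classic forgotten-direction-reversal extraction error.
    large_divergence: CI overlap below ``overlap_threshold`` percent, or
    es_diff above ``diff_threshold`` when one is configured.
    """
    if report is None:
        return ()
    flags: list[str] = []
    values = [c.comparison_value for c in cs.candidates]
    for i, x in enumerate(values):
        for y in values[i + 1:]:
            if x * y < 0 and abs(x + y) <= sign_tol * (abs(x) + abs(y)):
                flags.append(FLAG_SIGN_FLIP)
                break
        if flags:
            break
    diverged = (
        not math.isnan(report.ci_overlap_pct)
        and report.ci_overlap_pct < overlap_threshold
    )
    if diff_threshold is not None and report.es_diff > diff_threshold:
        diverged = True
    if diverged:
        flags.append(FLAG_LARGE_DIVERGENCE)
    return tuple(flags)
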