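"""Standardized-mean-difference family: Cohen's d, Hedges' g, MD.

All routes reduce to two primitives: the pooled-SD d,

    Sp = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2))
    d  = (m1 - m2) / Sp
    Var(d) = (n1 + n2) / (n1 n2) + d^2 / (2 (n1 + n2))

and the reconstruction of group moments from whatever precision statistic
was reported (SE, CI, medians with quartiles/ranges).  Hedges' g applies
the small-sample correction J = 1 - 3/(4 df - 1) (rational approximation
to the exact gamma ratio; accurate to 4 decimals for df >= 10).

p-values are treated as two-tailed throughout; a one-tailed p must be
doubled by the user before entry.
"""

from __future__ import annotations

import math

from scipy import stats

from .estimate import (
    DirectionRequiredError,
    EffectEstimate,
    InputError,
    UndefinedEffectError,
)


def pooled_sd(sd1: float, sd2: float, n1: float, n2: float) -> float:
    if min(n1, n2) < 2:
        raise InputError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise InputError("SDs must be strictly positive")
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


def var_d(d: float, n1: float, n2: float) -> float:
    """Large-sample variance of Cohen's d for two independent groups."""
    return (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))


def _d_estimate(d: float, n1: float, n2: float, route: str,
                note: str | None = None) -> EffectEstimate:
    return EffectEstimate.from_transform(
        "D", d, math.sqrt(var_d(d, n1, n2)), route,
        df_like=n1 + n2 - 2, note=note,
    )


def d_from_means(m1, m2, sd1, sd2, n1, n2, route: str = "means_sd") -> EffectEstimate:
    """Cohen's d from raw group means and SDs."""
    sp = pooled_sd(sd1, sd2, n1, n2)
    if sp == 0:
        raise UndefinedEffectError("pooled SD is zero: d undefined")
    return _d_estimate((m1 - m2) / sp, n1, n2, route)


def moments_from_precision(mean, n, se=None, ci=None):
    """Recover (mean, sd) from a group mean with its SE or 95% CI.

    sd = se * sqrt(n); from a CI, se = (upper - lower) / (2 * 1.96).
    """
    if n < 2:
        raise InputError("n must be >= 2")
    if se is None:
        if ci is None:
            raise InputError("supply se or ci")
        lo, up = ci
        if not up > lo:
            raise InputError("CI must have positive width")
        se = (up - lo) / 3.92
    if se <= 0:
        raise InputError("SE must be strictly positive")
    return mean, se * math.sqrt(n)


_QUANTILE_SCENARIOS = ("range_only", "iqr_only", "both")


def moments_from_quantiles(
    n, med=None, q1=None, q3=None, minimum=None, maximum=None, scenario=None
):
    """Estimate (mean, sd) of a sample reported as median with quartiles
    and/or range, assuming approximate normality.

    SDs follow the order-statistic estimators of Wan et al. (2014); means
    follow the optimized weights of Luo et al. (2018).  ``scenario`` is
    inferred from the supplied fields when not given.
    """
    if n < 5:
        raise InputError("quantile estimators need n >= 5")
    if med is None:
        raise InputError("median is required")
    have_iqr = q1 is not None and q3 is not None
    have_range = minimum is not None and maximum is not None
    if scenario is None:
        scenario = (
            "both" if have_iqr and have_range
            else "iqr_only" if have_iqr
            else "range_only" if have_range
            else None
        )
    if scenario not in _QUANTILE_SCENARIOS:
        raise InputError("supply quartiles and/or a range")
    for lo, hi, what in (
        (minimum, q1, "min <= q1"), (q1, med, "q1 <= median"),
        (med, q3, "median <= q3"), (q3, maximum, "q3 <= max"),
        (minimum, med, "min <= median"), (med, maximum, "median <= max"),
    ):
        if lo is not None and hi is not None and lo > hi:
            raise InputError(f"quantile ordering violated: {what}")

    z_range = stats.norm.ppf((n - 0.375) / (n + 0.25))
    z_iqr = stats.norm.ppf((0.75 * n - 0.125) / (n + 0.25))
    if scenario == "range_only":
        w = 4 / (4 + n**0.75)
        mean = w * (minimum + maximum) / 2 + (1 - w) * med
        sd = (maximum - minimum) / (2 * z_range)
    elif scenario == "iqr_only":
        w = 0.7 + 0.39 / n
        mean = w * (q1 + q3) / 2 + (1 - w) * med
        sd = (q3 - q1) / (2 * z_iqr)
    else:
        w1 = 2.2 / (2.2 + n**0.75)
        w2 = 0.7 - 0.72 / n**0.55
        mean = (
            w1 * (minimum + maximum) / 2
            + w2 * (q1 + q3) / 2
            + (1 - w1 - w2) * med
        )
        sd = (maximum - minimum) / (4 * z_range) + (q3 - q1) / (4 * z_iqr)
    return mean, sd


_TEST_STATS = ("t", "F", "p", "eta2")


def d_from_test_stat(stat, value, n1, n2, es_direction="unspecified") -> EffectEstimate:
    """Cohen's d from a two-group test statistic.

    t carries its own sign; F, two-tailed p and eta^2 are signless and
    require an explicit ``es_direction`` of 'positive' or 'negative'.
    """
    if min(n1, n2) < 2:
        raise InputError("each group needs n >= 2")
    df = n1 + n2 - 2
    sign = 1.0
    if stat in ("F", "p", "eta2"):
        if es_direction == "positive":
            sign = 1.0
        elif es_direction == "negative":
            sign = -1.0
        else:
            raise DirectionRequiredError(
                f"{stat} carries no sign: set es_direction to "
                "'positive' or 'negative'"
            )
    if stat == "t":
        d = value * math.sqrt(1 / n1 + 1 / n2)
        route = "t"
    elif stat == "F":
        if value < 0:
            raise InputError("F must be non-negative")
        d = sign * math.sqrt(value) * math.sqrt(1 / n1 + 1 / n2)
        route = "f"
    elif stat == "p":
        if not 0 < value <= 1:
            raise InputError("p must lie in (0, 1]")
        t = stats.t.ppf(1 - value / 2, df)
        d = sign * t * math.sqrt(1 / n1 + 1 / n2)
        route = "p"
    elif stat == "eta2":
        if not 0 <= value < 1:
            raise InputError("eta^2 must lie in [0, 1)")
        d = sign * 2 * math.sqrt(value / (1 - value))
        route = "eta2"
    else:
        raise InputError(f"unknown statistic {stat!r}; valid: {_TEST_STATS}")
    return _d_estimate(d, n1, n2, route)


def change_score_sd(sd_pre, sd_post, r_prepost) -> float:
    """SD of within-subject change scores from pre/post SDs and their
    correlation: sqrt(sd_pre^2 + sd_post^2 - 2 r sd_pre sd_post)."""
    if r_prepost is None:
        raise InputError(
            "the pre-post correlation must be supplied explicitly "
            "(no silent default)"
        )
    if not -1 < r_prepost < 1:
        raise InputError("r_prepost must lie in (-1, 1)")
    var = sd_pre**2 + sd_post**2 - 2 * r_prepost * sd_pre * sd_post
    if var < 1e-12 * (sd_pre**2 + sd_post**2):  # numerically degenerate
        raise UndefinedEffectError(
            "change-score SD is (numerically) zero: near-perfectly "
            "correlated equal SDs"
        )
    return math.sqrt(var)


def d_from_change(
    m1, m2, sd1, sd2, pre_m1, pre_m2, pre_sd1, pre_sd2, r_prepost, n1, n2
) -> EffectEstimate:
    """Cohen's d on pre-to-post change scores."""
    cs1 = change_score_sd(pre_sd1, sd1, r_prepost)
    cs2 = change_score_sd(pre_sd2, sd2, r_prepost)
    return d_from_means(m1 - pre_m1, m2 - pre_m2, cs1, cs2, n1, n2,
                        route="change_scores")


def d_from_ancova(adj_m1, adj_m2, adj_sd_pooled, n1, n2) -> EffectEstimate:
    """Cohen's d from covariate-adjusted means and the unadjusted-scale
    pooled SD (which the user must supply)."""
    if adj_sd_pooled is None or adj_sd_pooled <= 0:
        raise InputError("adj_sd_pooled must be strictly positive")
    return _d_estimate((adj_m1 - adj_m2) / adj_sd_pooled, n1, n2,
                       "ancova_means")


def d_from_md(md, md_se, n1, n2, route: str = "md_se") -> EffectEstimate:
    """Cohen's d from a reported mean difference with its SE.

    The pooled SD is recovered as md_se / sqrt(1/n1 + 1/n2).
    """
    if md_se is None or md_se <= 0:
        raise InputError("md_se must be strictly positive")
    sp = md_se / math.sqrt(1 / n1 + 1 / n2)
    return _d_estimate(md / sp, n1, n2, route)


def j_factor(df: float) -> float:
    """Hedges' small-sample correction J = 1 - 3/(4 df - 1)."""
    if df < 2:
        raise InputError("J requires df >= 2")
    return 1 - 3 / (4 * df - 1)


def hedges_correction(est: EffectEstimate) -> EffectEstimate:
    """Convert a D estimate to Hedges' g: g = J d, Var(g) = J^2 Var(d)."""
    if est.measure != "D":
        raise InputError("hedges_correction expects a D estimate")
    if est.df_like is None:
        raise InputError("df_like is required for the g correction")
    j = j_factor(est.df_like)
    return EffectEstimate.from_transform(
        "G", j * est.value, j * est.se, est.route,
        df_like=est.df_like, method=est.method, note=est.note,
    )


def md_from_means(m1, m2, sd1, sd2, n1, n2, route: str = "means_sd") -> EffectEstimate:
    """Raw mean difference: MD = m1 - m2, Var = sd1^2/n1 + sd2^2/n2."""
    if sd1 <= 0 or sd2 <= 0:
        raise InputError("SDs must be strictly positive")
    if min(n1, n2) < 2:
        raise InputError("each group needs n >= 2")
    se = math.sqrt(sd1**2 / n1 + sd2**2 / n2)
    return EffectEstimate.from_transform("MD", m1 - m2, se, route,
                                         df_like=n1 + n2 - 2)


def md_from_reported(md, se=None, ci=None, route: str = "md_se") -> EffectEstimate:
    """Pass-through of a reported MD with its SE or 95% CI."""
    if se is None:
        if ci is None:
            raise InputError("supply se or ci")
        lo, up = ci
        if not up > lo:
            raise InputError("CI must have positive width")
        se = (up - lo) / 3.92
        route = "md_ci"
    if se <= 0:
        raise InputError("SE must be strictly positive")
    return EffectEstimate.from_transform("MD", md, se, route)
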