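"""Binary-outcome measures: OR, RR, IRR, NNT, and cross-measure conversions.

Zero cells in a 2x2 table are handled with the Gart correction: 0.5 is
added to all four cells if and only if at least one cell is zero.  All
ratio measures carry their SE on the log scale.
"""

from __future__ import annotations

import math

from scipy import stats

from .estimate import (
    EffectEstimate,
    InputError,
    UndefinedEffectError,
    Z95,
)

#: Hasselblad-Hedges logistic constant: lnOR = d * pi / sqrt(3).
HH = math.pi / math.sqrt(3.0)
#: Cox's alternative constant: lnOR = 1.65 * d.
COX = 1.65

D_TO_LNOR_METHODS = ("hasselblad_hedges", "cox")


def _corrected_cells(a, b, c, d_cell):
    cells = (a, b, c, d_cell)
    if any(x < 0 for x in cells):
        raise InputError("2x2 cells must be non-negative")
    if a + b <= 0 or c + d_cell <= 0:
        raise InputError("each 2x2 row margin must be positive")
    if any(x == 0 for x in cells):
        cells = tuple(x + 0.5 for x in cells)
    return cells


def logor_from_2x2(a, b, c, d_cell, route: str = "2x2") -> EffectEstimate:
    """OR from a 2x2 table: lnOR = ln(ad/bc), SE = sqrt(sum of 1/cells)."""
    a, b, c, d_cell = _corrected_cells(a, b, c, d_cell)
    if a * d_cell == 0 or b * c == 0:
        raise UndefinedEffectError("degenerate 2x2 table: OR undefined")
    lnor = math.log(a * d_cell / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d_cell)
    return EffectEstimate.from_transform("OR", lnor, se, route)


def logrr_from_2x2(a, b, c, d_cell, route: str = "2x2") -> EffectEstimate:
    """RR from a 2x2 table: lnRR = ln((a/n1)/(c/n2)),
    SE = sqrt(1/a - 1/n1 + 1/c - 1/n2)."""
    a, b, c, d_cell = _corrected_cells(a, b, c, d_cell)
    n1, n2 = a + b, c + d_cell
    if a == 0 or c == 0:
        raise UndefinedEffectError("zero risk after correction: RR undefined")
    lnrr = math.log((a / n1) / (c / n2))
    se2 = 1 / a - 1 / n1 + 1 / c - 1 / n2
    if se2 <= 0:
        raise UndefinedEffectError("non-positive lnRR variance")
    return EffectEstimate.from_transform("RR", lnrr, math.sqrt(se2), route)


def logirr_from_rates(e1, time1, e2, time2) -> EffectEstimate:
    """IRR from event counts and person-time:
    lnIRR = ln((e1/time1)/(e2/time2)), SE = sqrt(1/e1 + 1/e2).

    A 0.5 correction is applied to a single zero event count; both counts
    zero is undefined.  Person-time units must match between groups.
    """
    if time1 <= 0 or time2 <= 0:
        raise InputError("person-time must be strictly positive")
    if e1 < 0 or e2 < 0:
        raise InputError("event counts must be non-negative")
    if e1 == 0 and e2 == 0:
        raise UndefinedEffectError("both event counts are zero: IRR undefined")
    if e1 == 0:
        e1 = 0.5
    elif e2 == 0:
        e2 = 0.5
    lnirr = math.log((e1 / time1) / (e2 / time2))
    se = math.sqrt(1 / e1 + 1 / e2)
    return EffectEstimate.from_transform("IRR", lnirr, se, "rates")


def ratio_from_reported(
    which: str,
    value: float | None = None,
    ci: tuple[float, float] | None = None,
    log_value: float | None = None,
    log_se: float | None = None,
    route: str | None = None,
) -> EffectEstimate:
    """A reported ratio (OR/RR/IRR) with its 95% CI or log-scale SE.

    From a CI: SE = (ln(upper) - ln(lower)) / 3.92.  The CI must contain
    the point estimate.
    """
    if which not in ("OR", "RR", "IRR"):
        raise InputError("which must be OR, RR or IRR")
    if log_value is not None or log_se is not None:
        if log_value is None or log_se is None or log_se <= 0:
            raise InputError("supply both log_value and a positive log_se")
        return EffectEstimate.from_transform(
            which, log_value, log_se, route or f"log{which.lower()}_se"
        )
    if value is None or value <= 0:
        raise InputError("ratio value must be strictly positive")
    if ci is None:
        raise InputError("supply a CI or a log-scale SE")
    lo, up = ci
    if not (0 < lo < up):
        raise InputError("CI bounds must be positive with lower < upper")
    if not lo <= value <= up:
        raise InputError(
            f"CI ({lo}, {up}) does not contain the point estimate {value}"
        )
    se = (math.log(up) - math.log(lo)) / (2 * Z95)
    return EffectEstimate.from_transform(
        which, math.log(value), se, route or f"{which.lower()}_ci"
    )


# ---------------------------------------------------------------------------
# d <-> lnOR


def logor_from_d(est: EffectEstimate, method: str = "hasselblad_hedges") -> EffectEstimate:
    """Convert a D estimate to an OR on the logistic model.

    hasselblad_hedges: lnOR = d pi/sqrt(3);  cox: lnOR = 1.65 d.
    """
    if est.measure != "D":
        raise InputError("logor_from_d expects a D estimate")
    k = {"hasselblad_hedges": HH, "cox": COX}.get(method)
    if k is None:
        raise InputError(f"unknown method {method!r}; valid: {D_TO_LNOR_METHODS}")
    return EffectEstimate.from_transform(
        "OR", k * est.value, k * est.se, est.route,
        df_like=est.df_like, method=method, note=est.note,
    )


def d_from_logor(est: EffectEstimate, method: str = "hasselblad_hedges") -> EffectEstimate:
    """Algebraic inverse of :func:`logor_from_d`."""
    if est.measure != "OR":
        raise InputError("d_from_logor expects an OR estimate")
    k = {"hasselblad_hedges": HH, "cox": COX}.get(method)
    if k is None:
        raise InputError(f"unknown method {method!r}; valid: {D_TO_LNOR_METHODS}")
    lnor = math.log(est.value)
    return EffectEstimate.from_transform(
        "D", lnor / k, est.se / k, est.route, method=method, note=est.note,
    )


# ---------------------------------------------------------------------------
# OR -> RR (six registered methods)


def _require_baseline(p0):
    if p0 is None or not 0 < p0 < 1:
        raise InputError("this method needs a baseline risk in (0, 1)")
    return p0


def _zhang_yu(or_est, p0, method_name):
    """RR = OR / (1 - p0 + p0 OR); SE by the delta method on the log scale:
    dlnRR/dlnOR = 1 - p0 OR / (1 - p0 + p0 OR)."""
    p0 = _require_baseline(p0)
    o = or_est.value
    denom = 1 - p0 + p0 * o
    rr = o / denom
    deriv = 1 - p0 * o / denom
    se = abs(deriv) * or_est.se
    if se <= 0:
        raise UndefinedEffectError("degenerate delta-method SE")
    return EffectEstimate.from_transform(
        "RR", math.log(rr), se, or_est.route, method=method_name, note=or_est.note
    )


def _rr_rare_disease(or_est, p0=None, n1=None, n2=None):
    """Rare-disease identity: RR = OR (valid when the event is rare)."""
    return EffectEstimate.from_transform(
        "RR", math.log(or_est.value), or_est.se, or_est.route,
        method="rare_disease", note=or_est.note,
    )


def _rr_zhang_yu(or_est, p0=None, n1=None, n2=None):
    """Zhang-Yu with the row's own control risk."""
    return _zhang_yu(or_est, p0, "zhang_yu")


def _rr_zhang_yu_median(or_est, p0=None, n1=None, n2=None):
    """Zhang-Yu with the dataset-median baseline risk (the caller supplies
    the median as ``p0``)."""
    return _zhang_yu(or_est, p0, "zhang_yu_median")


def _rr_reconstructed_2x2(or_est, p0=None, n1=None, n2=None):
    """Rebuild the 2x2 table from OR, control risk and group sizes, then
    apply the direct RR formula."""
    p0 = _require_baseline(p0)
    if n1 is None or n2 is None or n1 < 2 or n2 < 2:
        raise InputError("reconstructed_2x2 needs both group sizes")
    o = or_est.value
    odds1 = o * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    est = logrr_from_2x2(p1 * n1, (1 - p1) * n1, p0 * n2, (1 - p0) * n2,
                         route=or_est.route)
    return EffectEstimate.from_transform(
        "RR", math.log(est.value), est.se, or_est.route,
        method="reconstructed_2x2", note=or_est.note,
    )


def _rr_via_smd_probit(or_est, p0=None, n1=None, n2=None):
    """OR -> d (Hasselblad-Hedges), then d -> risks on the probit scale:
    EER = Phi(d + Phi^-1(p0)), RR = EER / p0."""
    p0 = _require_baseline(p0)
    d_est = d_from_logor(or_est)
    z0 = stats.norm.ppf(p0)
    eer = float(stats.norm.cdf(d_est.value + z0))
    if eer <= 0:
        raise UndefinedEffectError("degenerate probit risk")
    # delta method: dlnRR/dd = phi(d + z0)/EER
    deriv = float(stats.norm.pdf(d_est.value + z0)) / eer
    se = deriv * d_est.se
    if se <= 0:
        raise UndefinedEffectError("degenerate delta-method SE")
    return EffectEstimate.from_transform(
        "RR", math.log(eer / p0), se, or_est.route,
        method="via_smd_probit", note=or_est.note,
    )


def _rr_sqrt_or(or_est, p0=None, n1=None, n2=None):
    """Square-root approximation: RR = sqrt(OR), SE(lnRR) = SE(lnOR)/2."""
    return EffectEstimate.from_transform(
        "RR", math.log(or_est.value) / 2, or_est.se / 2, or_est.route,
        method="sqrt_or", note=or_est.note,
    )


#: The six registered OR->RR conversion approaches.
OR_TO_RR_METHODS = {
    "rare_disease": _rr_rare_disease,
    "zhang_yu": _rr_zhang_yu,
    "zhang_yu_median": _rr_zhang_yu_median,
    "reconstructed_2x2": _rr_reconstructed_2x2,
    "via_smd_probit": _rr_via_smd_probit,
    "sqrt_or": _rr_sqrt_or,
}


def rr_from_or(
    or_est: EffectEstimate,
    baseline_risk: float | None = None,
    method: str = "zhang_yu",
    n1: float | None = None,
    n2: float | None = None,
) -> EffectEstimate:
    """Convert an OR estimate to an RR by one of the six registered
    approaches (default Zhang-Yu)."""
    if or_est.measure != "OR":
        raise InputError("rr_from_or expects an OR estimate")
    fn = OR_TO_RR_METHODS.get(method)
    if fn is None:
        raise InputError(
            f"unknown method {method!r}; valid: {sorted(OR_TO_RR_METHODS)}"
        )
    return fn(or_est, p0=baseline_risk, n1=n1, n2=n2)


def or_from_rr(rr_est: EffectEstimate, baseline_risk: float) -> EffectEstimate:
    """Inverse Zhang-Yu: OR = RR (1 - p0) / (1 - p0 RR)."""
    if rr_est.measure != "RR":
        raise InputError("or_from_rr expects an RR estimate")
    p0 = _require_baseline(baseline_risk)
    rr = rr_est.value
    if p0 * rr >= 1:
        raise UndefinedEffectError(
            "baseline risk times RR reaches 1: OR undefined"
        )
    o = rr * (1 - p0) / (1 - p0 * rr)
    # dlnOR/dlnRR = 1 + p0 RR / (1 - p0 RR)
    deriv = 1 + p0 * rr / (1 - p0 * rr)
    return EffectEstimate.from_transform(
        "OR", math.log(o), deriv * rr_est.se, rr_est.route,
        method="zhang_yu_inverse", note=rr_est.note,
    )


# ---------------------------------------------------------------------------
# NNT


def nnt_from_risks(p1, p2, n1=None, n2=None, route: str = "2x2") -> EffectEstimate:
    """NNT = 1 / (p1 - p2); positive NNT means group 1 has more events.

    With group sizes, the CI transforms the Wald risk-difference interval;
    without them a nominal large-sample SE cannot be formed and an error
    is raised.  Reported unrounded (round up for clinical use).
    """
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise InputError("risks must lie in [0, 1]")
    ard = p1 - p2
    if ard == 0:
        raise UndefinedEffectError("equal risks: NNT is infinite")
    if n1 is None or n2 is None or n1 < 2 or n2 < 2:
        raise InputError("group sizes are needed for the NNT interval")
    var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var <= 0:
        raise UndefinedEffectError("degenerate risk-difference variance")
    return EffectEstimate.from_transform("NNT", ard, math.sqrt(var), route)


def nnt_from_d(d_est: EffectEstimate, cer: float) -> EffectEstimate:
    """Furukawa's conversion: NNT = 1 / (Phi(d + Phi^-1(CER)) - CER),
    with the SE mapped through the normal density (delta method)."""
    if d_est.measure != "D":
        raise InputError("nnt_from_d expects a D estimate")
    if cer is None or not 0 < cer < 1:
        raise InputError("CER must lie in (0, 1)")
    z0 = stats.norm.ppf(cer)
    eer = float(stats.norm.cdf(d_est.value + z0))
    ard = eer - cer
    if ard == 0:
        raise UndefinedEffectError("zero risk difference: NNT is infinite")
    se = float(stats.norm.pdf(d_est.value + z0)) * d_est.se
    if se <= 0:
        raise UndefinedEffectError("degenerate delta-method SE")
    return EffectEstimate.from_transform(
        "NNT", ard, se, d_est.route, method="furukawa", note=d_est.note
    )


def nnt_from_or(or_est: EffectEstimate, baseline_risk: float) -> EffectEstimate:
    """OR route: Zhang-Yu RR, then NNT = 1 / (p0 (RR - 1))."""
    rr_est = rr_from_or(or_est, baseline_risk, method="zhang_yu")
    return nnt_from_rr(rr_est, baseline_risk)


def nnt_from_rr(rr_est: EffectEstimate, baseline_risk: float) -> EffectEstimate:
    """RR route: EER = p0 RR, ARD = p0 (RR - 1), NNT = 1/ARD."""
    if rr_est.measure != "RR":
        raise InputError("nnt_from_rr expects an RR estimate")
    p0 = _require_baseline(baseline_risk)
    rr = rr_est.value
    ard = p0 * (rr - 1)
    if ard == 0:
        raise UndefinedEffectError("RR = 1: NNT is infinite")
    # delta method on lnRR: dARD/dlnRR = p0 RR
    se = p0 * rr * rr_est.se
    return EffectEstimate.from_transform(
        "NNT", ard, se, rr_est.route, method=rr_est.method, note=rr_est.note
    )
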