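"""Route registry: every (measure, input-route) formula the engine knows.

An *input route* is one recognized combination of reported statistics
(means+SDs, a 2x2 table, t with group sizes, ...).  For each of the 11
measures the registry holds an ordered list of :class:`Formula` entries;
the order IS the shipped pre-defined selection hierarchy and always ranks

    tier 0  direct/raw input            (means_sd, 2x2, r_n, rates, ...)
    tier 1  reported-estimate input     (means_se, or_ci, md_se, ...)
    tier 2  test statistics             (t, f, p, eta2)
    tier 3  approximations/conversions  (median-based, cross-measure)

The same ordering ships as one editable text file per measure under
``data/hierarchies/`` (the 'auto' selection strategy reads those files, so
users can re-rank routes without touching code).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable

from . import binary, corr, dispersion, smd
from .estimate import EffectEstimate, InputError, MEASURES


@dataclass(frozen=True)
class Formula:
    """One registered way of computing one measure from one input route."""

    measure: str
    route: str
    tier: int
    requires: tuple[str, ...]
    fn: Callable  # StudyRow -> EffectEstimate
    needs_direction: bool = False

    def applicable(self, row) -> bool:
        """True when every required field is present (direction included)."""
        if any(getattr(row, f) is None for f in self.requires):
            return False
        return True

    def direction_ok(self, row) -> bool:
        return (not self.needs_direction) or (
            getattr(row, "es_direction", None) in ("positive", "negative")
        )


# ---------------------------------------------------------------------------
# shared field bundles

_MEANS_SD = ("m1", "m2", "sd1", "sd2", "n1", "n2")
_MEANS_SE = ("m1", "m2", "se1", "se2", "n1", "n2")
_MEANS_CI = ("m1", "m2", "m1_ci_lo", "m1_ci_up", "m2_ci_lo", "m2_ci_up",
             "n1", "n2")
_MED_IQR = ("med1", "q1_1", "q3_1", "med2", "q1_2", "q3_2", "n1", "n2")
_MED_RANGE = ("med1", "min1", "max1", "med2", "min2", "max2", "n1", "n2")
_MED_BOTH = tuple(dict.fromkeys(_MED_IQR + _MED_RANGE))
_CHANGE = ("pre_m1", "pre_m2", "pre_sd1", "pre_sd2", "r_prepost",
           "m1", "m2", "sd1", "sd2", "n1", "n2")
_ANCOVA = ("adj_m1", "adj_m2", "adj_sd_pooled", "n1", "n2")
_2X2 = ("a", "b", "c", "d_cell")
_PROPS = ("p_event1", "p_event2", "n1", "n2")
_OR_CI = ("or_value", "or_ci_lo", "or_ci_up")
_LOGOR = ("logor_value", "logor_se")
_RR_CI = ("rr_value", "rr_ci_lo", "rr_ci_up")
_IRR_CI = ("irr_value", "irr_ci_lo", "irr_ci_up")
_RATES = ("e1", "time1", "e2", "time2")

_APPROX_NOTE = "median-based normal approximation"


# ---------------------------------------------------------------------------
# per-group moment reconstruction helpers


def _sds_via_se(row):
    _, sd1 = smd.moments_from_precision(row.m1, row.n1, se=row.se1)
    _, sd2 = smd.moments_from_precision(row.m2, row.n2, se=row.se2)
    return sd1, sd2


def _sds_via_ci(row):
    _, sd1 = smd.moments_from_precision(
        row.m1, row.n1, ci=(row.m1_ci_lo, row.m1_ci_up))
    _, sd2 = smd.moments_from_precision(
        row.m2, row.n2, ci=(row.m2_ci_lo, row.m2_ci_up))
    return sd1, sd2


def _moments_via_quantiles(row, scenario):
    m1, sd1 = smd.moments_from_quantiles(
        row.n1, med=row.med1, q1=row.q1_1, q3=row.q3_1,
        minimum=row.min1, maximum=row.max1, scenario=scenario)
    m2, sd2 = smd.moments_from_quantiles(
        row.n2, med=row.med2, q1=row.q1_2, q3=row.q3_2,
        minimum=row.min2, maximum=row.max2, scenario=scenario)
    return m1, sd1, m2, sd2


def _cells_from_props(row):
    a = row.p_event1 * row.n1
    c = row.p_event2 * row.n2
    return a, row.n1 - a, c, row.n2 - c


def _tag(est: EffectEstimate, note: str) -> EffectEstimate:
    from dataclasses import replace

    return replace(est, note=note if est.note is None else est.note)


# ---------------------------------------------------------------------------
# D builders (route id encoded in each)


def _d_means_sd(row):
    return smd.d_from_means(row.m1, row.m2, row.sd1, row.sd2, row.n1, row.n2)


def _d_means_se(row):
    sd1, sd2 = _sds_via_se(row)
    return smd.d_from_means(row.m1, row.m2, sd1, sd2, row.n1, row.n2,
                            route="means_se")


def _d_means_ci(row):
    sd1, sd2 = _sds_via_ci(row)
    return smd.d_from_means(row.m1, row.m2, sd1, sd2, row.n1, row.n2,
                            route="means_ci")


def _d_change(row):
    return smd.d_from_change(
        row.m1, row.m2, row.sd1, row.sd2, row.pre_m1, row.pre_m2,
        row.pre_sd1, row.pre_sd2, row.r_prepost, row.n1, row.n2)


def _d_ancova(row):
    return smd.d_from_ancova(row.adj_m1, row.adj_m2, row.adj_sd_pooled,
                             row.n1, row.n2)


def _d_md_se(row):
    return smd.d_from_md(row.md_value, row.md_se, row.n1, row.n2, route="md_se")


def _d_md_ci(row):
    if not row.md_ci_up > row.md_ci_lo:
        raise InputError("MD CI must have positive width")
    se = (row.md_ci_up - row.md_ci_lo) / 3.92
    return smd.d_from_md(row.md_value, se, row.n1, row.n2, route="md_ci")


def _d_t(row):
    return smd.d_from_test_stat("t", row.t_value, row.n1, row.n2,
                                row.es_direction or "unspecified")


def _d_f(row):
    return smd.d_from_test_stat("F", row.f_value, row.n1, row.n2,
                                row.es_direction or "unspecified")


def _d_p(row):
    return smd.d_from_test_stat("p", row.p_value, row.n1, row.n2,
                                row.es_direction or "unspecified")


def _d_eta2(row):
    return smd.d_from_test_stat("eta2", row.eta_sq, row.n1, row.n2,
                                row.es_direction or "unspecified")


def _make_d_quantile(scenario, route):
    def fn(row):
        m1, sd1, m2, sd2 = _moments_via_quantiles(row, scenario)
        est = smd.d_from_means(m1, m2, sd1, sd2, row.n1, row.n2, route=route)
        return _tag(est, _APPROX_NOTE)

    return fn


_d_med_iqr = _make_d_quantile("iqr_only", "med_iqr")
_d_med_range = _make_d_quantile("range_only", "med_range")
_d_med_both = _make_d_quantile("both", "med_iqr_range")


def _d_r_n(row):
    return corr.d_from_r(row.r_value, row.n_r)


def _or_2x2(row):
    return binary.logor_from_2x2(row.a, row.b, row.c, row.d_cell)


def _or_props(row):
    a, b, c, d_cell = _cells_from_props(row)
    return binary.logor_from_2x2(a, b, c, d_cell, route="props")


def _or_reported_ci(row):
    return binary.ratio_from_reported(
        "OR", value=row.or_value, ci=(row.or_ci_lo, row.or_ci_up))


def _or_reported_log(row):
    return binary.ratio_from_reported(
        "OR", log_value=row.logor_value, log_se=row.logor_se)


def _or_from_rr_ci(row):
    rr = binary.ratio_from_reported(
        "RR", value=row.rr_value, ci=(row.rr_ci_lo, row.rr_ci_up))
    return binary.or_from_rr(rr, row.baseline_risk)


def _d_via(or_fn, df_fn=None):
    """d from an OR builder; attaches df (for the g correction) when the
    input route lets the total sample size be recovered."""

    def fn(row):
        from dataclasses import replace

        est = binary.d_from_logor(or_fn(row))
        if df_fn is not None:
            est = replace(est, df_like=df_fn(row))
        return est

    return fn


_d_2x2 = _d_via(_or_2x2, lambda r: r.a + r.b + r.c + r.d_cell - 2)
_d_props = _d_via(_or_props, lambda r: r.n1 + r.n2 - 2)
_d_or_ci = _d_via(_or_reported_ci)
_d_logor_se = _d_via(_or_reported_log)
# reported-OR routes carry no sample size; the g correction needs one
_d_or_ci_n = _d_via(_or_reported_ci, lambda r: r.n1 + r.n2 - 2)
_d_logor_se_n = _d_via(_or_reported_log, lambda r: r.n1 + r.n2 - 2)

# (route, tier-for-D, requires, fn, needs_direction); order = D hierarchy
_D_DIRECT = [
    ("means_sd", 0, _MEANS_SD, _d_means_sd, False),
    ("change_scores", 0, _CHANGE, _d_change, False),
    ("ancova_means", 0, _ANCOVA, _d_ancova, False),
    ("means_se", 1, _MEANS_SE, _d_means_se, False),
    ("means_ci", 1, _MEANS_CI, _d_means_ci, False),
    ("md_se", 1, ("md_value", "md_se", "n1", "n2"), _d_md_se, False),
    ("md_ci", 1, ("md_value", "md_ci_lo", "md_ci_up", "n1", "n2"),
     _d_md_ci, False),
    ("t", 2, ("t_value", "n1", "n2"), _d_t, False),
    ("f", 2, ("f_value", "n1", "n2"), _d_f, True),
    ("p", 2, ("p_value", "n1", "n2"), _d_p, True),
    ("eta2", 2, ("eta_sq", "n1", "n2"), _d_eta2, True),
    ("med_iqr_range", 3, _MED_BOTH, _d_med_both, False),
    ("med_iqr", 3, _MED_IQR, _d_med_iqr, False),
    ("med_range", 3, _MED_RANGE, _d_med_range, False),
    ("r_n", 3, ("r_value", "n_r"), _d_r_n, False),
]

_D_FROM_OR = [
    ("2x2", 3, _2X2, _d_2x2, False),
    ("props", 3, _PROPS, _d_props, False),
    ("or_ci", 3, _OR_CI, _d_or_ci, False),
    ("logor_se", 3, _LOGOR, _d_logor_se, False),
]

_OR_NATIVE = [
    ("2x2", 0, _2X2, _or_2x2, False),
    ("props", 1, _PROPS, _or_props, False),
    ("or_ci", 1, _OR_CI, _or_reported_ci, False),
    ("logor_se", 1, _LOGOR, _or_reported_log, False),
    ("rr_ci", 3, _RR_CI + ("baseline_risk",), _or_from_rr_ci, False),
]


# ---------------------------------------------------------------------------
# registry assembly

_REGISTRY: dict[str, list[Formula]] = {m: [] for m in MEASURES}


def _reg(measure, route, tier, requires, fn, needs_direction=False):
    _REGISTRY[measure].append(
        Formula(measure, route, tier, tuple(requires), fn, needs_direction)
    )


def _g_wrap(d_fn):
    def fn(row):
        return smd.hedges_correction(d_fn(row))

    return fn


def _lnor_wrap(d_fn):
    def fn(row):
        return binary.logor_from_d(d_fn(row))

    return fn


def _r_wrap(d_fn):
    def fn(row):
        return corr.r_from_d(d_fn(row), row.n1, row.n2)

    return fn


def _r_from_or_wrap(or_fn):
    def fn(row):
        return corr.r_from_or(or_fn(row), method="via_d_hh")

    return fn


def _z_wrap(r_fn):
    def fn(row):
        return corr.z_from_r_estimate(r_fn(row))

    return fn


def _nnt_d_wrap(d_fn):
    def fn(row):
        return binary.nnt_from_d(d_fn(row), row.baseline_risk)

    return fn


# --- D and G
# G shares every D route; its reported-OR routes additionally need the
# group sizes so the small-sample correction has a df to work with.
_G_FROM_OR = [
    ("2x2", 3, _2X2, _d_2x2, False),
    ("props", 3, _PROPS, _d_props, False),
    ("or_ci", 3, _OR_CI + ("n1", "n2"), _d_or_ci_n, False),
    ("logor_se", 3, _LOGOR + ("n1", "n2"), _d_logor_se_n, False),
]
for route, tier, req, fn, nd in _D_DIRECT + _D_FROM_OR:
    _reg("D", route, tier, req, fn, nd)
for route, tier, req, fn, nd in _D_DIRECT + _G_FROM_OR:
    _reg("G", route, tier, req, _g_wrap(fn), nd)

# --- MD
def _md_means_sd(row):
    return smd.md_from_means(row.m1, row.m2, row.sd1, row.sd2, row.n1, row.n2)


def _md_means_se(row):
    sd1, sd2 = _sds_via_se(row)
    return smd.md_from_means(row.m1, row.m2, sd1, sd2, row.n1, row.n2,
                             route="means_se")


def _md_means_ci(row):
    sd1, sd2 = _sds_via_ci(row)
    return smd.md_from_means(row.m1, row.m2, sd1, sd2, row.n1, row.n2,
                             route="means_ci")


def _md_reported_se(row):
    return smd.md_from_reported(row.md_value, se=row.md_se)


def _md_reported_ci(row):
    return smd.md_from_reported(row.md_value,
                                ci=(row.md_ci_lo, row.md_ci_up))


def _make_md_quantile(scenario, route):
    def fn(row):
        m1, sd1, m2, sd2 = _moments_via_quantiles(row, scenario)
        est = smd.md_from_means(m1, m2, sd1, sd2, row.n1, row.n2, route=route)
        return _tag(est, _APPROX_NOTE)

    return fn


for route, tier, req, fn in [
    ("means_sd", 0, _MEANS_SD, _md_means_sd),
    ("means_se", 1, _MEANS_SE, _md_means_se),
    ("means_ci", 1, _MEANS_CI, _md_means_ci),
    ("md_se", 1, ("md_value", "md_se"), _md_reported_se),
    ("md_ci", 1, ("md_value", "md_ci_lo", "md_ci_up"), _md_reported_ci),
    ("med_iqr_range", 3, _MED_BOTH, _make_md_quantile("both", "med_iqr_range")),
    ("med_iqr", 3, _MED_IQR, _make_md_quantile("iqr_only", "med_iqr")),
    ("med_range", 3, _MED_RANGE, _make_md_quantile("range_only", "med_range")),
]:
    _reg("MD", route, tier, req, fn)

# --- OR
for route, tier, req, fn, nd in _OR_NATIVE:
    _reg("OR", route, tier, req, fn, nd)
for route, tier, req, fn, nd in _D_DIRECT:
    _reg("OR", route, 3, req, _lnor_wrap(fn), nd)

# --- RR
def _rr_2x2(row):
    return binary.logrr_from_2x2(row.a, row.b, row.c, row.d_cell)


def _rr_props(row):
    a, b, c, d_cell = _cells_from_props(row)
    return binary.logrr_from_2x2(a, b, c, d_cell, route="props")


def _rr_reported_ci(row):
    return binary.ratio_from_reported(
        "RR", value=row.rr_value, ci=(row.rr_ci_lo, row.rr_ci_up))


def _rr_from_or_ci(row):
    return binary.rr_from_or(_or_reported_ci(row), row.baseline_risk)


def _rr_from_logor(row):
    return binary.rr_from_or(_or_reported_log(row), row.baseline_risk)


for route, tier, req, fn in [
    ("2x2", 0, _2X2, _rr_2x2),
    ("props", 1, _PROPS, _rr_props),
    ("rr_ci", 1, _RR_CI, _rr_reported_ci),
    ("or_ci", 3, _OR_CI + ("baseline_risk",), _rr_from_or_ci),
    ("logor_se", 3, _LOGOR + ("baseline_risk",), _rr_from_logor),
]:
    _reg("RR", route, tier, req, fn)

# --- IRR
def _irr_rates(row):
    return binary.logirr_from_rates(row.e1, row.time1, row.e2, row.time2)


def _irr_reported_ci(row):
    return binary.ratio_from_reported(
        "IRR", value=row.irr_value, ci=(row.irr_ci_lo, row.irr_ci_up))


_reg("IRR", "rates", 0, _RATES, _irr_rates)
_reg("IRR", "irr_ci", 1, _IRR_CI, _irr_reported_ci)

# --- R and Z
def _r_direct(row):
    _, r_est = corr.z_from_r(row.r_value, row.n_r)
    return r_est


def _z_direct(row):
    z_est, _ = corr.z_from_r(row.r_value, row.n_r)
    return z_est


_reg("R", "r_n", 0, ("r_value", "n_r"), _r_direct)
_reg("Z", "r_n", 0, ("r_value", "n_r"), _z_direct)
for route, tier, req, fn, nd in _D_DIRECT:
    if route == "r_n":
        continue
    r_fn = _r_wrap(fn)
    _reg("R", route, 3, req, r_fn, nd)
    _reg("Z", route, 3, req, _z_wrap(r_fn), nd)
for route, tier, req, fn, nd in [
    ("2x2", 3, _2X2, _or_2x2, False),
    ("props", 3, _PROPS, _or_props, False),
    ("or_ci", 3, _OR_CI, _or_reported_ci, False),
    ("logor_se", 3, _LOGOR, _or_reported_log, False),
]:
    r_fn = _r_from_or_wrap(fn)
    _reg("R", route, tier, req, r_fn, nd)
    _reg("Z", route, tier, req, _z_wrap(r_fn), nd)

# --- VR and CVR
def _vr_means_sd(row):
    return dispersion.lnvr_from_moments(row.sd1, row.sd2, row.n1, row.n2)


def _vr_means_se(row):
    sd1, sd2 = _sds_via_se(row)
    return dispersion.lnvr_from_moments(sd1, sd2, row.n1, row.n2,
                                        route="means_se")


def _vr_means_ci(row):
    sd1, sd2 = _sds_via_ci(row)
    return dispersion.lnvr_from_moments(sd1, sd2, row.n1, row.n2,
                                        route="means_ci")


def _make_vr_quantile(scenario, route):
    def fn(row):
        _, sd1, _, sd2 = _moments_via_quantiles(row, scenario)
        est = dispersion.lnvr_from_moments(sd1, sd2, row.n1, row.n2,
                                           route=route)
        return _tag(est, _APPROX_NOTE)

    return fn


def _cvr_means_sd(row):
    return dispersion.lncvr_from_moments(row.m1, row.sd1, row.m2, row.sd2,
                                         row.n1, row.n2)


def _cvr_means_se(row):
    sd1, sd2 = _sds_via_se(row)
    return dispersion.lncvr_from_moments(row.m1, sd1, row.m2, sd2,
                                         row.n1, row.n2, route="means_se")


def _cvr_means_ci(row):
    sd1, sd2 = _sds_via_ci(row)
    return dispersion.lncvr_from_moments(row.m1, sd1, row.m2, sd2,
                                         row.n1, row.n2, route="means_ci")


def _make_cvr_quantile(scenario, route):
    def fn(row):
        m1, sd1, m2, sd2 = _moments_via_quantiles(row, scenario)
        est = dispersion.lncvr_from_moments(m1, sd1, m2, sd2,
                                            row.n1, row.n2, route=route)
        return _tag(est, _APPROX_NOTE)

    return fn


_SD_ONLY = ("sd1", "sd2", "n1", "n2")
for route, tier, req, fn in [
    ("means_sd", 0, _SD_ONLY, _vr_means_sd),
    ("means_se", 1, ("se1", "se2", "n1", "n2", "m1", "m2"), _vr_means_se),
    ("means_ci", 1, _MEANS_CI, _vr_means_ci),
    ("med_iqr_range", 3, _MED_BOTH, _make_vr_quantile("both", "med_iqr_range")),
    ("med_iqr", 3, _MED_IQR, _make_vr_quantile("iqr_only", "med_iqr")),
    ("med_range", 3, _MED_RANGE, _make_vr_quantile("range_only", "med_range")),
]:
    _reg("VR", route, tier, req, fn)
for route, tier, req, fn in [
    ("means_sd", 0, _MEANS_SD, _cvr_means_sd),
    ("means_se", 1, _MEANS_SE, _cvr_means_se),
    ("means_ci", 1, _MEANS_CI, _cvr_means_ci),
    ("med_iqr_range", 3, _MED_BOTH, _make_cvr_quantile("both", "med_iqr_range")),
    ("med_iqr", 3, _MED_IQR, _make_cvr_quantile("iqr_only", "med_iqr")),
    ("med_range", 3, _MED_RANGE, _make_cvr_quantile("range_only", "med_range")),
]:
    _reg("CVR", route, tier, req, fn)

# --- NNT
def _nnt_2x2(row):
    n1, n2 = row.a + row.b, row.c + row.d_cell
    if n1 <= 0 or n2 <= 0:
        raise InputError("each 2x2 row margin must be positive")
    return binary.nnt_from_risks(row.a / n1, row.c / n2, n1, n2, route="2x2")


def _nnt_props(row):
    return binary.nnt_from_risks(row.p_event1, row.p_event2, row.n1, row.n2,
                                 route="props")


def _nnt_or_ci(row):
    return binary.nnt_from_or(_or_reported_ci(row), row.baseline_risk)


def _nnt_logor(row):
    return binary.nnt_from_or(_or_reported_log(row), row.baseline_risk)


def _nnt_rr_ci(row):
    return binary.nnt_from_rr(_rr_reported_ci(row), row.baseline_risk)


for route, tier, req, fn in [
    ("2x2", 0, _2X2, _nnt_2x2),
    ("props", 1, _PROPS, _nnt_props),
    ("or_ci", 3, _OR_CI + ("baseline_risk",), _nnt_or_ci),
    ("logor_se", 3, _LOGOR + ("baseline_risk",), _nnt_logor),
    ("rr_ci", 3, _RR_CI + ("baseline_risk",), _nnt_rr_ci),
]:
    _reg("NNT", route, tier, req, fn)
for route, tier, req, fn, nd in _D_DIRECT:
    _reg("NNT", route, 3, req + ("baseline_risk",), _nnt_d_wrap(fn), nd)


# ---------------------------------------------------------------------------
# public API


def measures() -> tuple[str, ...]:
    return MEASURES


def formulas_for(measure: str) -> tuple[Formula, ...]:
    try:
        return tuple(_REGISTRY[measure])
    except KeyError:
        raise InputError(
            f"unknown measure {measure!r}; valid codes: {', '.join(MEASURES)}"
        )


def routes(measure: str | None = None) -> tuple[str, ...]:
    """Distinct input-route identifiers (optionally for one measure)."""
    if measure is not None:
        return tuple(f.route for f in formulas_for(measure))
    seen = dict.fromkeys(
        f.route for fs in _REGISTRY.values() for f in fs
    )
    return tuple(seen)


def n_formulas() -> int:
    return sum(len(fs) for fs in _REGISTRY.values())


def predefined_routes(measure: str) -> tuple[str, ...]:
    """The shipped pre-defined hierarchy for a measure.

    Read from the editable text config (one route id per line, '#'
    comments allowed); falls back to registry order if the file is
    missing or empty.
    """
    formulas_for(measure)  # validates the code
    try:
        text = (
            resources.files("esconvert")
            .joinpath(f"data/hierarchies/{measure}.txt")
            .read_text(encoding="utf-8")
        )
    except (FileNotFoundError, ModuleNotFoundError):
        return routes(measure)
    lines = [
        ln.strip() for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        return routes(measure)
    known = set(routes(measure))
    bad = [ln for ln in lines if ln not in known]
    if bad:
        raise InputError(
            f"hierarchy file for {measure} names unregistered route(s): {bad}"
        )
    return tuple(dict.fromkeys(lines))


def counts() -> dict[str, int]:
    """Registry-scale counts, all computed from the live registries."""
    from . import aggregate, consistency, engine

    return {
        "measures": len([m for m in MEASURES if _REGISTRY[m]]),
        "formulas": n_formulas(),
        "input_combinations": len(routes()),
        "or_to_rr_methods": len(binary.OR_TO_RR_METHODS),
        "aggregation_modes": len(aggregate.DEPENDENCE_MODES),
        "consistency_indicators": len(consistency.INDICATORS),
        "selection_approaches": len(engine.SELECTION_APPROACHES),
    }
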