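"""Effect-size estimate container and scale conventions.

Every computed effect size is an :class:`EffectEstimate`: the point value on
its natural reporting scale, a standard error on the measure's *transform*
scale (the scale on which ``value +/- 1.96*se`` is a valid Wald interval),
the back-transformed 95% CI, and bookkeeping about the input route that
produced it.

Scale conventions
-----------------
identity   D, G, MD, Z     value and SE share one additive scale
log        OR, RR, IRR, VR, CVR    SE on ln(value); CI exponentiated
fisher_z   R               SE on atanh(r); CI tanh-back-transformed
risk_diff  NNT             SE on the absolute risk difference 1/NNT;
                           CI by transforming the ARD interval bounds

A second, *comparison* scale is used whenever candidate estimates for one
row must be compared (selection of extremes, consistency indicators):
additive for D/G/MD/Z, log for the ratio measures, atanh(r) for R, and the
absolute risk difference for NNT (the reciprocal, so that the null maps to
0 and infinities never enter the arithmetic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

#: Normal multiplier used for every 95% interval, uniformly across measures.
Z95 = 1.96

MEASURES = ("D", "G", "MD", "OR", "RR", "IRR", "R", "Z", "VR", "CVR", "NNT")

LOG_MEASURES = frozenset({"OR", "RR", "IRR", "VR", "CVR"})

SCALE_IDENTITY = "identity"
SCALE_LOG = "log"
SCALE_FISHER_Z = "fisher_z"
SCALE_RISK_DIFF = "risk_diff"


class EsConvertError(Exception):
    """Base class for all package errors."""


class InputError(EsConvertError):
    """A formula received arguments outside its domain."""


class UndefinedEffectError(EsConvertError):
    """The effect size is mathematically undefined for these inputs
    (zero pooled SD, empty 2x2 margin, equal risks for an NNT, ...)."""


class DirectionRequiredError(InputError):
    """A signless statistic (F, p, eta^2) was supplied without an explicit
    effect direction; a silent positive sign is never assumed."""


def natural_scale(measure: str) -> str:
    """Transform scale on which a measure's SE lives."""
    if measure in LOG_MEASURES:
        return SCALE_LOG
    if measure in ("R", "Z"):
        return SCALE_FISHER_Z
    if measure == "NNT":
        return SCALE_RISK_DIFF
    return SCALE_IDENTITY


@dataclass(frozen=True)
class EffectEstimate:
    """One computed effect size.

    Parameters
    ----------
    measure : str
        One of :data:`MEASURES`.
    value : float
        Point estimate on the natural reporting scale (an OR, not a lnOR).
    se : float
        Standard error on the transform scale given by ``scale``.
    ci_lo, ci_up : float
        95% CI bounds on the natural scale.  May be NaN for an NNT whose
        risk-difference interval spans zero.
    scale : str
        Transform scale; see module docstring.
    route : str
        Identifier of the input-data combination used (``"means_sd"``,
        ``"2x2"``, ...).
    df_like : float or None
        Degrees-of-freedom-like quantity when one exists (n1+n2-2 for SMD
        routes); required by the small-sample g correction.
    method : str or None
        Named calculation method when a route admits several
        (e.g. ``"zhang_yu"`` for OR->RR).
    note : str or None
        Free-text caveat (approximation warnings etc.).
    """

    measure: str
    value: float
    se: float
    ci_lo: float
    ci_up: float
    scale: str
    route: str
    df_like: float | None = None
    method: str | None = None
    note: str | None = None

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise InputError(f"unknown measure {self.measure!r}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise InputError(
                f"standard error must be finite and positive, got {self.se!r}"
            )
        if math.isfinite(self.ci_lo) and math.isfinite(self.ci_up):
            if not (self.ci_lo <= self.value <= self.ci_up):
                raise InputError(
                    f"CI ({self.ci_lo}, {self.ci_up}) does not bracket "
                    f"value {self.value}"
                )

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_transform(
        cls,
        measure: str,
        tvalue: float,
        se: float,
        route: str,
        *,
        df_like: float | None = None,
        method: str | None = None,
        note: str | None = None,
    ) -> "EffectEstimate":
        """Build an estimate from (transform-scale value, SE).

        ``tvalue`` is the lnOR for OR, atanh(r) for R, z itself for Z, the
        absolute risk difference for NNT, and the plain value otherwise.
        """
        scale = natural_scale(measure)
        lo_t, up_t = tvalue - Z95 * se, tvalue + Z95 * se
        if scale == SCALE_LOG:
            value, ci_lo, ci_up = math.exp(tvalue), math.exp(lo_t), math.exp(up_t)
        elif scale == SCALE_FISHER_Z and measure == "R":
            value, ci_lo, ci_up = math.tanh(tvalue), math.tanh(lo_t), math.tanh(up_t)
        elif scale == SCALE_RISK_DIFF:
            if tvalue == 0:
                raise UndefinedEffectError(
                    "risk difference is zero: NNT is infinite"
                )
            value = 1.0 / tvalue
            if lo_t * up_t > 0:  # ARD interval excludes 0
                ci_lo, ci_up = sorted((1.0 / lo_t, 1.0 / up_t))
            else:
                ci_lo = ci_up = math.nan
                note = (note + "; " if note else "") + (
                    "risk-difference CI spans 0: NNT CI undefined"
                )
        else:
            value, ci_lo, ci_up = tvalue, lo_t, up_t
        return cls(
            measure=measure,
            value=value,
            se=se,
            ci_lo=ci_lo,
            ci_up=ci_up,
            scale=scale,
            route=route,
            df_like=df_like,
            method=method,
            note=note,
        )

    # -- scale accessors -------------------------------------------------

    @property
    def transform_value(self) -> float:
        """Point estimate on the transform scale (matches ``se``)."""
        if self.scale == SCALE_LOG:
            return math.log(self.value)
        if self.scale == SCALE_FISHER_Z and self.measure == "R":
            return math.atanh(self.value)
        if self.scale == SCALE_RISK_DIFF:
            return 1.0 / self.value
        return self.value

    @property
    def comparison_value(self) -> float:
        """Point estimate on the comparison scale (null always at 0)."""
        return self.transform_value

    @property
    def comparison_interval(self) -> tuple[float, float]:
        """95% CI on the comparison scale, ordered."""
        if self.scale == SCALE_LOG:
            return math.log(self.ci_lo), math.log(self.ci_up)
        if self.scale == SCALE_FISHER_Z and self.measure == "R":
            return math.atanh(self.ci_lo), math.atanh(self.ci_up)
        if self.scale == SCALE_RISK_DIFF:
            t = self.transform_value
            return t - Z95 * self.se, t + Z95 * self.se
        return self.ci_lo, self.ci_up

    def with_route(self, route: str) -> "EffectEstimate":
        return replace(self, route=route)
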