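"""Correlation measures: r, Fisher's z, and conversions from d and OR.

R and Z share one inferential scale: the SE always lives on the Fisher-z
scale with Var(z) = 1/(n-3), and R's CI is formed on z then mapped back
through tanh.  No natural-scale (1-r^2)^2 variance is ever reported.
"""

from __future__ import annotations

import math

from .estimate import EffectEstimate, InputError


def z_from_r(r_value: float, n_r: float, route: str = "r_n"):
    """Fisher transform of a reported correlation.

    Returns ``(z_estimate, r_estimate)`` — both measures are derivable
    from the one input.  z = atanh(r), Var(z) = 1/(n-3).
    """
    if not -1 < r_value < 1:
        raise InputError("r must lie in (-1, 1)")
    if n_r is None or n_r <= 3:
        raise InputError("n must be at least 4 for Var(z) = 1/(n-3)")
    z = math.atanh(r_value)
    se = 1 / math.sqrt(n_r - 3)
    z_est = EffectEstimate.from_transform("Z", z, se, route, df_like=n_r - 3)
    r_est = EffectEstimate.from_transform("R", z, se, route, df_like=n_r - 3)
    return z_est, r_est


def z_from_r_estimate(r_est: EffectEstimate) -> EffectEstimate:
    """Re-label an R estimate as Z (both already live on the z scale)."""
    if r_est.measure != "R":
        raise InputError("expects an R estimate")
    return EffectEstimate.from_transform(
        "Z", math.atanh(r_est.value), r_est.se, r_est.route,
        df_like=r_est.df_like, method=r_est.method, note=r_est.note,
    )


def r_from_d(est: EffectEstimate, n1=None, n2=None) -> EffectEstimate:
    """Algebraic d -> r conversion: r = d / sqrt(d^2 + a),
    a = (n1+n2)^2/(n1 n2), defaulting to a = 4 when group sizes are
    unknown.  The CI is formed on the Fisher-z scale with n = n1 + n2."""
    if est.measure != "D":
        raise InputError("r_from_d expects a D estimate")
    if n1 is not None and n2 is not None:
        if min(n1, n2) < 2:
            raise InputError("each group needs n >= 2")
        a = (n1 + n2) ** 2 / (n1 * n2)
        n = n1 + n2
    else:
        a = 4.0
        n = (est.df_like + 2) if est.df_like else None
    d = est.value
    r = d / math.sqrt(d * d + a)
    if n is not None and n > 3:
        # interval on the Fisher-z scale with the total sample size
        se_z = 1 / math.sqrt(n - 3)
    else:
        # delta method through z = atanh(r(d)): dz/dd = (dr/dd)/(1-r^2)
        dr_dd = a / (d * d + a) ** 1.5
        se_z = dr_dd / (1 - r * r) * est.se
    return EffectEstimate.from_transform(
        "R", math.atanh(r), se_z, "d_to_r" if est.route == "d" else est.route,
        df_like=est.df_like, method=est.method, note=est.note,
    )


def d_from_r(r_value: float, n_r: float) -> EffectEstimate:
    """Inverse conversion r -> d with a = 4: d = 2r/sqrt(1-r^2),
    Var(d) = 4 Var(r)/(1-r^2)^3 with Var(r) = (1-r^2)^2/(n-1)."""
    if not -1 < r_value < 1:
        raise InputError("r must lie in (-1, 1)")
    if n_r is None or n_r < 4:
        raise InputError("n must be at least 4")
    om = 1 - r_value**2
    d = 2 * r_value / math.sqrt(om)
    var_r = om**2 / (n_r - 1)
    var_d = 4 * var_r / om**3
    return EffectEstimate.from_transform(
        "D", d, math.sqrt(var_d), "r_n", df_like=n_r - 2
    )


OR_TO_R_METHODS = ("via_d_hh", "via_d_cox", "tetrachoric_approx")


def r_from_or(or_est: EffectEstimate, method: str = "via_d_hh") -> EffectEstimate:
    """Convert an OR to a correlation by one of three registered methods.

    via_d_hh / via_d_cox chain the logistic lnOR -> d conversion with the
    algebraic d -> r (a = 4); tetrachoric_approx uses the closed form
    r = cos(pi / (1 + sqrt(OR))).
    """
    from . import binary

    if or_est.measure != "OR":
        raise InputError("r_from_or expects an OR estimate")
    if method == "via_d_hh":
        return r_from_d(binary.d_from_logor(or_est, "hasselblad_hedges"))
    if method == "via_d_cox":
        return r_from_d(binary.d_from_logor(or_est, "cox"))
    if method == "tetrachoric_approx":
        o = or_est.value
        r = math.cos(math.pi / (1 + math.sqrt(o)))
        # delta method on lnOR through r(OR), then onto the z scale
        dr_do = (
            math.sin(math.pi / (1 + math.sqrt(o)))
            * math.pi / (1 + math.sqrt(o)) ** 2 / (2 * math.sqrt(o))
        )
        se_z = dr_do * o / (1 - r * r) * or_est.se
        return EffectEstimate.from_transform(
            "R", math.atanh(r), se_z, or_est.route,
            method="tetrachoric_approx", note=or_est.note,
        )
    raise InputError(f"unknown method {method!r}; valid: {OR_TO_R_METHODS}")
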