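"""Dispersion-ratio measures: lnVR and lnCVR.

Both compare the variability of two groups on the log scale, with the
small-sample bias correction 1/(2(n-1)) per group.  The CVR variance
omits the mean-SD correlation term (the schema carries no within-study
raw data from which to estimate it); this is a documented limitation.
"""

from __future__ import annotations

import math

from .estimate import EffectEstimate, InputError


def lnvr_from_moments(sd1, sd2, n1, n2, route: str = "means_sd") -> EffectEstimate:
    """Variability ratio:
    lnVR = ln(sd1/sd2) + 1/(2(n1-1)) - 1/(2(n2-1)),
    Var  = 1/(2(n1-1)) + 1/(2(n2-1))."""
    if sd1 <= 0 or sd2 <= 0:
        raise InputError("SDs must be strictly positive")
    if min(n1, n2) < 2:
        raise InputError("each group needs n >= 2")
    lnvr = math.log(sd1 / sd2) + 1 / (2 * (n1 - 1)) - 1 / (2 * (n2 - 1))
    se = math.sqrt(1 / (2 * (n1 - 1)) + 1 / (2 * (n2 - 1)))
    return EffectEstimate.from_transform("VR", lnvr, se, route)


def lncvr_from_moments(m1, sd1, m2, sd2, n1, n2, route: str = "means_sd") -> EffectEstimate:
    """Coefficient-of-variation ratio:
    lnCVR = ln((sd1/m1)/(sd2/m2)) + 1/(2(n1-1)) - 1/(2(n2-1)),
    Var   = sd1^2/(n1 m1^2) + 1/(2(n1-1)) + sd2^2/(n2 m2^2) + 1/(2(n2-1))."""
    if m1 <= 0 or m2 <= 0:
        raise InputError(
            "CVR requires ratio-scale data: both group means must be "
            "strictly positive"
        )
    if sd1 <= 0 or sd2 <= 0:
        raise InputError("SDs must be strictly positive")
    if min(n1, n2) < 2:
        raise InputError("each group needs n >= 2")
    lncvr = (
        math.log((sd1 / m1) / (sd2 / m2))
        + 1 / (2 * (n1 - 1))
        - 1 / (2 * (n2 - 1))
    )
    var = (
        sd1**2 / (n1 * m1**2)
        + 1 / (2 * (n1 - 1))
        + sd2**2 / (n2 * m2**2)
        + 1 / (2 * (n2 - 1))
    )
    return EffectEstimate.from_transform("CVR", lncvr, math.sqrt(var), route)
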