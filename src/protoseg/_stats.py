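"""Shared small statistics helpers (odds ratios with confidence intervals)."""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class OddsRatio:
    """Odds ratio of a 2x2 table [[a, b], [c, d]] with a Woolf (log-OR
    normal approximation) confidence interval.

    ``corrected`` is True when the Haldane-Anscombe +0.5 adjustment was
    applied (some cell was zero); ``defined`` is False when a margin is
    empty and no finite estimate is meaningful.
    """

    a: int
    b: int
    c: int
    d: int
    value: float
    ci_low: float
    ci_high: float
    corrected: bool
    defined: bool


_Z_CACHE: dict[float, float] = {}


def _z_for(ci_level: float) -> float:
    if ci_level not in _Z_CACHE:
        from scipy import stats

        _Z_CACHE[ci_level] = float(stats.norm.ppf(0.5 + ci_level / 2))
    return _Z_CACHE[ci_level]


def odds_ratio(a: int, b: int, c: int, d: int, ci_level: float = 0.95) -> OddsRatio:
    """OR = (a*d)/(b*c) with Woolf CI; Haldane-Anscombe 0.5 correction when
    any cell is zero.  A table with an empty margin (e.g. no selected
    participants at all) is flagged undefined rather than returned as 0."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return OddsRatio(a, b, c, d, math.nan, math.nan, math.nan, False, False)
    corrected = min(a, b, c, d) == 0
    if corrected:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    est = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = _z_for(ci_level)
    log_est = math.log(est)
    return OddsRatio(
        a,
        b,
        c,
        d,
        est,
        math.exp(log_est - z * se),
        math.exp(log_est + z * se),
        corrected,
        True,
    )
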