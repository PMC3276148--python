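"""Unit conversions between coalescent-scaled parameters and natural units.

theta = 4 Ne mu(per generation); with a per-year mutation rate mu and a
generation time g in years, mu*g is the per-generation rate, so
Ne = theta / (4 mu g).  Coalescent times in units of 4 Ne generations
convert to years as t * 4 Ne * g (per-year mutation rate makes split times
in years independent of g).
"""

from __future__ import annotations

import math


def round_sig(x: float, digits: int = 2) -> float:
    """Round to the given number of significant figures (reporting helper)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, digits - 1 - exponent)


def effective_size(theta_per_site: float, mu_per_year: float, g_years: float) -> float:
    """Ne = theta / (4 mu g)."""
    if theta_per_site <= 0 or mu_per_year <= 0 or g_years <= 0:
        raise ValueError("all inputs must be > 0")
    return theta_per_site / (4.0 * mu_per_year * g_years)


def split_time_years(t_s: float, Ne: float, g_years: float) -> float:
    """Convert a split time in 4*Ne-generation units to years."""
    if Ne <= 0 or g_years <= 0:
        raise ValueError("Ne and g must be > 0")
    if t_s < 0:
        raise ValueError("t_s must be >= 0")
    return t_s * 4.0 * Ne * g_years
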