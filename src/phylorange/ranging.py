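"""The DD:AD itinerancy statistic.

Wide-ranging Carnivora do not sweep their whole annual home range (AHR)
daily; itinerant ("semi-nomadic") species occupy small sub-regions at a
time and relocate through the year.  DD:AD quantifies this as the ratio of
median daily travel distance (DD, km/day) to a conservative estimate of
minimum annual travel distance (AD, km): the circumference of the circle
whose area equals the AHR.  Treating every species' range as a circle makes
the estimate comparable across species, and the ratio is dimensionless —
rescaling both inputs consistently (dd -> k*dd, ahr -> k^2*ahr) leaves it
unchanged.  Small DD:AD marks an itinerant species (polar bear ~ 0.04-0.1),
large DD:AD a sedentary one (red fox ~ 1.2).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = ["annual_travel_distance", "ddad_ratio", "annotate_table"]


def annual_travel_distance(ahr_km2: float) -> float:
    """Minimum annual travel distance: circumference of a circle of area ``ahr_km2``.

    AD = 2 * sqrt(pi * AHR).  A zero home range gives AD = 0.
    """
    if ahr_km2 < 0:
        raise ValueError(f"home-range area must be nonnegative, got {ahr_km2}")
    return 2.0 * math.sqrt(math.pi * ahr_km2)


def ddad_ratio(dd_km: float, ahr_km2: float) -> float:
    """DD:AD = daily travel distance / annual travel distance.

    Returns NaN (with a warning) when ``ahr_km2`` is zero, where the ratio
    is undefined.
    """
    if dd_km < 0:
        raise ValueError(f"daily distance must be nonnegative, got {dd_km}")
    ad = annual_travel_distance(ahr_km2)
    if ad == 0.0:
        warnings.warn("zero home-range area: DD:AD undefined, returning NaN", stacklevel=2)
        return math.nan
    return dd_km / ad


def annotate_table(
    table: pd.DataFrame,
    dd_col: str = "dd_km",
    ahr_col: str = "ahr_km2",
    ad_col: str = "ad_km",
    ddad_col: str = "ddad",
) -> pd.DataFrame:
    """Return a copy of ``table`` with derived ``ad_km`` and ``ddad`` columns.

    Rows missing either input get a missing DD:AD; rows with a zero home
    range get a missing DD:AD but a zero AD.
    """
    missing = [c for c in (dd_col, ahr_col) if c not in table.columns]
    if missing:
        raise KeyError(f"columns not found in trait table: {missing}")
    out = table.copy()
    ahr = out[ahr_col].astype(float)
    dd = out[dd_col].astype(float)
    if (ahr.dropna() < 0).any() or (dd.dropna() < 0).any():
        raise ValueError("negative DD or AHR values in trait table")
    ad = 2.0 * np.sqrt(np.pi * ahr)
    with np.errstate(divide="ignore", invalid="ignore"):
        ddad = dd / ad
    ddad = ddad.where(ad > 0)
    out[ad_col] = ad
    out[ddad_col] = ddad
    return out
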