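"""Latitude-corrected cell areas and the area distribution of the sea floor.

The area of a lat/lon raster cell on a spherical Earth is
``R^2 * dlambda * (sin(phi_upper) - sin(phi_lower))`` with R = 6371 km; the
spherical approximation errs by <0.4% and cancels entirely in area
*fractions*.  Zone and stratum area fractions are the hypsometry of the
grid: how much sea-floor area lies at each bottom depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import BathymetryGrid
from .zones import DEFAULT_ZONES, DepthZone, zone_index_of_depth

__all__ = [
    "EARTH_RADIUS_KM",
    "cell_areas",
    "zone_area_fractions",
    "stratum_area_fractions",
    "stratum_fractions_from_zones",
]

EARTH_RADIUS_KM = 6371.0


def cell_areas(bathy: BathymetryGrid) -> np.ndarray:
    """Area of every grid cell in km^2 (shape (n_lat, n_lon), mask ignored)."""
    phi = np.deg2rad(bathy.lat_edges)
    dlam = np.deg2rad(np.diff(bathy.lon_edges))
    band = EARTH_RADIUS_KM**2 * np.diff(np.sin(phi))  # per-latitude-band factor
    return np.outer(band, dlam)


def zone_area_fractions(
    bathy: BathymetryGrid, zones: tuple[DepthZone, ...] = DEFAULT_ZONES
) -> pd.DataFrame:
    """Percent of ocean area in each depth zone, with the cumulative column.

    Only unmasked (ocean) cells contribute.  Raises on an all-land grid.
    """
    areas = cell_areas(bathy)
    ocean = ~bathy.mask
    total = areas[ocean].sum()
    if not total > 0:
        raise ValueError("grid has no ocean cells")
    idx = zone_index_of_depth(bathy.depth[ocean], zones)
    frac = np.bincount(idx, weights=areas[ocean], minlength=len(zones)) / total
    pct = 100.0 * frac
    return pd.DataFrame(
        {
            "label": [z.label for z in zones],
            "name": [z.name for z in zones],
            "lower_m": [z.lower for z in zones],
            "upper_m": [z.upper for z in zones],
            "area_fraction_pct": pct,
            "cumulative_pct": np.cumsum(pct),
        }
    )


def stratum_area_fractions(bathy: BathymetryGrid, scheme) -> np.ndarray:
    """Ocean-area fraction whose bottom depth falls in each stratum.

    Fractions sum to 1.  Raises if any ocean depth exceeds the scheme's
    coverage.
    """
    areas = cell_areas(bathy)
    ocean = ~bathy.mask
    total = areas[ocean].sum()
    if not total > 0:
        raise ValueError("grid has no ocean cells")
    idx = scheme.assign(bathy.depth[ocean])
    return np.bincount(idx, weights=areas[ocean], minlength=scheme.n_strata) / total


def stratum_fractions_from_zones(
    zone_fractions: dict[str, float],
    scheme,
    zones: tuple[DepthZone, ...] = DEFAULT_ZONES,
) -> np.ndarray:
    """Spread zone area fractions uniformly (per metre of depth) over the
    scheme's strata — a fallback when the grid is coarser than the strata.

    The deepest zone's unbounded interval is truncated at the scheme's
    maximum depth for the per-metre spread.
    """
    fracs = np.array([zone_fractions[z.label] for z in zones], dtype=float)
    if not np.isclose(fracs.sum(), 1.0, atol=1e-9):
        raise ValueError("zone fractions must sum to 1")
    # zone of each stratum, by its upper bound under (lower, upper]
    zidx = zone_index_of_depth(scheme.uppers, zones)
    out = np.empty(scheme.n_strata)
    for k, z in enumerate(zones):
        members = zidx == k
        if not members.any():
            continue
        zone_top = min(z.upper, scheme.max_depth)
        widths = scheme.widths[members]
        out[members] = fracs[k] * widths / (zone_top - z.lower)
    return out
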