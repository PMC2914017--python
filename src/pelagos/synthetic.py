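"""Synthetic bathymetry and depth-biased occurrence records.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without external downloads:

* a bathymetry grid whose hypsometry (area share per depth zone) matches
  configurable targets, defaulting to the global-ocean shares;
* occurrence records whose horizontal placement is area-weighted with a
  shallow sampling-effort bias, and whose sample depths follow a
  three-component vertical mixture — a surface-attached exponential, a
  seabed-attached exponential, and a uniform midwater component — modelling
  the empirical concentration of sampling at the surface and on the sea bed;
* injected data anomalies: negative depths and records whose recorded sample
  depth exceeds the bottom depth.

The mixture admits a closed-form midwater fraction
(:func:`expected_midwater_fraction`), which serves as the analytic oracle
for parameter-recovery tests.  All randomness flows from one seed through a
named :class:`numpy.random.Generator`; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypsometry import cell_areas
from .io import BathymetryGrid
from .midwater import DEFAULT_MIDWATER_RULE, MidwaterRule
from .zones import DEFAULT_ZONES, GLOBAL_ZONE_AREA_FRACTIONS, DepthZone

__all__ = [
    "VerticalMixture",
    "DEFAULT_MIXTURE",
    "AnomalySpec",
    "NO_ANOMALIES",
    "DEFAULT_ANOMALIES",
    "HADAL_CAP_M",
    "DEFAULT_EFFORT_SCALE_M",
    "generate_bathymetry",
    "generate_occurrences",
    "expected_midwater_fraction",
]

#: Deepest representable sea floor (m); the deepest trenches approach 11 km.
HADAL_CAP_M = 11000.0

#: e-folding scale (m) of the default sampling-effort decline with bottom
#: depth.  Effort exp(-bottom/1000 m) on top of area weighting puts over
#: half of the records on the shelf and a few percent on the abyssal plain —
#: the depth bias characteristic of global occurrence databases.
DEFAULT_EFFORT_SCALE_M = 1000.0


@dataclass(frozen=True)
class VerticalMixture:
    """Three-component model of where in the water column samples are taken.

    With probability ``pi_surface`` the sample depth is exponential with
    mean ``surface_scale`` below the surface; with ``pi_seabed`` it is
    exponential with mean ``seabed_scale`` above the sea bed; with ``pi_mid``
    it is uniform through the column.  Each component is truncated to
    [0, bottom depth].
    """

    pi_surface: float
    pi_seabed: float
    pi_mid: float
    surface_scale: float
    seabed_scale: float

    def __post_init__(self) -> None:
        pis = (self.pi_surface, self.pi_seabed, self.pi_mid)
        if any(p < 0 or p > 1 for p in pis):
            raise ValueError("mixture weights must lie in [0, 1]")
        if abs(sum(pis) - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if self.surface_scale <= 0 or self.seabed_scale <= 0:
            raise ValueError("exponential scales must be positive")


DEFAULT_MIXTURE = VerticalMixture(
    pi_surface=0.55, pi_seabed=0.35, pi_mid=0.10, surface_scale=10.0, seabed_scale=20.0
)


@dataclass(frozen=True)
class AnomalySpec:
    """Data anomalies to inject into generated records.

    ``n_negative_sample`` / ``n_negative_bottom`` records get a negative
    sample / bottom depth (replacing the drawn value, on disjoint record
    sets); then a ``frac_exceed`` share of the untouched records has its
    sample depth pushed below the sea bed by up to ``exceed_offset`` m.
    """

    n_negative_sample: int = 0
    n_negative_bottom: int = 0
    frac_exceed: float = 0.0
    exceed_offset: float = 20.0

    def __post_init__(self) -> None:
        if self.n_negative_sample < 0 or self.n_negative_bottom < 0:
            raise ValueError("anomaly counts must be >= 0")
        if not 0.0 <= self.frac_exceed <= 1.0:
            raise ValueError("frac_exceed must lie in [0, 1]")
        if self.exceed_offset <= 0:
            raise ValueError("exceed_offset must be positive")


NO_ANOMALIES = AnomalySpec()

#: Anomaly load of a typical global occurrence extract: a handful of negative
#: depths and ~7% of records with sample depth exceeding the gridded bottom
#: depth, generally by <= 20 m.
DEFAULT_ANOMALIES = AnomalySpec(
    n_negative_sample=14, n_negative_bottom=1, frac_exceed=0.07, exceed_offset=20.0
)


def generate_bathymetry(
    n_lat: int,
    n_lon: int,
    zone_fractions: dict[str, float] | None = None,
    seed: int = 0,
    zones: tuple[DepthZone, ...] = DEFAULT_ZONES,
) -> BathymetryGrid:
    """A global grid of sea-floor depths matching target zone-area shares.

    Cells (weighted by their true spherical area) are assigned to zones so
    that each zone's area fraction matches ``zone_fractions`` (default: the
    global-ocean shares) to within one cell's area; within a zone, depth is
    uniform over the zone's interval, with the unbounded deepest zone capped
    at 11000 m.  Deterministic for a fixed seed.
    """
    if n_lat < 2 or n_lon < 2:
        raise ValueError("grid must be at least 2 x 2")
    fractions = dict(GLOBAL_ZONE_AREA_FRACTIONS if zone_fractions is None else zone_fractions)
    fracs = np.array([fractions[z.label] for z in zones], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("zone fractions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    grid = BathymetryGrid.global_grid(n_lat, n_lon, np.zeros((n_lat, n_lon)))
    areas = cell_areas(grid).ravel()
    order = rng.permutation(areas.size)
    cum_area = np.cumsum(areas[order]) / areas.sum()
    cum_target = np.cumsum(fracs)

    # walk cells in random order, switching zone when the running area share
    # passes the zone's cumulative target
    zone_of_cell = np.searchsorted(cum_target, cum_area - areas[order] / (2 * areas.sum()))
    zone_of_cell = np.minimum(zone_of_cell, len(zones) - 1)
    got = np.bincount(zone_of_cell, minlength=len(zones))
    for k, z in enumerate(zones):
        if fracs[k] > 0 and got[k] == 0:
            raise ValueError(
                f"grid too small to realize zone {z.label} "
                f"(target fraction {fracs[k]:g})"
            )

    depth = np.empty(areas.size)
    uppers = np.array([min(z.upper, HADAL_CAP_M) for z in zones])
    lowers = np.array([z.lower for z in zones])
    depth[order] = lowers[zone_of_cell] + rng.random(areas.size) * (
        uppers[zone_of_cell] - lowers[zone_of_cell]
    )
    return BathymetryGrid.global_grid(n_lat, n_lon, depth.reshape(n_lat, n_lon))


def _truncated_exponential(rng, scale: float, upper: np.ndarray) -> np.ndarray:
    """Draws from Exp(scale) truncated to [0, upper], via inverse CDF."""
    u = rng.random(upper.shape)
    return -scale * np.log1p(-u * -np.expm1(-upper / scale))


def generate_occurrences(
    n_records: int,
    bathy: BathymetryGrid,
    mix: VerticalMixture = DEFAULT_MIXTURE,
    anomalies: AnomalySpec = NO_ANOMALIES,
    seed: int = 0,
    effort_scale: float | None = DEFAULT_EFFORT_SCALE_M,
) -> pd.DataFrame:
    """Synthetic occurrence records over a bathymetry grid.

    Horizontal placement picks a grid cell with probability proportional to
    cell area times a sampling-effort factor ``exp(-bottom/effort_scale)``
    (``effort_scale=None`` disables the bias, leaving pure area weighting),
    then a uniform position within the cell.  Sample depth is drawn from the
    vertical mixture truncated to the local water column, anomalies are
    injected afterwards, and the true component label is retained in a
    ``true_component`` column (``anomaly`` flags injected rows) for
    recovery tests.  Deterministic for a fixed seed.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    ocean = ~bathy.mask
    if not ocean.any():
        raise ValueError("bathymetry has no ocean cells")
    if anomalies.n_negative_sample + anomalies.n_negative_bottom > n_records:
        raise ValueError("more negative-depth anomalies requested than records")

    rng = np.random.default_rng(seed)
    areas = cell_areas(bathy)
    weights = np.where(ocean, areas, 0.0).ravel()
    if effort_scale is not None:
        weights = weights * np.exp(
            -np.where(ocean, bathy.depth, 0.0).ravel() / effort_scale
        )
    cells = rng.choice(weights.size, size=n_records, p=weights / weights.sum())
    i, j = np.unravel_index(cells, bathy.depth.shape)
    lat = bathy.lat_edges[i] + rng.random(n_records) * np.diff(bathy.lat_edges)[i]
    lon = bathy.lon_edges[j] + rng.random(n_records) * np.diff(bathy.lon_edges)[j]
    bottom = bathy.depth[i, j]

    component = rng.choice(
        3, size=n_records, p=[mix.pi_surface, mix.pi_seabed, mix.pi_mid]
    )
    sample = np.empty(n_records)
    surf = component == 0
    bed = component == 1
    mid = component == 2
    sample[surf] = _truncated_exponential(rng, mix.surface_scale, bottom[surf])
    sample[bed] = bottom[bed] - _truncated_exponential(rng, mix.seabed_scale, bottom[bed])
    sample[mid] = rng.random(mid.sum()) * bottom[mid]

    labels = np.array(["surface", "seabed", "midwater"])[component]
    anomaly = np.full(n_records, "", dtype=object)

    n_neg = anomalies.n_negative_sample + anomalies.n_negative_bottom
    if n_neg or anomalies.frac_exceed:
        touched = rng.choice(n_records, size=n_neg, replace=False) if n_neg else np.array([], int)
        neg_s = touched[: anomalies.n_negative_sample]
        neg_b = touched[anomalies.n_negative_sample :]
        sample[neg_s] = -rng.uniform(0.1, 10.0, size=neg_s.size)
        bottom = bottom.copy()
        bottom[neg_b] = -rng.uniform(0.1, 10.0, size=neg_b.size)
        anomaly[neg_s] = "negative_sample"
        anomaly[neg_b] = "negative_bottom"

        n_exceed = round(anomalies.frac_exceed * n_records)
        untouched = np.setdiff1d(np.arange(n_records), touched)
        if n_exceed > untouched.size:
            raise ValueError("frac_exceed too large given negative-depth anomalies")
        exc = rng.choice(untouched, size=n_exceed, replace=False)
        # offset in (0, exceed_offset] so the exceedance is strict
        sample[exc] = bottom[exc] + anomalies.exceed_offset * (1.0 - rng.random(exc.size))
        anomaly[exc] = "exceed"

    return pd.DataFrame(
        {
            "latitude": lat,
            "longitude": lon,
            "sample_depth": sample,
            "bottom_depth": bottom,
            "true_component": labels,
            "anomaly": anomaly,
        }
    )


def _trunc_exp_cdf(x: float, scale: float, upper: float) -> float:
    """CDF at x of Exp(scale) truncated to [0, upper]."""
    x = min(max(x, 0.0), upper)
    return np.expm1(-x / scale) / np.expm1(-upper / scale)


def expected_midwater_fraction(
    mix: VerticalMixture,
    bottom_depth: float,
    rule: MidwaterRule = DEFAULT_MIDWATER_RULE,
) -> float:
    """Exact probability that a mixture draw at this bottom depth is midwater.

    Closed form: truncated-exponential CDF differences over the open band
    (surface_exclusion, bottom - seabed_exclusion) for the two attached
    components, plus the band's share of the column for the uniform
    component.  Returns 0 when the exclusion bands leave no midwater.
    """
    if bottom_depth <= 0:
        raise ValueError("bottom_depth must be positive")
    surf_ex, bed_ex = rule.bands(bottom_depth)
    lo, hi = float(surf_ex), bottom_depth - float(bed_ex)
    if hi <= lo:
        return 0.0
    b = bottom_depth
    p_surface = _trunc_exp_cdf(hi, mix.surface_scale, b) - _trunc_exp_cdf(
        lo, mix.surface_scale, b
    )
    # seabed offset Y = bottom - depth: depth in (lo, hi) iff Y in (bed_ex, b - lo)
    p_seabed = _trunc_exp_cdf(b - lo, mix.seabed_scale, b) - _trunc_exp_cdf(
        float(bed_ex), mix.seabed_scale, b
    )
    p_mid = (hi - lo) / b
    return mix.pi_surface * p_surface + mix.pi_seabed * p_seabed + mix.pi_mid * p_mid
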