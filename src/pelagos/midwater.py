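"""Midwater classification and the bottom-depth vs midwater-proportion test.

"Midwater" is the water column away from its two well-sampled margins: a
surface band and a seabed band, whose thicknesses depend on the bottom-depth
zone.  On the shelf (bottom <= 200 m) the bands are 10 m each; in deeper
zones the surface band is 100 m and the seabed band 100 m (mesopelagic),
200 m (bathypelagic and abyssal) or 1000 m (hadal).  A record is midwater
iff its sample depth lies strictly inside the remaining open band.

Per-bottom-stratum midwater proportions, computed on the fine (10 m shelf)
strata, feed a Spearman rank correlation of proportion against bottom depth.
The two shallowest fine strata (0-10 and 10-20 m) admit no midwater at all
under the shelf bands and are excluded.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .depthmatrix import StrataScheme
from .zones import DEFAULT_ZONES, DepthZone, zone_index_of_depth

logger = logging.getLogger(__name__)

__all__ = [
    "MidwaterRule",
    "DEFAULT_MIDWATER_RULE",
    "is_midwater",
    "midwater_by_stratum",
    "RankCorrelation",
    "rank_correlation",
    "zone_summaries",
    "MidwaterSummary",
    "summarize_midwater",
]


@dataclass(frozen=True)
class MidwaterRule:
    """Per-zone (surface exclusion, seabed exclusion) band thicknesses, m."""

    exclusions: tuple[tuple[float, float], ...]
    zones: tuple[DepthZone, ...] = DEFAULT_ZONES

    def __post_init__(self) -> None:
        if len(self.exclusions) != len(self.zones):
            raise ValueError("one (surface, seabed) pair per zone required")
        for s, e in self.exclusions:
            if s <= 0 or e <= 0:
                raise ValueError("exclusion bands must be positive")

    def bands(self, bottom_depth):
        """(surface_exclusion, seabed_exclusion) for each bottom depth."""
        zidx = zone_index_of_depth(bottom_depth, self.zones)
        surf = np.array([s for s, _ in self.exclusions])[zidx]
        bed = np.array([e for _, e in self.exclusions])[zidx]
        return surf, bed


DEFAULT_MIDWATER_RULE = MidwaterRule(
    exclusions=(
        (10.0, 10.0),    # A: continental shelf
        (100.0, 100.0),  # B: mesopelagic slope
        (100.0, 200.0),  # C: bathypelagic slope
        (100.0, 200.0),  # D: abyssal plain
        (100.0, 1000.0), # E: hadal
    )
)


def is_midwater(sample_depth, bottom_depth, rule: MidwaterRule = DEFAULT_MIDWATER_RULE):
    """True where the sample lies strictly inside the midwater band.

    The band for a record with bottom depth B in a zone with exclusions
    (s, e) is the open interval (s, B - e); if B <= s + e there is no
    midwater at that bottom depth.
    """
    sample = np.asarray(sample_depth, dtype=float)
    bottom = np.asarray(bottom_depth, dtype=float)
    surf, bed = rule.bands(bottom)
    out = (sample > surf) & (sample < bottom - bed)
    return out if out.ndim else bool(out)


def midwater_by_stratum(
    records: pd.DataFrame,
    scheme: StrataScheme,
    rule: MidwaterRule = DEFAULT_MIDWATER_RULE,
) -> pd.DataFrame:
    """Midwater proportion of records in each bottom-depth stratum.

    Strata that cannot contain midwater under the rule — those whose upper
    bound does not exceed their zone's combined exclusion bands (the 0-10 m
    and 10-20 m fine strata) — are flagged ``excluded`` and carry no
    proportion.  Empty strata keep a NaN proportion; their count is logged
    since they drop out of the correlation sample.
    """
    sch = scheme
    b = sch.assign(records["bottom_depth"].to_numpy(dtype=float))
    mid = is_midwater(
        records["sample_depth"].to_numpy(dtype=float),
        records["bottom_depth"].to_numpy(dtype=float),
        rule,
    )
    total = np.bincount(b, minlength=sch.n_strata)
    n_mid = np.bincount(b, weights=mid.astype(float), minlength=sch.n_strata).astype(int)

    surf, bed = rule.bands(sch.uppers)
    excluded = sch.uppers <= surf + bed
    with np.errstate(invalid="ignore"):
        prop = np.where(~excluded & (total > 0), n_mid / np.maximum(total, 1), np.nan)

    n_empty = int((~excluded & (total == 0)).sum())
    if n_empty:
        logger.info("midwater_by_stratum: %d strata have no records", n_empty)
    return pd.DataFrame(
        {
            "lower": sch.lowers,
            "upper": sch.uppers,
            "midpoint": sch.midpoints,
            "n_records": total,
            "n_midwater": n_mid,
            "proportion": prop,
            "excluded": excluded,
        }
    )


@dataclass(frozen=True)
class RankCorrelation:
    rho: float
    df: int
    p_value: float
    n: int


def rank_correlation(
    depths, proportions, method: str = "asymptotic"
) -> RankCorrelation:
    """Spearman rank correlation of midwater proportion against depth.

    Average ranks are used for ties and the two-sided p-value comes from the
    t approximation (``method="exact"`` enumerates all permutations, only
    feasible for n <= 10).  Degrees of freedom are n - 2.  If either
    variable is constant the correlation is undefined and rho is NaN.
    """
    x = np.asarray(depths, dtype=float)
    y = np.asarray(proportions, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 strata with defined proportions")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("rank_correlation: constant input, rho undefined")
        return RankCorrelation(rho=float("nan"), df=n - 2, p_value=float("nan"), n=n)
    if method == "asymptotic":
        res = stats.spearmanr(x, y)
        return RankCorrelation(rho=float(res.statistic), df=n - 2, p_value=float(res.pvalue), n=n)
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        rho_obs = float(stats.spearmanr(x, y).statistic)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx = rx - rx.mean()
        denom = math.sqrt((rx**2).sum())
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            yp = ry[list(perm)] - ry.mean()
            r = float(rx @ yp) / (denom * math.sqrt((yp**2).sum()))
            hits += abs(r) >= abs(rho_obs) - 1e-12
            total += 1
        return RankCorrelation(rho=rho_obs, df=n - 2, p_value=hits / total, n=n)
    raise ValueError(f"unknown method {method!r}")


def zone_summaries(
    stratum_table: pd.DataFrame, zones: tuple[DepthZone, ...] = DEFAULT_ZONES
) -> pd.DataFrame:
    """Median, interquartile range and total range of stratum midwater
    proportions within each zone (excluded and empty strata dropped).

    A zone with no contributing strata is absent from the result (logged).
    """
    tab = stratum_table.loc[
        ~stratum_table["excluded"] & stratum_table["proportion"].notna()
    ].copy()
    tab["zone"] = [zones[k].label for k in zone_index_of_depth(tab["upper"].to_numpy(), zones)]
    rows = []
    for z in zones:
        sub = tab.loc[tab["zone"] == z.label, "proportion"]
        if sub.empty:
            logger.info("zone_summaries: zone %s has no contributing strata", z.label)
            continue
        rows.append(
            {
                "zone": z.label,
                "name": z.name,
                "n_strata": len(sub),
                "median": sub.median(),
                "q1": sub.quantile(0.25),
                "q3": sub.quantile(0.75),
                "min": sub.min(),
                "max": sub.max(),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MidwaterSummary:
    """Per-stratum proportions, per-zone order statistics and the rank test."""

    strata: pd.DataFrame
    zones: pd.DataFrame
    correlation: RankCorrelation


def summarize_midwater(
    records: pd.DataFrame,
    scheme: StrataScheme,
    rule: MidwaterRule = DEFAULT_MIDWATER_RULE,
) -> MidwaterSummary:
    """Full midwater analysis: stratum proportions, zone summaries and the
    Spearman correlation of proportion against stratum midpoint depth."""
    strata = midwater_by_stratum(records, scheme, rule)
    contributing = ~strata["excluded"] & strata["proportion"].notna()
    corr = rank_correlation(
        strata.loc[contributing, "midpoint"], strata.loc[contributing, "proportion"]
    )
    return MidwaterSummary(
        strata=strata, zones=zone_summaries(strata), correlation=corr
    )
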