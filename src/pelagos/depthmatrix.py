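"""Variable-resolution depth strata and the bottom x sample depth matrix.

The water column is tiled with strata whose thickness coarsens with depth:
the default scheme uses 50 m strata to 200 m, 100 m to 1000 m, 200 m to
6000 m and 1000 m strata below, covering to 11000 m — 42 strata in all.  A
fine variant subdivides the top 200 m into 10 m strata (58 strata) for
shelf-scale analyses.  Strata are half-open ``(lower, upper]`` intervals,
closed at 0, so a 200 m sample belongs to the 150-200 m stratum.

Occurrence records are binned into the matrix of bottom stratum x sample
stratum; only cells with sample stratum <= bottom stratum exist (a sample
cannot lie below the sea floor), giving n(n+1)/2 valid cells — 903 under the
default scheme.  Because a stratum over the abyssal plain spans far more
ocean than the same stratum over the shelf, raw counts are standardized by
each cell's relative water volume (bottom-stratum area fraction x sample-
stratum thickness) before log10 transformation; a per-column re-calibration
to proportions shows the vertical distribution of records independently of
how many there are at each bottom depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BREAKPOINTS",
    "FINE_BREAKPOINTS",
    "StrataScheme",
    "build_scheme",
    "DepthMatrix",
    "build_matrix",
]

#: (segment upper bound m, stratum thickness m); segments tile (0, 11000].
DEFAULT_BREAKPOINTS = ((200.0, 50.0), (1000.0, 100.0), (6000.0, 200.0), (11000.0, 1000.0))
#: 10 m shelf strata for analyses of the shelf and mesopelagic slope.
FINE_BREAKPOINTS = ((200.0, 10.0), (1000.0, 100.0), (6000.0, 200.0), (11000.0, 1000.0))


@dataclass(frozen=True)
class StrataScheme:
    """An ordered tiling of (0, max_depth] by contiguous depth strata."""

    breakpoints: tuple[tuple[float, float], ...]
    lowers: np.ndarray = field(repr=False)
    uppers: np.ndarray = field(repr=False)

    @property
    def n_strata(self) -> int:
        return self.uppers.size

    @property
    def max_depth(self) -> float:
        return float(self.uppers[-1])

    @property
    def widths(self) -> np.ndarray:
        return self.uppers - self.lowers

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.lowers + self.uppers)

    @property
    def n_valid_cells(self) -> int:
        """Number of (bottom, sample) cells with sample stratum <= bottom."""
        n = self.n_strata
        return n * (n + 1) // 2

    def assign(self, depth):
        """Stratum index of each depth under (lower, upper] membership;
        depth 0 goes to the first stratum.  Raises outside [0, max_depth]."""
        d = np.asarray(depth, dtype=float)
        if np.any(d < 0) or np.any(d > self.max_depth):
            raise ValueError(f"depth outside scheme coverage [0, {self.max_depth}]")
        idx = np.searchsorted(self.uppers, d, side="left")
        return idx if d.ndim else int(idx)


def build_scheme(breakpoints=DEFAULT_BREAKPOINTS) -> StrataScheme:
    """Derive the strata from (upper bound, resolution) segments.

    Segment bounds must ascend from 0 and each resolution must divide its
    segment's span exactly.
    """
    edges = [0.0]
    prev = 0.0
    for upper, res in breakpoints:
        if upper <= prev:
            raise ValueError(f"segment bounds must ascend: {upper} after {prev}")
        if res <= 0:
            raise ValueError("resolution must be positive")
        n = (upper - prev) / res
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"resolution {res} m does not divide segment ({prev}, {upper}] m"
            )
        edges.extend(prev + res * np.arange(1, round(n) + 1))
        edges[-1] = upper  # guard against float accumulation
        prev = upper
    edges = np.asarray(edges, dtype=float)
    return StrataScheme(
        breakpoints=tuple((float(u), float(r)) for u, r in breakpoints),
        lowers=edges[:-1],
        uppers=edges[1:],
    )


@dataclass
class DepthMatrix:
    """Counts and derived fields on the bottom x sample stratum grid.

    Arrays are (n_strata, n_strata), indexed ``[sample_stratum,
    bottom_stratum]`` so that each *column* is one bottom depth.  Cells with
    sample stratum > bottom stratum are structurally absent (``valid`` is
    False there; derived arrays hold NaN).  ``log_density`` is NaN — an
    explicit empty flag, not -inf — wherever the count is zero, and
    ``column_proportions`` is NaN throughout empty columns.
    """

    scheme: StrataScheme
    counts: np.ndarray
    volumes: np.ndarray
    density: np.ndarray
    log_density: np.ndarray
    column_proportions: np.ndarray
    valid: np.ndarray

    @property
    def n_records(self) -> int:
        return int(self.counts[self.valid].sum())

    @property
    def n_valid_cells(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table over the valid cells."""
        s_idx, b_idx = np.nonzero(self.valid)
        sch = self.scheme
        return pd.DataFrame(
            {
                "bottom_lower": sch.lowers[b_idx],
                "bottom_upper": sch.uppers[b_idx],
                "sample_lower": sch.lowers[s_idx],
                "sample_upper": sch.uppers[s_idx],
                "count": self.counts[s_idx, b_idx],
                "volume": self.volumes[s_idx, b_idx],
                "density": self.density[s_idx, b_idx],
                "log_density": self.log_density[s_idx, b_idx],
                "column_proportion": self.column_proportions[s_idx, b_idx],
            }
        )


def build_matrix(
    records: pd.DataFrame, scheme: StrataScheme, strat_areas: np.ndarray
) -> DepthMatrix:
    """Bin cleaned records and standardize by relative cell volume.

    ``strat_areas`` are the per-bottom-stratum ocean-area fractions (from
    :func:`pelagos.hypsometry.stratum_area_fractions`, or the uniform-
    within-zone fallback).  A cell's relative volume is that area fraction
    times the sample stratum's thickness; density = count / volume.
    Records must already satisfy sample <= bottom (run cleaning first); a
    record deeper than the scheme's coverage raises.
    """
    strat_areas = np.asarray(strat_areas, dtype=float)
    if strat_areas.shape != (scheme.n_strata,):
        raise ValueError("strat_areas must have one entry per stratum")
    n = scheme.n_strata
    b = scheme.assign(records["bottom_depth"].to_numpy(dtype=float))
    s = scheme.assign(records["sample_depth"].to_numpy(dtype=float))
    if np.any(s > np.asarray(b)):
        raise ValueError("records with sample below bottom present: clean first")

    valid = np.triu(np.ones((n, n), dtype=bool))  # sample index <= bottom index
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (s, b), 1)

    volumes = np.where(valid, np.outer(scheme.widths, strat_areas), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(valid, counts / volumes, np.nan)
        log_density = np.where(valid & (counts > 0), np.log10(density), np.nan)
        colsum = counts.sum(axis=0, where=valid, keepdims=True)
        column_proportions = np.where(valid & (colsum > 0), counts / colsum, np.nan)
    return DepthMatrix(
        scheme=scheme,
        counts=np.where(valid, counts, 0),
        volumes=volumes,
        density=density,
        log_density=log_density,
        column_proportions=column_proportions,
        valid=valid,
    )
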