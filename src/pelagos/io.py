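"""Reading and writing occurrence records and bathymetry grids.

Occurrence records live in a plain :class:`pandas.DataFrame` with canonical
columns ``latitude``, ``longitude``, ``sample_depth`` and, once the sea floor
has been looked up, ``bottom_depth`` (all depths in metres, positive down).
Bathymetry is a regular latitude/longitude raster of sea-floor depth.

Supported grid formats are netCDF (via xarray) and ESRI ASCII grids; both
round-trip losslessly.  Grid cells are half-open ``[edge_i, edge_{i+1})`` in
both axes, with a coordinate exactly on the global upper edge assigned to the
last cell, and records are matched to the *cell* containing their coordinate
(nearest-cell, no interpolation): gridded bottom depth is a cell average, not
a continuous surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "RECORD_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "BathymetryGrid",
    "read_records",
    "write_records",
    "read_bathymetry",
    "write_bathymetry",
    "lookup_bottom_depth",
]

#: Canonical record columns, in write order.
RECORD_COLUMNS = ("latitude", "longitude", "sample_depth", "bottom_depth")

#: Accepted aliases for the canonical columns (Darwin-Core style names plus
#: the names this package writes).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "decimalLatitude": "latitude",
    "decimalLongitude": "longitude",
    "sampleDepth_m": "sample_depth",
    "bottomDepth_m": "bottom_depth",
    "latitude": "latitude",
    "longitude": "longitude",
    "sample_depth": "sample_depth",
    "bottom_depth": "bottom_depth",
}


def normalize_longitude(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class BathymetryGrid:
    """A regular lat/lon raster of sea-floor depth, positive down.

    ``depth`` has shape ``(n_lat, n_lon)`` with rows ordered south to north
    (matching the ascending ``lat_edges``).  Land (or otherwise invalid)
    cells are flagged in ``mask`` and excluded from all area accounting;
    records falling on them are never silently assigned a depth.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    depth: np.ndarray
    mask: np.ndarray = field(default=None)  # True where land/invalid

    def __post_init__(self) -> None:
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.depth) | (self.depth < 0)
        self.mask = np.asarray(self.mask, dtype=bool)
        for name, edges in (("lat_edges", self.lat_edges), ("lon_edges", self.lon_edges)):
            if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
                raise ValueError(f"{name} must be 1-D, length >= 2, strictly ascending")
        shape = (self.lat_edges.size - 1, self.lon_edges.size - 1)
        if self.depth.shape != shape:
            raise ValueError(f"depth shape {self.depth.shape} != {shape} implied by edges")
        if self.mask.shape != shape:
            raise ValueError("mask shape mismatch")

    @property
    def n_lat(self) -> int:
        return self.lat_edges.size - 1

    @property
    def n_lon(self) -> int:
        return self.lon_edges.size - 1

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def ocean_depths(self) -> np.ndarray:
        """Depths of unmasked (ocean) cells, flattened."""
        return self.depth[~self.mask]

    @classmethod
    def global_grid(cls, n_lat: int, n_lon: int, depth: np.ndarray, mask=None) -> "BathymetryGrid":
        """A grid spanning the whole globe with equally spaced edges."""
        return cls(
            lat_edges=np.linspace(-90.0, 90.0, n_lat + 1),
            lon_edges=np.linspace(-180.0, 180.0, n_lon + 1),
            depth=depth,
            mask=mask,
        )


# ---------------------------------------------------------------------------
# occurrence records

def read_records(path, column_map: dict[str, str] | None = None, sep: str = ",") -> pd.DataFrame:
    """Read occurrence records from delimited text.

    ``column_map`` maps file column names to canonical names and is merged
    over the Darwin-Core defaults.  Rows with unparseable coordinates or
    depths, or coordinates outside [-90, 90] x [-180, 180], are dropped with
    a logged count.  A missing mandatory column raises ``ValueError`` naming
    it.
    """
    mapping = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        mapping.update(column_map)
    raw = pd.read_csv(path, sep=sep)
    df = raw.rename(columns={c: mapping[c] for c in raw.columns if c in mapping})
    for col in ("latitude", "longitude", "sample_depth"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    numeric_cols = [c for c in RECORD_COLUMNS if c in df.columns]
    for col in numeric_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = df[numeric_cols].notna().all(axis=1)
    ok &= df["latitude"].between(-90.0, 90.0) & df["longitude"].between(-180.0, 180.0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_records: dropped %d unparseable/out-of-range rows", n_dropped)
    out = df.loc[ok].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def write_records(records: pd.DataFrame, path, with_truth: bool = False) -> None:
    """Write records as CSV with Darwin-Core style column names."""
    inverse = {
        "latitude": "decimalLatitude",
        "longitude": "decimalLongitude",
        "sample_depth": "sampleDepth_m",
        "bottom_depth": "bottomDepth_m",
    }
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    if with_truth:
        cols += [c for c in ("true_component", "anomaly") if c in records.columns]
    records[cols].rename(columns=inverse).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bathymetry grids

_NODATA = -99999.0


def write_bathymetry(grid: BathymetryGrid, path) -> None:
    """Write a grid as netCDF (``.nc``) or ESRI ASCII (``.asc``).

    The ASCII format requires square cells (one cellsize for both axes).
    """
    path = Path(path)
    if path.suffix == ".nc":
        depth = grid.depth.copy()
        depth[grid.mask] = np.nan
        ds = xr.Dataset(
            {
                "depth": (("lat", "lon"), depth),
                "lat_edges": ("lat_edge", grid.lat_edges),
                "lon_edges": ("lon_edge", grid.lon_edges),
            },
            coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
            attrs={"convention": "depth_positive_down_m"},
        )
        ds.to_netcdf(path, engine="scipy")
    elif path.suffix == ".asc":
        dlat = np.diff(grid.lat_edges)
        dlon = np.diff(grid.lon_edges)
        cellsize = dlat[0]
        if not (np.allclose(dlat, cellsize) and np.allclose(dlon, cellsize)):
            raise ValueError("ESRI ASCII grids require uniform square cells; use netCDF")
        depth = grid.depth.copy()
        depth[grid.mask] = _NODATA
        with open(path, "w") as fh:
            fh.write(f"ncols {grid.n_lon}\n")
            fh.write(f"nrows {grid.n_lat}\n")
            fh.write(f"xllcorner {float(grid.lon_edges[0])!r}\n")
            fh.write(f"yllcorner {float(grid.lat_edges[0])!r}\n")
            fh.write(f"cellsize {float(cellsize)!r}\n")
            fh.write(f"NODATA_value {float(_NODATA)!r}\n")
            # rows are written north to south, per the format; %.17g keeps
            # the round-trip bit-exact for float64
            np.savetxt(fh, depth[::-1], fmt="%.17g")
    else:
        raise ValueError(f"unsupported grid format: {path.suffix!r} (use .nc or .asc)")


def read_bathymetry(path, convention: str = "depth") -> BathymetryGrid:
    """Read a bathymetry grid from netCDF or ESRI ASCII.

    ``convention`` sets the sign of the stored values: ``"depth"`` means
    positive-down sea-floor depth (negative values are land and get masked);
    ``"elevation"`` means relief-model elevation (ocean is negative, land
    positive) and is negated on read.  Either way the returned grid is
    depth-positive-down with land masked.
    """
    if convention not in ("depth", "elevation"):
        raise ValueError("convention must be 'depth' or 'elevation'")
    path = Path(path)
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            if "lat_edges" in ds:
                lat_edges = ds["lat_edges"].values.copy()
                lon_edges = ds["lon_edges"].values.copy()
            else:  # cell centers only: infer edges from uniform spacing
                lat_edges = _edges_from_centers(ds["lat"].values)
                lon_edges = _edges_from_centers(ds["lon"].values)
            values = ds["depth"].values.copy()
    elif path.suffix == ".asc":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        cs = header["cellsize"]
        values = np.atleast_2d(values)[::-1]  # back to south-to-north rows
        if values.shape != (nrows, ncols):
            raise ValueError("ASCII grid body does not match header dimensions")
        lon_edges = header["xllcorner"] + cs * np.arange(ncols + 1)
        lat_edges = header["yllcorner"] + cs * np.arange(nrows + 1)
        nodata = header.get("nodata_value")
        if nodata is not None:
            values = np.where(values == nodata, np.nan, values)
    else:
        raise ValueError(f"unsupported grid format: {path.suffix!r} (use .nc or .asc)")

    if convention == "elevation":
        values = -values
    mask = ~np.isfinite(values) | (values < 0)
    return BathymetryGrid(lat_edges=lat_edges, lon_edges=lon_edges, depth=values, mask=mask)


def _edges_from_centers(centers: np.ndarray) -> np.ndarray:
    steps = np.diff(centers)
    if centers.size < 2 or not np.allclose(steps, steps[0]):
        raise ValueError("cannot infer edges from non-uniform cell centers")
    step = steps[0]
    return np.concatenate([centers - step / 2, [centers[-1] + step / 2]])


# ---------------------------------------------------------------------------
# bottom-depth lookup

def _cell_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [edge_i, edge_{i+1}) cell index; the global upper edge maps
    to the last cell; -1 marks out-of-extent values."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = edges.size - 2
    out = (values < edges[0]) | (values > edges[-1])
    idx[out] = -1
    return idx


def lookup_bottom_depth(
    records: pd.DataFrame, bathy: BathymetryGrid, strict: bool = False
) -> pd.DataFrame:
    """Assign each record the sea-floor depth of its grid cell.

    Longitudes are wrapped to [-180, 180) before matching.  Records outside
    the grid extent or over land-masked cells are dropped with a logged
    count (``strict=True`` raises instead).  The result is independent of
    record order and idempotent.
    """
    lat = records["latitude"].to_numpy(dtype=float)
    lon = normalize_longitude(records["longitude"].to_numpy(dtype=float))
    i = _cell_index(lat, bathy.lat_edges)
    j = _cell_index(lon, bathy.lon_edges)
    inside = (i >= 0) & (j >= 0)
    n_outside = int((~inside).sum())
    masked = np.zeros(len(records), dtype=bool)
    masked[inside] = bathy.mask[i[inside], j[inside]]
    n_masked = int(masked.sum())
    if strict and (n_outside or n_masked):
        raise ValueError(
            f"{n_outside} records outside grid extent, {n_masked} over masked cells"
        )
    if n_outside:
        logger.info("lookup_bottom_depth: dropped %d records outside grid extent", n_outside)
    if n_masked:
        logger.info("lookup_bottom_depth: dropped %d records over masked (land) cells", n_masked)
    keep = inside & ~masked
    out = records.loc[keep].copy()
    out["bottom_depth"] = bathy.depth[i[keep], j[keep]]
    out = out.reset_index(drop=True)
    out.attrs["n_dropped_outside"] = n_outside
    out.attrs["n_dropped_masked"] = n_masked
    return out
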