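"""Figure analogues of the depth-distribution analysis.

Each plot has a pure geometry companion so tests can assert on the plotted
coordinate data rather than on pixels, and every figure is produced from
saved pipeline outputs only (re-renderable without recomputation):

* record counts against bottom depth with a lowess trend and the zone
  boundary guides (200 / 1000 / 4000 / 6000 m);
* zone record-proportion against zone area-proportion with the 1:1 line of
  proportional representation;
* the bottom x sample depth matrix as a heat image whose column widths are
  proportional to bottom-stratum area — in volume-scaled mode (linear axes,
  log10 volumetric density, drawn cell area proportional to ocean volume) or
  in proportion mode (per-column proportions, cells contributing <=1% of
  their column masked, display axes compressed as d' = d^(2/3), a' = sqrt(a)
  to make the thin surface strata and small zones legible).
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib.pyplot as plt
import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .depthmatrix import DepthMatrix

__all__ = [
    "ZONE_BOUNDARY_GUIDES_M",
    "AxisTransform",
    "DISPLAY_TRANSFORMS",
    "lowess_smooth",
    "plot_records_vs_depth",
    "plot_representation",
    "matrix_plot_geometry",
    "plot_matrix",
]

ZONE_BOUNDARY_GUIDES_M = (200.0, 1000.0, 4000.0, 6000.0)


@dataclass(frozen=True)
class AxisTransform:
    """Monotone power compressions for the proportion-mode display axes."""

    depth_exponent: float = 2.0 / 3.0
    area_exponent: float = 0.5

    def __post_init__(self) -> None:
        if self.depth_exponent <= 0 or self.area_exponent <= 0:
            raise ValueError("transform exponents must be positive (monotone)")

    def depth(self, d):
        return np.asarray(d, dtype=float) ** self.depth_exponent

    def area(self, a):
        return np.asarray(a, dtype=float) ** self.area_exponent


DISPLAY_TRANSFORMS = AxisTransform()


def lowess_smooth(x, y, frac: float = 2.0 / 3.0, it: int = 3) -> np.ndarray:
    """Locally weighted scatterplot smoothing; returns (n, 2) sorted (x, fit)."""
    return _sm_lowess(np.asarray(y, float), np.asarray(x, float), frac=frac, it=it)


def plot_records_vs_depth(
    depths,
    counts,
    frac: float = 2.0 / 3.0,
    guides=ZONE_BOUNDARY_GUIDES_M,
    ax=None,
):
    """Record count against bottom depth with a lowess trend.

    Depth runs down the vertical axis; the count axis is logarithmic, so the
    smooth is fitted to log10(count) (zero-count depths are dropped).
    Horizontal guide lines mark the zone boundaries.
    """
    depths = np.asarray(depths, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if depths.size == 0:
        raise ValueError("no counts to plot")
    keep = counts > 0
    smooth = lowess_smooth(depths[keep], np.log10(counts[keep]), frac=frac)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(counts[keep], depths[keep], color="0.6", label="records")
    ax.plot(10.0 ** smooth[:, 1], smooth[:, 0], color="k", label="lowess")
    for g in guides:
        ax.axhline(g, linestyle="--", color="0.4", linewidth=0.8)
    ax.set_xscale("log")
    ax.invert_yaxis()
    ax.set_xlabel("number of records")
    ax.set_ylabel("bottom depth (m)")
    return ax.figure, ax


def plot_representation(zone_record_props, zone_area_props, ax=None):
    """Zone share of records against zone share of ocean area, with the 1:1
    line separating over- from under-represented zones.

    Both inputs are mappings from zone label to proportion and must cover
    the same zones and each sum to 1.
    """
    if set(zone_record_props) != set(zone_area_props):
        raise ValueError("record and area proportions cover different zones")
    labels = sorted(zone_record_props)
    rec = np.array([zone_record_props[k] for k in labels], dtype=float)
    area = np.array([zone_area_props[k] for k in labels], dtype=float)
    for name, v in (("record", rec), ("area", area)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"zone {name} proportions must sum to 1")
    if ax is None:
        _, ax = plt.subplots()
    lim = max(rec.max(), area.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="0.5", linewidth=0.8, label="1:1")
    ax.scatter(area, rec)
    for k, a, r in zip(labels, area, rec):
        ax.annotate(k, (a, r), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("proportion of ocean area")
    ax.set_ylabel("proportion of records")
    return ax.figure, ax


def matrix_plot_geometry(
    matrix: DepthMatrix,
    mode: str = "volume",
    transforms: AxisTransform | None = None,
    mask_threshold: float = 0.01,
) -> dict:
    """Plot coordinates and masked values for the matrix heat image.

    Column edges are the cumulative bottom-stratum area fractions (recovered
    from the matrix's own cell volumes), so that in volume-scaled mode —
    linear axes, log10 volumetric density — the drawn area of every cell is
    exactly proportional to its ocean volume.  Proportion mode shows column
    proportions, masks cells contributing ``mask_threshold`` or less of
    their column, and applies the display transforms (supplying transforms
    in volume-scaled mode is rejected).
    """
    if mode not in ("volume", "proportion"):
        raise ValueError("mode must be 'volume' or 'proportion'")
    scheme = matrix.scheme
    # bottom-stratum area fractions: volume of the first sample stratum's
    # cell in each column divided by that stratum's thickness
    area_b = matrix.volumes[0, :] / scheme.widths[0]
    x_edges = np.concatenate([[0.0], np.cumsum(area_b)])
    y_edges = np.concatenate([[0.0], scheme.uppers])
    if mode == "volume":
        if transforms is not None:
            raise ValueError("volume-scaled mode uses linear axes; no transforms")
        values = np.ma.masked_invalid(matrix.log_density)
    else:
        if transforms is None:
            transforms = DISPLAY_TRANSFORMS
        prop = matrix.column_proportions
        bad = ~matrix.valid | ~np.isfinite(prop) | (prop <= mask_threshold)
        values = np.ma.masked_array(prop, mask=bad)
        x_edges = transforms.area(x_edges)
        y_edges = transforms.depth(y_edges)
    return {"x_edges": x_edges, "y_edges": y_edges, "values": values, "mode": mode}


def plot_matrix(
    matrix: DepthMatrix,
    mode: str = "volume",
    transforms: AxisTransform | None = None,
    mask_threshold: float = 0.01,
    inset: DepthMatrix | None = None,
    cmap: str = "viridis",
    ax=None,
):
    """Render the bottom x sample depth matrix (see
    :func:`matrix_plot_geometry` for the geometric contract).

    ``inset``, if given, is a fine-resolution matrix drawn in a corner inset
    restricted to the shelf and slope (bottom depths to 1000 m).
    """
    geom = matrix_plot_geometry(matrix, mode, transforms, mask_threshold)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    mesh = ax.pcolormesh(geom["x_edges"], geom["y_edges"], geom["values"], cmap=cmap)
    ax.invert_yaxis()
    ax.set_xlabel("cumulative ocean area fraction" + (" (transformed)" if mode == "proportion" else ""))
    ax.set_ylabel("sample depth (m)" + (" (transformed)" if mode == "proportion" else ""))
    label = "log10 records per unit volume" if mode == "volume" else "proportion of column"
    ax.figure.colorbar(mesh, ax=ax, label=label)
    if inset is not None:
        sub = ax.inset_axes([0.55, 0.08, 0.42, 0.45])
        igeom = matrix_plot_geometry(inset, mode, transforms, mask_threshold)
        keep_b = inset.scheme.uppers <= 1000.0
        keep_s = inset.scheme.uppers <= 1000.0
        sub.pcolormesh(
            igeom["x_edges"][: keep_b.sum() + 1],
            igeom["y_edges"][: keep_s.sum() + 1],
            igeom["values"][: keep_s.sum(), : keep_b.sum()],
            cmap=cmap,
        )
        sub.invert_yaxis()
    return ax.figure, ax
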