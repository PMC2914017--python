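"""Ocean depth zones and their global area shares.

The ocean is conventionally divided by bottom depth into five zones:
continental shelf (0-200 m), mesopelagic continental slope (200-1000 m),
bathypelagic continental slope (1000-4000 m), abyssal plain (4000-6000 m)
and hadal zone (>6000 m).  Zone membership uses (lower, upper] intervals,
closed below at 0, so a bottom depth of exactly 200 m is a shelf depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepthZone",
    "DEFAULT_ZONES",
    "GLOBAL_ZONE_AREA_FRACTIONS",
    "zone_index_of_depth",
]


@dataclass(frozen=True)
class DepthZone:
    """One bottom-depth zone: a half-open depth interval (lower, upper]."""

    label: str
    name: str
    lower: float
    upper: float  # np.inf for the deepest zone

    def __post_init__(self) -> None:
        if not self.upper > self.lower >= 0:
            raise ValueError(f"zone {self.label}: need 0 <= lower < upper")


DEFAULT_ZONES: tuple[DepthZone, ...] = (
    DepthZone("A", "Continental Shelf", 0.0, 200.0),
    DepthZone("B", "Continental Slope / Mesopelagic", 200.0, 1000.0),
    DepthZone("C", "Continental Slope / Bathypelagic", 1000.0, 4000.0),
    DepthZone("D", "Abyssal Plain", 4000.0, 6000.0),
    DepthZone("E", "Hadal Zone", 6000.0, np.inf),
)

#: Area share of the global ocean in each zone, estimated from global
#: sea-floor topography.  The abyssal plain alone is almost half the ocean
#: floor; the hadal trenches are a sliver.
GLOBAL_ZONE_AREA_FRACTIONS: dict[str, float] = {
    "A": 0.087,
    "B": 0.058,
    "C": 0.363,
    "D": 0.486,
    "E": 0.006,
}


def zone_index_of_depth(depth, zones: tuple[DepthZone, ...] = DEFAULT_ZONES):
    """Index of the zone containing each depth, under (lower, upper] membership.

    Depth 0 belongs to the first zone.  Raises on negative depths.
    """
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative depth has no zone")
    uppers = np.array([z.upper for z in zones])
    idx = np.searchsorted(uppers, d, side="left")
    return idx if d.ndim else int(idx)
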