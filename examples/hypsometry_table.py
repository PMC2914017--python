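"""Area share of the ocean in each depth zone.

Generates a synthetic global bathymetry targeting the standard hypsometry
and recomputes the zone-area table from it with latitude-corrected
(spherical) cell areas.
"""

import pelagos as pg

bathy = pg.generate_bathymetry(180, 360, seed=1)
table = pg.zone_area_fractions(bathy)
print(table.round(3).to_string(index=False))
# area_fraction_pct should match the generator's targets (8.7, 5.8, 36.3,
# 48.6, 0.6) to within one grid cell's area; cumulative_pct is the running
# sum in depth order and ends at 100.
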