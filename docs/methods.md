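# Methods

`pelagos` reconstructs, as a tested pipeline, the analysis of where in the
water column recorded marine biodiversity comes from: given occurrence
records with a sample depth and a bottom depth, how are records distributed
over the three-dimensional ocean once the very unequal areas (and volumes)
of its depth zones are accounted for?

## Position in the water column

Each record carries a **sample depth** (metres below the surface at which it
was collected) and a **bottom depth** (sea-floor depth under its
coordinates, taken from a gridded bathymetry by nearest-cell lookup).
Together they place the record in the water column. Bottom depth is a cell
average over a raster, not a point measurement, which motivates both the
lookup convention and one of the QC rules below.

Grid cells are half-open `[edge_i, edge_{i+1})` in both axes, with a
coordinate exactly on the global upper edge assigned to the last cell;
longitudes are wrapped to [-180, 180) first. Nearest-cell (not bilinear)
lookup is used deliberately: the gridded depth is the cell's value, not a
continuous surface to interpolate.

## Record QC

Two rules, applied in a fixed order:

1. drop records with a negative sample depth, then records with a negative
   bottom depth (typically intertidal records);
2. for every remaining record with sample depth > bottom depth, trust the
   sample depth (a point measurement) and set the bottom depth equal to it —
   the discrepancy is attributed to the cell-averaged bathymetry.

The order matters because the exceedance fraction's denominator depends on
it; the cleaning report carries all counts (with the pre-removal record
count as the documented denominator) so either convention can be recovered.
Zero depths are legitimate surface samples and are retained. Cleaning is
idempotent and its output satisfies `sample_depth <= bottom_depth`
everywhere, which is asserted on every pipeline run.

## Zones, strata and hypsometry

Bottom depth divides the ocean into five zones — shelf (0–200 m),
mesopelagic slope (200–1000 m), bathypelagic slope (1000–4000 m), abyssal
plain (4000–6000 m), hadal (>6000 m). Depth-interval membership is
`(lower, upper]`, closed at 0, everywhere in the package (zones, strata,
grid lookups); the convention is configurable but asserted consistently,
since no natural rule decides whether a 200 m bottom is "shelf" or "slope".

Cell areas use a spherical Earth (R = 6371 km):
`R^2 * dlambda * (sin(phi_u) - sin(phi_l))`. The ellipsoidal correction is
below 0.4% and cancels in area fractions, which are all the analysis uses.

The water column (and the bottom-depth axis) is tiled by a
variable-resolution strata scheme: 50 m strata to 200 m, 100 m to 1000 m,
200 m to 6000 m and 1000 m strata above that, covering to 11 000 m — 42
strata, chosen so the deepest trench depths (the deepest sample in global
extracts is 10 670 m) are representable. A fine variant uses 10 m shelf
strata (58 strata) for shelf-scale analyses and the midwater statistics.

## The bottom x sample depth matrix

Cleaned records are binned by (bottom stratum, sample stratum). Only cells
with sample stratum <= bottom stratum exist — n(n+1)/2 cells, 903 under the
default scheme. Raw counts conflate sampling effort with habitat size: a
200 m stratum over the abyssal plain holds far more water than one over the
shelf. Each cell's count is therefore divided by its **relative volume**,
the bottom stratum's ocean-area fraction times the sample stratum's
thickness, and log10-transformed for display. Empty cells carry an explicit
NaN flag rather than -inf: no pseudocount is invented. A per-column
re-calibration (each bottom-depth column summing to 1) shows the vertical
distribution of records independently of how many there are at each bottom
depth.

Per-bottom-stratum area fractions come from the grid's own hypsometry; a
uniform-within-zone fallback (`stratum_fractions_from_zones`) spreads zone
totals per metre of depth when only zone-level areas are available.

## Midwater statistics

Midwater excludes a surface band and a seabed band whose thicknesses depend
on the zone: 10/10 m on the shelf, 100/100 m mesopelagic, 100/200 m
bathypelagic and abyssal, 100/1000 m hadal. The band is open: a sample
exactly on an exclusion boundary is not midwater. Per fine bottom stratum,
the midwater proportion of its records is computed; strata whose upper bound
does not exceed the combined bands (0–10 and 10–20 m) can contain no
midwater by construction and are excluded, leaving 56 contributing strata
and hence 54 degrees of freedom for the correlation when all are populated.

The trend of proportion against bottom depth is tested with Spearman's rank
correlation (average ranks for ties, two-sided p by the t approximation;
exact permutation enumeration is available for n <= 10). The stratum's
representative depth is its midpoint — Spearman depends only on rank order,
so any monotone representative is equivalent; the midpoint is documented for
reproducibility. Strata with zero records are dropped from the correlation
rather than treated as proportion 0 (dropping avoids manufacturing data;
configurable by filtering the stratum table). Zone-level summaries report
the median, interquartile range and total range of their strata's
proportions.

## The synthetic-data model

The generators produce data with the statistical structure the analysis
assumes, so every stage is testable end to end without downloads.

**Bathymetry.** Grid cells (weighted by true spherical area) are assigned to
zones in a random order so each zone's area share matches its target —
default: the global-ocean shares 8.7 / 5.8 / 36.3 / 48.6 / 0.6% — to within
one cell's area. Within a zone, depth is uniform over the zone's interval,
the minimal assumption given that only zone totals are constrained; real
hypsometry is not uniform within zones, so absolute within-zone depth
distributions of the synthetic grids are not realistic and nothing
downstream relies on them. Hadal depths are capped at 11 000 m.

**Records.** Horizontal placement picks a cell with probability proportional
to area times a sampling-effort factor `exp(-bottom / 1000 m)`. The effort
decay reproduces the depth bias characteristic of global occurrence
databases — over half the records over the shelf (<10% of the ocean's area),
a few percent over the abyssal plain (half of it); `effort_scale=None`
disables it for calibration tests, where pure area weighting
(cos-latitude) is verified directly. Vertical placement follows a
three-component mixture: a surface-attached exponential (mean 10 m), a
seabed-attached exponential (mean 20 m), and a uniform midwater component,
each truncated to the local column, with default weights 0.55 / 0.35 / 0.10.
The mixture is the simplest generator that both reproduces the observed
surface/seabed concentration of sampling and can be inverted: its midwater
probability has the closed form

    P(mid | B) = pi_s [F_s(B - e) - F_s(s)] + pi_b [F_b(B - s) - F_b(e)]
                 + pi_m (B - s - e) / B,

where F is the truncated-exponential CDF on [0, B] and (s, e) are the
zone's exclusion bands — the analytic oracle used in parameter-recovery
tests. No claim is made that real record-generating processes follow this
mixture; it defines the study conditions for the synthetic experiments.

**Anomalies.** Negative sample/bottom depths replace drawn values on
disjoint record sets at exact requested counts (defaults 14 and 1); then a
7% share of the untouched records has its sample depth pushed 0–20 m below
the sea bed (strictly, so the exceedance is detectable). Injection after
drawing, on disjoint sets, makes the cleaning report's recovery exact, which
the tests assert.

All randomness flows from a single seed through one named
`numpy.random.Generator`.

## Figures

Each figure has a pure geometry companion so tests assert on coordinate
data, not pixels. The volume-scaled matrix image uses column widths equal to
per-stratum area fractions (not uniform within zones), making drawn cell
area exactly proportional to ocean volume; a `stratum_fractions_from_zones`
fallback gives uniform-within-zone widths if preferred. The
proportion-mode image masks cells contributing <=1% of their column and
compresses the axes (`d' = d^(2/3)`, `a' = sqrt(a)`) so thin surface strata
and small zones stay legible; transforms are rejected in volume-scaled mode,
whose axes must stay linear for the area-volume proportionality to hold.
The lowess trend (statsmodels; span 2/3 by default, a conventional choice)
is cross-checked in the tests against an independent tricube local-linear
implementation. Colormaps and fonts are unconstrained.

## Problem sizes and determinism

The test and acceptance runs use a 1-degree (180x360) grid for hypsometry
checks, a 5-degree (36x72) grid for replicate loops, 1e5 records for
recovery experiments and 100 replicates of 2e4 records for the
correlation-sign experiment — sizes at which binomial tolerances (3 SE) are
tight enough to be meaningful while a full run completes in seconds. All
stochastic tests fix seeds.

## Known limitations

- Synthetic bathymetry has no spatial autocorrelation; zone membership is
  salt-and-pepper. Hypsometry, which is all the analysis consumes, is
  unaffected.
- Within-zone depth distributions are uniform (see above).
- The generator models neither taxonomy, abundance, gear, nor seasonality;
  passing tests show the *pipeline* recovers known structure, not that real
  databases follow the mixture.
- Bottom-depth lookup is nearest-cell; no sub-cell bathymetric variation.
- The Spearman p-value's t approximation is asymptotic; for tiny stratum
  counts use the exact permutation option.
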