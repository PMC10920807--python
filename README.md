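# abitower

GOES-R ABI land-surface products as half-hourly time series at point
locations — the format eddy covariance (flux-tower) scientists actually work
with.

Geostationary satellites image the full Western Hemisphere disk every ten
minutes, but their Level-2 products arrive as one raster file per scan on
the instrument's *fixed grid* of scan angles. Linking them with a flux
tower's half-hourly CSV record requires: matching the tower to the right
fixed-grid pixel (including the parallax shift of elevated targets),
reading and decoding per-pixel data-quality flags, collapsing three scans
per half hour into one end-stamped record, upsampling the hourly products
(downward shortwave radiation, land surface temperature) to the half-hour
with a gap-aware interpolation rule, and deriving the photosynthesis
proxies NDVI, NIRv and NIRvP. `abitower` implements that whole chain,
plus the validation statistics used to judge the result against tower
measurements, and a seeded synthetic-scene generator so everything can be
exercised offline with known ground truth.

## The core computations

**Fixed-grid projection.** A target at geodetic latitude/longitude/elevation
(φ, λ, z) on the GRS80 ellipsoid maps to E/W and N/S scan angles (x, y)
through the standard geostationary closed forms: geodetic latitude is
converted to geocentric, the geocentric radius r_c (plus z for elevated
targets) places the point in a satellite-centred frame, and the scan angles
follow from the frame components. The inverse solves a quadratic for the
near-side ray–ellipsoid intersection. Pixel footprints are the four cell
corners projected to the ground; their area is evaluated exactly on the
equal-area (authalic) sphere. A 2-km-class pixel covers 4 km² at nadir,
stretching to ~7.3 km² near Madison, WI and ~15 km² near Seattle, WA.

**Quality flags.** Products carry either a categorical flag or an 8-bit
mask (least-significant bit = bit 0). For surface reflectance (BRF) the
observed values decode as 8 = clear-sky retrieval daytime (the only value
recommended for use), 16 = cloudy-path retrieval, 24/26 = no retrieval
day/night. The Aerosol Detection flag's "invalid due to snow/ice/cloud"
bit doubles as a snow mask for the NIRv family. Schemas are editable YAML
files shipped with the package.

**Temporal fusion.** Scans starting in [H:00, H:30) are averaged and
stamped at H:30 (end-of-interval, the flux-network convention); the record
flag is the worst contributing flag. Hourly snapshots are upsampled with
monotone piecewise-cubic (PCHIP) interpolation between *consecutive*
present hours only — gaps of an hour or more are never filled — and
inserted values are flagged as estimates.

**Indices and validation statistics.**

    NDVI  = (NIR − Red) / (NIR + Red)
    NIRv  = (NDVI − soil_offset) · NIR        (soil_offset defaults to 0)
    PAR   = 0.45 · DSR                        (W m⁻²; PPFD = 4.56 · PAR)
    NIRvP = NIRv · PAR

    LST_tower = [ LW_IN/σ − LW_IN/(εσ) + LW_OUT/(εσ) ]^¼ ,  ε = 0.98
    centroid  = Σ_t NIRvP_t · t / Σ_t NIRvP_t            (12 = local noon)

plus midday medians (10:00–14:00 local), solar-noon-centred 2.5-h means,
monthly mean/SD composites, 14-day moving averages, and pairwise-complete
r².

## Worked example

```
$ abitower geometry --lat 43.07 --lon -89.40 --elev 300 --satellite goes-east
SITE_LAT=43.070000
SITE_LON=-89.400000
ELEVATION=300.000000
PIXEL_AREA=7.266062
CORRECTED_LAT=43.073197
CORRECTED_LON=-89.401622
VAA=159.654016
VZA=51.701714
PARALLAX=378.964087
...
```

A 300-m tower near Madison is seen by GOES-East at a 51.7° view zenith
angle; its apparent position is displaced ~379 m toward the satellite's
azimuth, and the pixel containing it covers 7.27 km² of ground.

The full synthetic pipeline:

```
$ abitower synth --seed 5 --days 1 --out demo --products BRF,DSR
$ printf 'SITE_ID,SITE_LAT,SITE_LON,ELEVATION,UTC_OFFSET\nSYN-WI,43.07,-89.40,300,-6\n' > sites.csv
$ abitower extract --sites sites.csv --scenes demo/scenes --out extracted
SYN-WI: 48 half-hour rows
$ abitower validate --timeseries extracted/SYN-WI.csv \
      --tower demo/tower_SYN-WI.csv --utc-offset -6
{
  "n_halfhours": 48,
  "dsr_r2": 0.839,
  "dsr_bias_w_m2": 20.3,
  ...
}
```

Here `dsr_r2` compares the satellite's downward-shortwave column (hourly
snapshots plus interpolated half-hours) against the simulated tower
pyranometer: with the generator's default cloud flicker and 5% sensor
noise the two agree at r² ≈ 0.84, while on measured (non-interpolated)
records alone the agreement is r² ≈ 0.99 — the gap is the price of
interpolating across half-hourly cloud changes.

Library use mirrors the CLI: `generate_scene_stack` → 
`assemble_site_timeseries` → `write_timeseries_csv`, with every step
importable on its own.

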