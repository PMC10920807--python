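# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `abitower`. It is written for a user deciding whether
the package's assumptions fit their data.

## Earth model and fixed-grid projection

All geometry runs on the GRS80 ellipsoid (semi-major axis 6 378 137 m,
semi-minor 6 356 752.31414 m) with the geostationary satellite at a
perspective height of 35 786 023 m above the ellipsoid surface
(geocentric distance 42 164 160 m). GOES-East sits at 75.2° W, GOES-West
at 137.2° W. Scan-angle increments are 56 µrad for the 2-km pixel class
(halving for the 1-km and 0.5-km classes), with full-disk grids of
5424/10848/21696 cells per side whose centres are placed symmetrically
about nadir.

The forward projection converts geodetic to geocentric latitude, computes
the geocentric surface radius r_c, and expresses the target in a
satellite-centred frame from which the two scan angles follow; a limb
inequality decides visibility. The inverse solves the ray–ellipsoid
quadratic and keeps the near-side root. Round-trip accuracy is at the
10⁻¹²-degree level, and the forward map reproduces the published
worked example for a satellite at 75.0° W — (33.846162° N, 84.690932° W)
→ (−0.024052, 0.095340) rad — to six decimals of a radian.

**Elevated targets and parallax.** Fixed-grid products are not
terrain-corrected: an elevated target appears displaced away from the
sub-satellite point. Before pixel matching, the target's elevation is
added to its geocentric radius and the satellite ray through that raised
point is intersected with the sea-level ellipsoid (exactly, via the
closed-form inverse — not the small-angle z·tan(VZA) approximation,
which serves only as a test oracle; the two agree within ~0.25% at
mid-latitudes). The resulting "corrected" coordinates are what the
fixed grid perceives, and pixel matching uses them. Cells are half-open
scan-angle intervals [centre − res/2, centre + res/2); boundary ties go
to the higher index, so every on-disk point has exactly one pixel.

**Pixel areas.** Footprint corners are the four projected cell-corner
scan angles, ordered counter-clockwise. Areas use the authalic (equal-
area) sphere: each vertex's geodetic latitude is mapped to its authalic
latitude and the spherical quadrilateral's signed excess is evaluated
with the van Oosterom–Strackee triangle formula. For quadrilaterals a
few km across this equals the rigorous geodesic area to well below 0.1%
(the authalic map is exactly area-preserving; the only error is the
great-circle vs. geodesic edge approximation, negligible at this size).
Local-scale checks: 4.016 km² at nadir vs. the (height × resolution)²
flat estimate of 4.017 km²; agreement with the slant-range/cos(VZA)
scaling oracle to ~0.5% out to VZA 60°.

## Solar geometry

Solar zenith/azimuth come from the NOAA solar-calculator condensation of
Meeus' algorithms (geometric mean longitude/anomaly, equation of centre,
apparent longitude, corrected obliquity, declination, equation of time).
Errors are well under 0.1° for 1950–2050, against a contract of ≤0.2°.
No atmospheric refraction is applied: near the 67° daylight cut
refraction is below 0.02°, irrelevant at this tolerance. Solar noon is
the equation-of-time-corrected meridian crossing, refined once (≤1 min).
The combined "solar position" scalar emitted in the record is simply
SZA + SAA, which uniquely tags a sun position over a day.

The daylight classifier is strict: daytime ⇔ SZA < 67°. The source
material uses both "<" and "≤" in different places; "<" is adopted and
the threshold is a parameter everywhere it is used.

Local standard time is UTC plus a fixed site offset, never
daylight-saving — the flux-network convention.

## Quality flags

Two flag kinds exist: categorical levels (imagery, cloud mask, aerosol
optical depth, downward shortwave) and 8-bit masks (surface reflectance,
albedo, aerosol detection, surface temperature). Bit numbering is
least-significant = bit 0; multi-bit fields read the higher position as
the more significant digit. This is the only convention under which the
reflectance flag's observed decimal values decode correctly:
8 = 2³ (clear-sky retrieval, daytime — the sole "usable" value),
16 = 2⁴ (cloudy-path retrieval), 24 = 2³+2⁴ (no retrieval, daytime),
26 = +2¹ (no retrieval, nighttime).

Schemas are declarative YAML, one file per product, so a user can correct
them without code changes. The reflectance layout is canonical; the
albedo, aerosol-detection and surface-temperature layouts are marked
`provisional: true` — their operational definitions live in product
documentation not reproduced here, and the shipped files are sensible
placeholders that the synthetic generator also uses (so package-internal
consistency is exact even where the operational layout may differ).
Every schema covers all eight bits (padding fields named `empty`), which
makes encode∘decode the identity on 0–255 — an exhaustively tested
invariant.

Filtering policy defaults: reflectance bands kept only at flag 8;
downward shortwave dropped at flag 1; the NDVI/NIRv/NIRvP family dropped
where the aerosol-detection snow/ice/cloud bit is set. Raw flag columns
are always retained; filtering only blanks value columns.

## Temporal fusion

* **Window rule.** A scan belongs to the half-hour window containing its
  start time; the :30 scan opens the next window. Windows are stamped at
  their END, matching tower files. (Whether the source record used scan
  start or midpoint is not stated; start is adopted.)
* **Averaging.** The record value is the arithmetic mean over scans with
  valid values (nominally three per window at the ten-minute cadence);
  partial windows average whatever is present, and a provenance column
  can carry the contributing-scan count. The record flag is the maximum
  (worst) flag among contributing scans — conservative labelling.
* **Hourly products.** Downward shortwave and surface temperature are
  top-of-hour instantaneous snapshots. The :30 values are inserted by
  monotone piecewise-cubic (PCHIP) interpolation over each maximal run
  of consecutive present hours. "Cubic interpolation" alone is
  under-determined; PCHIP is chosen because it is local, reproduces
  anchors exactly, is exact on linear data, and never overshoots its
  bracketing anchors. Where either bracketing hour is missing, nothing
  is inserted (gaps of an hour or more are not filled). Inserted values
  carry an `interpolated` provenance flag; their quality flag is the
  worst of the two brackets.
* **Indices after fusion.** NDVI/NIRv are computed from the half-hourly
  fused red/NIR reflectances, PAR from the fused shortwave, NIRvP as
  their product. (Computing indices per scan and then averaging would
  differ only through within-window variation; the fused order is
  adopted and applies uniformly.)

## Validation statistics

The longwave surface-temperature estimator treats measured outgoing
longwave as emitted-plus-reflected radiation at emissivity ε = 0.98 and
σ = 5.67×10⁻⁸ W m⁻² K⁻⁴; non-physical radiation pairs (non-positive
radicand) yield missing values. The diurnal centroid is the
NIRvP-weighted mean hour, evaluated over whatever half-hours are
available using the record's interval-end hour as t. Midday summaries
come in two flavours: the fixed-clock median over 10:00–14:00 local
(endpoints inclusive) and the solar mean over ±75 min around the day's
solar noon. Monthly composites are the mean and sample SD (ddof 1)
of daily midday values across days within the month — the per-site
across-days reading; an SD needs at least two days. Moving averages are
centred day-windows ignoring missing values. r² is squared Pearson
correlation over pairwise-complete cases (the missing-data rule is not
stated in the source; pairwise-complete is adopted), undefined below
three pairs or at zero variance.

## Synthetic benchmark

The generator defines the study conditions under which the pipeline is
verified:

* clear-sky downward shortwave = 1000 W m⁻² × max(0, cos SZA) — a
  standard clear-sky scaling; per-half-hour Bernoulli cloud cover with
  probability 0.3 multiplies it by an attenuation factor 0.35;
* a seasonal NDVI sinusoid (base 0.55, amplitude 0.25, peak near day
  200) with fixed NIR reflectance 0.35, red derived from NDVI;
* surface temperature 286 K + 14 K × max(0, cos SZA);
* tower noise: 5% multiplicative on shortwave, 5 W m⁻² additive on each
  longwave stream, GPP = 0.12 × NIRvP + noise (SD 1 µmol m⁻² s⁻¹);
* flags written from the generative state (8/16/26 for reflectance;
  snow spans set the aerosol-detection snow bit; 2% of shortwave hours
  flagged invalid);
* two neighbouring Wisconsin-like sites ~25 km apart share one small
  scene window; one seeded generator drives all randomness, so identical
  configurations reproduce byte-identical outputs.

Ground truth is defined on the half-hourly record lattice, except that
hourly products carry truth only at their top-of-hour anchors: the :30
entries of those columns are interpolation *estimates* by construction
and have no independent truth. Consequently the parameter-recovery
benchmark compares measured records: noiselessly the pipeline reproduces
stored truth to better than 10⁻⁹ relative, and with the stated noise the
satellite-vs-tower shortwave regression over ~45 days (≈1060 measured
half-hours) has slope ≈ 1.00 and r² ≈ 0.996. Including interpolated
records lowers r² to ≈ 0.8 — not sensor error but the cost of
interpolating across half-hourly cloud flips, the same mechanism that
caps agreement in real data.

What the fixtures do **not** emulate: radiative transfer (no aerosol,
water vapour, or angular BRDF effects), realistic cloud spatial fields
(state is per-site, not advected), footprint mismatch between a tower's
flux source area and a 2-km pixel, and sensor calibration drift. Passing
the recovery tests therefore demonstrates the correctness of the
plumbing, geometry, flag logic, fusion rules and formulas — not the
accuracy of the upstream retrievals, which are consumed as given.

## Problem sizes

The bundled golden case is two sites × three days (144 half-hour rows
per site) with all products; the noisy recovery benchmark is one site ×
45 days of hourly shortwave scenes. These sizes were chosen as the
smallest that exercise every code path and give ≥1000 measured
half-hours for stable regression statistics.

## Known limitations

* Scene files use the netCDF-3 (scipy) container with the operational
  attribute layout; compressed netCDF-4 inputs would need conversion.
* The corrected (parallax-shifted) location inherits the convention of
  raising the target along the geocentric radius; raising along the
  geodetic normal would differ by metres at kilometre elevations.
* Pixel areas treat cell edges as great circles on the authalic sphere;
  exact geodesic edges would change nothing at the stated tolerances.
* The Seattle-class pixel (VZA ≈ 71°) sits past the reflectance
  product's VZA < 70° validity limit; geometry is still computed there,
  but reflectance columns are blanked with a warning.
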