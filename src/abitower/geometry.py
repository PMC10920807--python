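"""Geostationary fixed-grid geometry for the GOES-R ABI.

The ABI fixed grid indexes pixels by the instrument's E/W (``x``) and N/S
(``y``) scan angles, which stay constant over the satellite's life.  This
module implements the closed-form conversions between geodetic coordinates
on the GRS80 ellipsoid and scan angles, the view geometry (zenith/azimuth,
slant range), the parallax shift of elevated targets, and pixel footprint
polygons and areas on the ellipsoid surface.

Conventions
-----------
* Latitudes/longitudes in degrees, east-positive longitude, geodetic
  latitude everywhere in the public API (geocentric latitude is internal).
* Scan angles in radians; ``x`` increases eastward, ``y`` northward.
* Elevation above the ellipsoid in metres.  An elevated target is treated
  by adding its elevation to the geocentric radius before projecting, so
  the resulting scan angles are those of the satellite ray through the
  raised point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EllipsoidModel",
    "SatelliteSpec",
    "GeodeticLocation",
    "ScanAngleCoord",
    "FixedGridSpec",
    "ViewGeometry",
    "NotVisibleError",
    "OffEarthError",
    "PixelTruncatedError",
    "GRS80",
    "GOES_EAST",
    "GOES_WEST",
    "geodetic_to_scan",
    "scan_to_geodetic",
    "view_geometry",
    "pixel_for_location",
    "pixel_center",
    "pixel_polygon",
    "pixel_polygon_at",
    "pixel_area_km2",
    "polygon_area_km2",
    "polygon_is_ccw",
    "SITE_TABLE_COLUMNS",
    "site_constants",
]


class NotVisibleError(ValueError):
    """The target is beyond the limb and cannot be seen by the satellite."""


class OffEarthError(ValueError):
    """The scan-angle ray does not intersect the ellipsoid."""


class PixelTruncatedError(ValueError):
    """At least one pixel corner falls off the Earth disk."""


@dataclass(frozen=True)
class EllipsoidModel:
    """Reference ellipsoid (default constants are GRS80)."""

    semi_major_axis_m: float = 6378137.0
    semi_minor_axis_m: float = 6356752.31414

    def __post_init__(self) -> None:
        if not (self.semi_major_axis_m > self.semi_minor_axis_m > 0):
            raise ValueError("require semi_major > semi_minor > 0")

    @property
    def eccentricity(self) -> float:
        ratio = self.semi_minor_axis_m / self.semi_major_axis_m
        return math.sqrt(1.0 - ratio * ratio)

    @property
    def flattening_sq(self) -> float:
        """(r_eq / r_pol)**2, used by the inverse projection."""
        return (self.semi_major_axis_m / self.semi_minor_axis_m) ** 2

    def authalic_radius_m(self) -> float:
        e = self.eccentricity
        qp = self._q(math.pi / 2.0)
        return self.semi_major_axis_m * math.sqrt(qp / 2.0)

    def _q(self, phi_rad: float) -> float:
        e = self.eccentricity
        s = math.sin(phi_rad)
        return (1.0 - e * e) * (
            s / (1.0 - e * e * s * s)
            - (1.0 / (2.0 * e)) * math.log((1.0 - e * s) / (1.0 + e * s))
        )

    def authalic_latitude_rad(self, phi_deg: float) -> float:
        """Latitude on the equal-area sphere mapping of the ellipsoid."""
        q = self._q(math.radians(phi_deg))
        qp = self._q(math.pi / 2.0)
        return math.asin(min(1.0, max(-1.0, q / qp)))


GRS80 = EllipsoidModel()


@dataclass(frozen=True)
class SatelliteSpec:
    """A geostationary satellite: sub-satellite longitude and height."""

    sub_satellite_longitude_deg: float
    perspective_height_m: float = 35786023.0
    ellipsoid: EllipsoidModel = GRS80
    name: str = ""

    def __post_init__(self) -> None:
        if not -180.0 <= self.sub_satellite_longitude_deg <= 180.0:
            raise ValueError("sub-satellite longitude outside [-180, 180]")
        if self.perspective_height_m <= 0:
            raise ValueError("perspective height must be positive")

    @property
    def geocentric_distance_m(self) -> float:
        """Distance from Earth's centre to the satellite (H)."""
        return self.perspective_height_m + self.ellipsoid.semi_major_axis_m


GOES_EAST = SatelliteSpec(-75.2, name="goes-east")
GOES_WEST = SatelliteSpec(-137.2, name="goes-west")


@dataclass(frozen=True)
class GeodeticLocation:
    latitude_deg: float
    longitude_deg: float
    elevation_m: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValueError(f"latitude {self.latitude_deg} outside [-90, 90]")
        if not -180.0 <= self.longitude_deg <= 180.0:
            raise ValueError(f"longitude {self.longitude_deg} outside [-180, 180]")
        if self.elevation_m < -500.0:
            raise ValueError("elevation below -500 m is not a surface target")


@dataclass(frozen=True)
class ScanAngleCoord:
    x_rad: float
    y_rad: float


@dataclass(frozen=True)
class FixedGridSpec:
    """A regular grid of scan angles.

    Column ``j`` has centre ``x_offset_rad + j * resolution_rad`` (eastward),
    row ``i`` has centre ``y_offset_rad - i * resolution_rad`` (southward),
    matching the north-to-south row order of ABI imagery.
    """

    resolution_rad: float
    x_offset_rad: float
    y_offset_rad: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.resolution_rad <= 0:
            raise ValueError("resolution must be positive")

    # Nominal full-disk grids.  The scan-angle increment is 56 urad for the
    # 2-km pixel class, halving with each finer class; offsets place pixel
    # centres symmetrically about nadir.
    _FULL_DISK = {
        "2km": (56e-6, 5424),
        "1km": (28e-6, 10848),
        "0.5km": (14e-6, 21696),
    }

    @classmethod
    def full_disk(cls, resolution: str = "2km") -> "FixedGridSpec":
        try:
            res, n = cls._FULL_DISK[resolution]
        except KeyError:
            raise ValueError(f"unknown resolution class {resolution!r}") from None
        half = (n - 1) / 2.0 * res
        return cls(res, -half, half, n, n)

    def x_center(self, col) -> np.ndarray | float:
        return self.x_offset_rad + np.asarray(col) * self.resolution_rad

    def y_center(self, row) -> np.ndarray | float:
        return self.y_offset_rad - np.asarray(row) * self.resolution_rad


@dataclass(frozen=True)
class ViewGeometry:
    vza_deg: float
    vaa_deg: float
    parallax_m: float
    corrected: GeodeticLocation
    slant_range_m: float = 0.0


# ---------------------------------------------------------------------------
# core projections
# ---------------------------------------------------------------------------

def _sat_frame_position(loc: GeodeticLocation, sat: SatelliteSpec):
    """Target position in the satellite-centred frame used by the fixed grid.

    The frame has s_x from Earth's centre toward the satellite (origin at the
    satellite), s_y toward west in the equatorial plane and s_z toward north.
    """
    ell = sat.ellipsoid
    phi = math.radians(loc.latitude_deg)
    dlam = math.radians(loc.longitude_deg - sat.sub_satellite_longitude_deg)
    e2 = ell.eccentricity ** 2
    # geocentric latitude of the geodetic surface point
    phi_c = math.atan((1.0 - e2) * math.tan(phi)) if abs(loc.latitude_deg) < 90 else phi
    r_c = ell.semi_minor_axis_m / math.sqrt(1.0 - e2 * math.cos(phi_c) ** 2)
    r_c += loc.elevation_m  # elevated target: raise along the geocentric radius
    H = sat.geocentric_distance_m
    s_x = H - r_c * math.cos(phi_c) * math.cos(dlam)
    s_y = -r_c * math.cos(phi_c) * math.sin(dlam)
    s_z = r_c * math.sin(phi_c)
    return s_x, s_y, s_z, H


def geodetic_to_scan(loc: GeodeticLocation, sat: SatelliteSpec) -> ScanAngleCoord:
    """Forward projection: geodetic location -> fixed-grid scan angles.

    Raises :class:`NotVisibleError` when the location lies beyond the limb.
    """
    s_x, s_y, s_z, H = _sat_frame_position(loc, sat)
    ell = sat.ellipsoid
    # Limb test: the ray from the satellite to the point must not pass
    # through the ellipsoid before reaching it.
    if H * (H - s_x) < s_y * s_y + ell.flattening_sq * s_z * s_z:
        raise NotVisibleError(
            f"location ({loc.latitude_deg}, {loc.longitude_deg}) is beyond the "
            f"limb of {sat.name or 'the satellite'} at "
            f"{sat.sub_satellite_longitude_deg} deg"
        )
    norm = math.sqrt(s_x * s_x + s_y * s_y + s_z * s_z)
    y = math.atan2(s_z, s_x)
    x = math.asin(-s_y / norm)
    return ScanAngleCoord(x, y)


def scan_to_geodetic(scan: ScanAngleCoord, sat: SatelliteSpec) -> GeodeticLocation:
    """Inverse projection: scan angles -> geodetic location on the ellipsoid.

    Returns the near-side intersection of the view ray with the ellipsoid
    (elevation 0).  Raises :class:`OffEarthError` if the ray misses Earth.
    """
    ell = sat.ellipsoid
    H = sat.geocentric_distance_m
    x, y = scan.x_rad, scan.y_rad
    sinx, cosx = math.sin(x), math.cos(x)
    siny, cosy = math.sin(y), math.cos(y)
    a = sinx * sinx + cosx * cosx * (cosy * cosy + ell.flattening_sq * siny * siny)
    b = -2.0 * H * cosx * cosy
    c = H * H - ell.semi_major_axis_m ** 2
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        raise OffEarthError(f"scan angle ({x}, {y}) rad does not intersect Earth")
    r_s = (-b - math.sqrt(disc)) / (2.0 * a)  # near-side root
    s_x = r_s * cosx * cosy
    s_y = -r_s * sinx
    s_z = r_s * cosx * siny
    lat = math.degrees(
        math.atan(ell.flattening_sq * s_z / math.hypot(H - s_x, s_y))
    )
    lon = sat.sub_satellite_longitude_deg - math.degrees(math.atan2(s_y, H - s_x))
    if lon > 180.0:
        lon -= 360.0
    elif lon < -180.0:
        lon += 360.0
    return GeodeticLocation(lat, lon, 0.0)


# ---------------------------------------------------------------------------
# view geometry and parallax
# ---------------------------------------------------------------------------

def _ecef(loc: GeodeticLocation, ell: EllipsoidModel) -> np.ndarray:
    phi = math.radians(loc.latitude_deg)
    lam = math.radians(loc.longitude_deg)
    e2 = ell.eccentricity ** 2
    n = ell.semi_major_axis_m / math.sqrt(1.0 - e2 * math.sin(phi) ** 2)
    z = loc.elevation_m
    return np.array(
        [
            (n + z) * math.cos(phi) * math.cos(lam),
            (n + z) * math.cos(phi) * math.sin(lam),
            (n * (1.0 - e2) + z) * math.sin(phi),
        ]
    )


def _satellite_ecef(sat: SatelliteSpec) -> np.ndarray:
    lam0 = math.radians(sat.sub_satellite_longitude_deg)
    H = sat.geocentric_distance_m
    return np.array([H * math.cos(lam0), H * math.sin(lam0), 0.0])


def view_geometry(loc: GeodeticLocation, sat: SatelliteSpec) -> ViewGeometry:
    """View zenith/azimuth, slant range, and the parallax-shifted location.

    The parallax-corrected location is where the fixed grid *perceives* an
    elevation-``z`` target to be: the intersection of the satellite ray
    through the raised point with the sea-level ellipsoid.
    """
    scan = geodetic_to_scan(loc, sat)  # raises NotVisibleError off-disk

    ell = sat.ellipsoid
    surface = _ecef(replace(loc, elevation_m=0.0), ell)
    sat_pos = _satellite_ecef(sat)
    to_sat = sat_pos - surface
    rng = float(np.linalg.norm(to_sat))
    to_sat = to_sat / rng

    phi = math.radians(loc.latitude_deg)
    lam = math.radians(loc.longitude_deg)
    up = np.array(
        [math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)]
    )
    east = np.array([-math.sin(lam), math.cos(lam), 0.0])
    north = np.cross(up, east)

    cos_vza = float(np.clip(np.dot(to_sat, up), -1.0, 1.0))
    vza = math.degrees(math.acos(cos_vza))
    vaa = math.degrees(math.atan2(np.dot(to_sat, east), np.dot(to_sat, north))) % 360.0

    if loc.elevation_m == 0.0 or vza == 0.0:
        corrected = GeodeticLocation(loc.latitude_deg, loc.longitude_deg, 0.0)
        parallax = 0.0
    else:
        corrected = scan_to_geodetic(scan, sat)
        chord = _ecef(corrected, ell) - surface
        parallax = float(np.linalg.norm(chord))
    return ViewGeometry(vza, vaa, parallax, corrected, slant_range_m=rng)


# ---------------------------------------------------------------------------
# pixel matching, polygons, areas
# ---------------------------------------------------------------------------

def pixel_for_location(
    loc: GeodeticLocation, sat: SatelliteSpec, grid: FixedGridSpec
) -> tuple[int, int]:
    """(row, col) of the fixed-grid cell containing the target.

    The parallax-shifted scan angle is used, so an elevated target is
    matched to the pixel in which the satellite actually perceives it.
    Cells are half-open intervals [centre - res/2, centre + res/2) in scan
    angle, with boundary ties going to the higher index.
    """
    scan = geodetic_to_scan(loc, sat)
    res = grid.resolution_rad
    col = math.floor((scan.x_rad - grid.x_offset_rad) / res + 0.5)
    row = math.floor((grid.y_offset_rad - scan.y_rad) / res + 0.5)
    if not (0 <= col < grid.n_cols and 0 <= row < grid.n_rows):
        raise IndexError(f"scan angle falls outside the grid: row={row} col={col}")
    return row, col


def pixel_center(
    pix: tuple[int, int], grid: FixedGridSpec
) -> ScanAngleCoord:
    row, col = pix
    return ScanAngleCoord(float(grid.x_center(col)), float(grid.y_center(row)))


def pixel_polygon_at(
    center: ScanAngleCoord, resolution_rad: float, sat: SatelliteSpec
) -> list[GeodeticLocation]:
    """Ground corners of the scan-angle cell centred at ``center``.

    Corners are returned counter-clockwise in the lon/lat plane
    (SW, SE, NE, NW as seen on a map for a northern-hemisphere pixel).
    """
    h = resolution_rad / 2.0
    corners_scan = [
        ScanAngleCoord(center.x_rad - h, center.y_rad - h),
        ScanAngleCoord(center.x_rad + h, center.y_rad - h),
        ScanAngleCoord(center.x_rad + h, center.y_rad + h),
        ScanAngleCoord(center.x_rad - h, center.y_rad + h),
    ]
    try:
        return [scan_to_geodetic(c, sat) for c in corners_scan]
    except OffEarthError as exc:
        raise PixelTruncatedError(f"pixel truncated by the limb: {exc}") from exc


def pixel_polygon(
    pix: tuple[int, int], sat: SatelliteSpec, grid: FixedGridSpec
) -> list[GeodeticLocation]:
    return pixel_polygon_at(pixel_center(pix, grid), grid.resolution_rad, sat)


def _polygon_signed_area_m2(
    corners: list[GeodeticLocation], ell: EllipsoidModel
) -> float:
    """Signed ellipsoid-surface area via the equal-area (authalic) sphere.

    Vertices are mapped to authalic latitudes, the polygon is fanned into
    spherical triangles, and each triangle's signed excess is evaluated with
    the van Oosterom-Strackee formula.  Positive area means the vertices run
    counter-clockwise seen from outside the sphere.
    """
    R = ell.authalic_radius_m()
    units = []
    for c in corners:
        xi = ell.authalic_latitude_rad(c.latitude_deg)
        lam = math.radians(c.longitude_deg)
        units.append(
            np.array(
                [
                    math.cos(xi) * math.cos(lam),
                    math.cos(xi) * math.sin(lam),
                    math.sin(xi),
                ]
            )
        )
    total = 0.0
    a = units[0]
    for i in range(1, len(units) - 1):
        b, c = units[i], units[i + 1]
        num = float(np.dot(a, np.cross(b, c)))
        den = 1.0 + float(np.dot(a, b) + np.dot(b, c) + np.dot(c, a))
        total += 2.0 * math.atan2(num, den)
    return total * R * R


def polygon_area_km2(corners: list[GeodeticLocation], ell: EllipsoidModel = GRS80) -> float:
    return abs(_polygon_signed_area_m2(corners, ell)) / 1e6


def polygon_is_ccw(corners: list[GeodeticLocation], ell: EllipsoidModel = GRS80) -> bool:
    return _polygon_signed_area_m2(corners, ell) > 0.0


def pixel_area_km2(
    target: tuple[int, int] | GeodeticLocation,
    sat: SatelliteSpec,
    grid: FixedGridSpec,
) -> float:
    """Ellipsoid-surface area (km^2) of a fixed-grid pixel.

    ``target`` may be a (row, col) index pair or a location, in which case
    the containing pixel (after parallax correction) is used.
    """
    if isinstance(target, GeodeticLocation):
        target = pixel_for_location(target, sat, grid)
    corners = pixel_polygon(target, sat, grid)
    return polygon_area_km2(corners, sat.ellipsoid)


# ---------------------------------------------------------------------------
# site constants (the per-site static record)
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = [
    "SITE_ID",
    "TIMEZONE",
    "SITE_LAT",
    "SITE_LON",
    "ELEVATION",
    "PIXEL_AREA",
    "CORRECTED_LAT",
    "CORRECTED_LON",
    "VAA",
    "VZA",
    "PARALLAX",
    "VEGETATION_IGBP",
    "CLIMATE_KOEPPEN",
]


def site_constants(
    loc: GeodeticLocation,
    sat: SatelliteSpec,
    grid: FixedGridSpec,
    site_id: str = "",
    vegetation_igbp: str | int | None = None,
    climate_koeppen: str | None = None,
    timezone: str = "",
) -> dict:
    """One row of the static per-site table (geometry + metadata)."""
    view = view_geometry(loc, sat)
    area = pixel_area_km2(loc, sat, grid)
    return {
        "SITE_ID": site_id,
        "TIMEZONE": timezone,
        "SITE_LAT": loc.latitude_deg,
        "SITE_LON": loc.longitude_deg,
        "ELEVATION": loc.elevation_m,
        "PIXEL_AREA": area,
        "CORRECTED_LAT": view.corrected.latitude_deg,
        "CORRECTED_LON": view.corrected.longitude_deg,
        "VAA": view.vaa_deg,
        "VZA": view.vza_deg,
        "PARALLAX": view.parallax_m,
        "VEGETATION_IGBP": vegetation_igbp,
        "CLIMATE_KOEPPEN": climate_koeppen,
    }
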