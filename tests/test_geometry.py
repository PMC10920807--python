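"""Fixed-grid projection, view geometry, parallax, and pixel footprints."""

import math

import numpy as np
import pytest

from abitower.geometry import (
    EllipsoidModel,
    FixedGridSpec,
    GeodeticLocation,
    GOES_EAST,
    NotVisibleError,
    OffEarthError,
    PixelTruncatedError,
    SatelliteSpec,
    ScanAngleCoord,
    SITE_TABLE_COLUMNS,
    geodetic_to_scan,
    pixel_area_km2,
    pixel_center,
    pixel_for_location,
    pixel_polygon,
    pixel_polygon_at,
    polygon_is_ccw,
    scan_to_geodetic,
    site_constants,
    view_geometry,
)

# Published fixed-grid worked example: (33.846162 N, 84.690932 W) maps to
# scan angles (-0.024052, 0.095340) rad for a satellite at 75.0 W.
PUG_SAT = SatelliteSpec(-75.0)
PUG_LOC = GeodeticLocation(33.846162, -84.690932, 0.0)
PUG_SCAN = ScanAngleCoord(-0.024052, 0.095340)

MADISON = GeodeticLocation(43.07, -89.40, 0.0)
SEATTLE = GeodeticLocation(47.61, -122.33, 0.0)


def _ecef_geocentric_raised(loc, sat):
    """Target position raised by z along the geocentric radius (ECEF)."""
    ell = sat.ellipsoid
    e2 = ell.eccentricity**2
    phi = math.radians(loc.latitude_deg)
    lam = math.radians(loc.longitude_deg)
    phi_c = math.atan((1 - e2) * math.tan(phi))
    r_c = ell.semi_minor_axis_m / math.sqrt(1 - e2 * math.cos(phi_c) ** 2)
    r = r_c + loc.elevation_m
    return np.array(
        [
            r * math.cos(phi_c) * math.cos(lam),
            r * math.cos(phi_c) * math.sin(lam),
            r * math.sin(phi_c),
        ]
    )


def _ray_intersection_oracle(loc, sat):
    """Numerically intersect the satellite->elevated-target ray with the
    sea-level ellipsoid (independent of the closed-form inverse)."""
    from scipy.optimize import brentq

    ell = sat.ellipsoid
    lam0 = math.radians(sat.sub_satellite_longitude_deg)
    sat_pos = np.array(
        [
            sat.geocentric_distance_m * math.cos(lam0),
            sat.geocentric_distance_m * math.sin(lam0),
            0.0,
        ]
    )
    target = _ecef_geocentric_raised(loc, sat)
    direction = target - sat_pos

    def f(t):
        p = sat_pos + t * direction
        return (
            (p[0] ** 2 + p[1] ** 2) / ell.semi_major_axis_m**2
            + p[2] ** 2 / ell.semi_minor_axis_m**2
            - 1.0
        )

    # the sea-level intersection lies just beyond the elevated target
    t_hit = brentq(f, 1.0 - 1e-12, 1.02, xtol=1e-15)
    p = sat_pos + t_hit * direction
    lat_c = math.atan2(p[2], math.hypot(p[0], p[1]))
    lat = math.degrees(math.atan(math.tan(lat_c) / (1 - ell.eccentricity**2)))
    lon = math.degrees(math.atan2(p[1], p[0]))
    return lat, lon


class TestProjection:
    def test_sub_satellite_point_is_grid_origin(self):
        scan = geodetic_to_scan(GeodeticLocation(0.0, -75.2, 0.0), GOES_EAST)
        assert scan.x_rad == pytest.approx(0.0, abs=1e-12)
        assert scan.y_rad == pytest.approx(0.0, abs=1e-12)

    def test_forward_matches_published_worked_example(self):
        scan = geodetic_to_scan(PUG_LOC, PUG_SAT)
        assert round(scan.x_rad, 6) == PUG_SCAN.x_rad
        assert round(scan.y_rad, 6) == PUG_SCAN.y_rad

    def test_inverse_matches_published_worked_example(self):
        loc = scan_to_geodetic(PUG_SCAN, PUG_SAT)
        assert loc.latitude_deg == pytest.approx(PUG_LOC.latitude_deg, abs=5e-6)
        assert loc.longitude_deg == pytest.approx(PUG_LOC.longitude_deg, abs=5e-6)

    def test_nadir_scan_maps_to_sub_satellite_point(self):
        loc = scan_to_geodetic(ScanAngleCoord(0.0, 0.0), GOES_EAST)
        assert loc.latitude_deg == pytest.approx(0.0, abs=1e-12)
        assert loc.longitude_deg == pytest.approx(-75.2, abs=1e-12)

    def test_round_trip_on_lattice(self):
        for lat in np.linspace(-62.0, 62.0, 10):
            for lon in np.linspace(-140.0, -12.0, 10):
                p = GeodeticLocation(float(lat), float(lon), 0.0)
                back = scan_to_geodetic(geodetic_to_scan(p, GOES_EAST), GOES_EAST)
                assert back.latitude_deg == pytest.approx(lat, abs=1e-6)
                assert back.longitude_deg == pytest.approx(lon, abs=1e-6)

    def test_scan_round_trip_tight(self):
        p = GeodeticLocation(43.07, -89.40, 0.0)
        scan = geodetic_to_scan(p, GOES_EAST)
        again = geodetic_to_scan(scan_to_geodetic(scan, GOES_EAST), GOES_EAST)
        assert again.x_rad == pytest.approx(scan.x_rad, abs=1e-9)
        assert again.y_rad == pytest.approx(scan.y_rad, abs=1e-9)

    def test_far_side_location_not_visible(self):
        with pytest.raises(NotVisibleError):
            geodetic_to_scan(GeodeticLocation(0.0, 100.0, 0.0), GOES_EAST)

    def test_off_earth_scan_angle(self):
        with pytest.raises(OffEarthError):
            scan_to_geodetic(ScanAngleCoord(0.2, 0.0), GOES_EAST)

    def test_ellipsoid_eccentricity_consistent(self):
        ell = EllipsoidModel()
        expected = math.sqrt(
            1 - (ell.semi_minor_axis_m / ell.semi_major_axis_m) ** 2
        )
        assert ell.eccentricity == pytest.approx(expected, abs=1e-12)


class TestViewGeometry:
    def test_nadir_view(self):
        view = view_geometry(GeodeticLocation(0.0, -75.2, 250.0), GOES_EAST)
        assert view.vza_deg == pytest.approx(0.0, abs=1e-6)
        assert view.parallax_m == pytest.approx(0.0, abs=0.1)

    def test_sea_level_target_has_no_parallax(self):
        view = view_geometry(MADISON, GOES_EAST)
        assert view.parallax_m == 0.0
        assert view.corrected.latitude_deg == MADISON.latitude_deg
        assert view.corrected.longitude_deg == MADISON.longitude_deg

    def test_parallax_close_to_tangent_approximation(self):
        loc = GeodeticLocation(43.07, -89.40, 1000.0)
        view = view_geometry(loc, GOES_EAST)
        approx = 1000.0 * math.tan(math.radians(view.vza_deg))
        assert view.parallax_m == pytest.approx(approx, rel=0.02)

    def test_corrected_location_matches_ray_intersection_oracle(self):
        loc = GeodeticLocation(43.07, -89.40, 1200.0)
        view = view_geometry(loc, GOES_EAST)
        lat, lon = _ray_intersection_oracle(loc, GOES_EAST)
        assert view.corrected.latitude_deg == pytest.approx(lat, abs=1e-5)
        assert view.corrected.longitude_deg == pytest.approx(lon, abs=1e-5)

    def test_parallax_strictly_increases_with_elevation(self):
        values = [
            view_geometry(
                GeodeticLocation(43.07, -89.40, z), GOES_EAST
            ).parallax_m
            for z in (100.0, 500.0, 1500.0, 3000.0)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_vza_increases_away_from_nadir(self):
        vzas = [
            view_geometry(GeodeticLocation(lat, -75.2, 0.0), GOES_EAST).vza_deg
            for lat in (0.0, 10.0, 25.0, 40.0, 55.0)
        ]
        assert vzas[0] == pytest.approx(0.0, abs=1e-6)
        assert all(a < b for a, b in zip(vzas, vzas[1:]))


class TestPixelMatching:
    def test_pixel_center_maps_to_own_pixel(self, goes_east, full_grid_2km):
        pix = (1500, 2000)
        center = pixel_center(pix, full_grid_2km)
        loc = scan_to_geodetic(center, goes_east)
        assert pixel_for_location(loc, goes_east, full_grid_2km) == pix

    def test_nearby_locations_share_a_pixel(self, goes_east, full_grid_2km):
        a = pixel_for_location(MADISON, goes_east, full_grid_2km)
        nudged = GeodeticLocation(43.0701, -89.4001, 0.0)
        assert pixel_for_location(nudged, goes_east, full_grid_2km) == a

    def test_elevation_can_shift_the_matched_pixel(self, goes_east, full_grid_2km):
        flat = pixel_for_location(MADISON, goes_east, full_grid_2km)
        # ~3.2 km ground shift at VZA 52 deg crosses a 2-km cell boundary
        tall = pixel_for_location(
            GeodeticLocation(43.07, -89.40, 2500.0), goes_east, full_grid_2km
        )
        assert tall != flat
        assert abs(tall[0] - flat[0]) <= 2 and abs(tall[1] - flat[1]) <= 2


class TestPixelFootprints:
    def test_nadir_pixel_corners_symmetric(self, goes_east):
        corners = pixel_polygon_at(ScanAngleCoord(0.0, 0.0), 56e-6, goes_east)
        lats = [c.latitude_deg for c in corners]
        lons = [c.longitude_deg - (-75.2) for c in corners]
        assert sorted(round(v, 9) for v in lats) == sorted(
            round(-v, 9) for v in lats
        )
        assert sorted(round(v, 9) for v in lons) == sorted(
            round(-v, 9) for v in lons
        )

    def test_corner_round_trip_reproduces_cell_edges(self, goes_east, full_grid_2km):
        pix = pixel_for_location(MADISON, goes_east, full_grid_2km)
        center = pixel_center(pix, full_grid_2km)
        h = full_grid_2km.resolution_rad / 2
        corners = pixel_polygon(pix, goes_east, full_grid_2km)
        expected = {
            (round(center.x_rad - h, 12), round(center.y_rad - h, 12)),
            (round(center.x_rad + h, 12), round(center.y_rad - h, 12)),
            (round(center.x_rad + h, 12), round(center.y_rad + h, 12)),
            (round(center.x_rad - h, 12), round(center.y_rad + h, 12)),
        }
        for c in corners:
            scan = geodetic_to_scan(c, goes_east)
            match = min(
                expected,
                key=lambda e: abs(e[0] - scan.x_rad) + abs(e[1] - scan.y_rad),
            )
            assert scan.x_rad == pytest.approx(match[0], abs=1e-9)
            assert scan.y_rad == pytest.approx(match[1], abs=1e-9)

    def test_polygons_counter_clockwise(self, goes_east, full_grid_2km):
        rng = np.random.default_rng(42)
        count = 0
        while count < 50:
            row = int(rng.integers(500, 4900))
            col = int(rng.integers(500, 4900))
            try:
                corners = pixel_polygon((row, col), goes_east, full_grid_2km)
            except PixelTruncatedError:
                continue
            assert polygon_is_ccw(corners)
            count += 1

    def test_limb_pixel_truncated(self, goes_east):
        with pytest.raises(PixelTruncatedError):
            pixel_polygon_at(ScanAngleCoord(0.0, 0.15134), 56e-6, goes_east)


class TestPixelAreas:
    def test_nadir_area_is_four_km2(self, goes_east):
        area = pixel_area_km2(GeodeticLocation(0.0, -75.2, 0.0), goes_east,
                              FixedGridSpec.full_disk("2km"))
        assert area == pytest.approx(4.0, abs=0.2)

    @pytest.mark.parametrize(
        "loc,printed", [(MADISON, 7.2), (SEATTLE, 14.3)],
        ids=["madison", "seattle"],
    )
    def test_printed_city_pixel_areas(self, goes_east, full_grid_2km, loc, printed):
        area = pixel_area_km2(loc, goes_east, full_grid_2km)
        assert area == pytest.approx(printed, rel=0.05)

    def test_nadir_area_matches_flat_estimate(self, goes_east):
        nominal = (goes_east.perspective_height_m * 56e-6) ** 2 / 1e6
        area = pixel_area_km2(GeodeticLocation(0.0, -75.2, 0.0), goes_east,
                              FixedGridSpec.full_disk("2km"))
        assert area == pytest.approx(nominal, rel=0.05)

    def test_area_increases_along_vza_transect(self, goes_east, full_grid_2km):
        areas = [
            pixel_area_km2(GeodeticLocation(lat, -75.2, 0.0), goes_east,
                           full_grid_2km)
            for lat in (0.0, 15.0, 30.0, 45.0, 60.0)
        ]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_area_matches_slant_range_oracle_below_60_deg(
        self, goes_east, full_grid_2km
    ):
        nominal = (goes_east.perspective_height_m * 56e-6) ** 2 / 1e6
        for lat, lon in [(0.0, -75.2), (20.0, -90.0), (43.07, -89.40), (35.0, -110.0)]:
            loc = GeodeticLocation(lat, lon, 0.0)
            view = view_geometry(loc, goes_east)
            assert view.vza_deg < 60.0
            oracle = (
                (view.slant_range_m / goes_east.perspective_height_m) ** 2
                * nominal
                / math.cos(math.radians(view.vza_deg))
            )
            area = pixel_area_km2(loc, goes_east, full_grid_2km)
            assert area == pytest.approx(oracle, rel=0.02)


class TestSiteConstants:
    def test_columns_match_site_table_schema(self, goes_east, full_grid_2km):
        row = site_constants(MADISON, goes_east, full_grid_2km, site_id="US-XYZ")
        assert list(row.keys()) == SITE_TABLE_COLUMNS

    def test_sub_satellite_site_trivial_geometry(self, goes_east, full_grid_2km):
        row = site_constants(
            GeodeticLocation(0.0, -75.2, 0.0), goes_east, full_grid_2km
        )
        assert row["VZA"] == pytest.approx(0.0, abs=1e-6)
        assert row["PARALLAX"] == 0.0
        assert row["CORRECTED_LAT"] == row["SITE_LAT"]
        assert row["CORRECTED_LON"] == row["SITE_LON"]

    def test_corrected_coordinates_match_oracle(self, goes_east, full_grid_2km):
        loc = GeodeticLocation(43.07, -89.40, 800.0)
        row = site_constants(loc, goes_east, full_grid_2km)
        lat, lon = _ray_intersection_oracle(loc, goes_east)
        assert row["CORRECTED_LAT"] == pytest.approx(lat, abs=1e-5)
        assert row["CORRECTED_LON"] == pytest.approx(lon, abs=1e-5)
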