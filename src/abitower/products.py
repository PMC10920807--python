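"""Readers and writers for L2 scenes, the DSR geographic grid, tower CSVs,
and the half-hourly output tables.

Scene files follow the operational layout: one variable grid per product
variable, a per-pixel DQF grid, packed-integer storage with
``scale_factor``/``add_offset``/``_FillValue`` attributes, scaled-integer
scan-angle coordinates, and a projection variable carrying the
sub-satellite longitude, perspective height, and ellipsoid axes.  Files are
written through xarray's scipy (netCDF-3) engine so no binary tooling
beyond scipy is needed.

Tower files follow the half-hourly flux-network convention: interval
start/end timestamps in local standard time (``YYYYMMDDHHMM``), sentinel
-9999 for missing.  Records are keyed by interval END to match the
satellite record's end-of-interval stamping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .geometry import (
    FixedGridSpec,
    GeodeticLocation,
    SatelliteSpec,
    SITE_TABLE_COLUMNS,
)

__all__ = [
    "ProductScene",
    "LatLonGrid",
    "TowerSeries",
    "SiteInfo",
    "FormatError",
    "CoverageError",
    "SchemaError",
    "TABLE2_COLUMNS",
    "PRODUCT_VARIABLES",
    "DQF_FOR_VARIABLE",
    "read_l2_scene",
    "write_l2_scene",
    "extract_pixel",
    "extract_latlon",
    "read_tower_csv",
    "write_tower_csv",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_site_table",
]


class FormatError(ValueError):
    """A scene file is missing required structure or metadata."""


class CoverageError(ValueError):
    """A queried location falls outside a scene's grid extent."""


class SchemaError(ValueError):
    """An output table is missing mandatory columns."""


# ---------------------------------------------------------------------------
# output schema (the dynamic half-hourly record)
# ---------------------------------------------------------------------------

_CMI_BANDS = [f"{b:02d}" for b in range(1, 17)]

#: Physical/dqf variables carried by each product's scenes.
PRODUCT_VARIABLES: dict[str, list[str]] = {
    "ADP": ["ADP_aero", "ADP_smk", "ADP_dust"],
    "AOD": ["AOD"],
    "BRF": ["BRF1", "BRF2", "BRF3", "BRF5", "BRF6"],
    "ACM": ["ACM"],
    "CMI": [f"CMI_C{b}" for b in _CMI_BANDS],
    "DSR": ["DSR"],
    "LSA": ["LSA"],
    "LST": ["LST"],
}

#: DQF column accompanying each dynamic variable (CMI has one per band).
DQF_FOR_VARIABLE: dict[str, str] = {
    **{v: "ADP_DQF" for v in PRODUCT_VARIABLES["ADP"]},
    "AOD": "AOD_DQF",
    **{v: "BRF_DQF" for v in PRODUCT_VARIABLES["BRF"]},
    "ACM": "ACM_DQF",
    **{f"CMI_C{b}": f"DQF_C{b}" for b in _CMI_BANDS},
    "DSR": "DSR_DQF",
    "LSA": "LSA_DQF",
    "LST": "LST_DQF",
}

TABLE2_COLUMNS: list[str] = (
    ["ADP_aero", "ADP_smk", "ADP_dust", "ADP_DQF", "AOD", "AOD_DQF"]
    + PRODUCT_VARIABLES["BRF"]
    + ["BRF_DQF", "ACM", "ACM_DQF"]
    + PRODUCT_VARIABLES["CMI"]
    + [f"DQF_C{b}" for b in _CMI_BANDS]
    + ["DSR", "DSR_DQF", "LSA", "LSA_DQF", "LST", "LST_DQF"]
    + ["NDVI", "NIRv", "PAR", "NIRvP"]
    + ["SAA", "SZA", "SOLAR_POS"]
    + ["UTC_TIME", "LOCAL_TIME", "DOY", "HOUR"]
)

_TIMESTAMP_COLUMNS = ("UTC_TIME", "LOCAL_TIME")
_DQF_COLUMNS = tuple(c for c in TABLE2_COLUMNS if "DQF" in c)


# ---------------------------------------------------------------------------
# grids and scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatLonGrid:
    """Regular geographic grid; row 0 is the northernmost cell centre."""

    lat0_deg: float
    lon0_deg: float
    dlat_deg: float
    dlon_deg: float
    n_lat: int
    n_lon: int

    def cell_for(self, loc: GeodeticLocation) -> tuple[int, int]:
        i = round((self.lat0_deg - loc.latitude_deg) / self.dlat_deg)
        j = round((loc.longitude_deg - self.lon0_deg) / self.dlon_deg)
        if not (0 <= i < self.n_lat and 0 <= j < self.n_lon):
            raise CoverageError(
                f"({loc.latitude_deg}, {loc.longitude_deg}) outside grid extent"
            )
        return int(i), int(j)

    @property
    def lats(self) -> np.ndarray:
        return self.lat0_deg - np.arange(self.n_lat) * self.dlat_deg

    @property
    def lons(self) -> np.ndarray:
        return self.lon0_deg + np.arange(self.n_lon) * self.dlon_deg


@dataclass
class ProductScene:
    """One timestamped raster of one L2 product at one satellite."""

    product_id: str
    timestamp_utc: pd.Timestamp
    satellite: SatelliteSpec | None
    grid: FixedGridSpec | LatLonGrid
    data: dict[str, np.ndarray]
    dqf: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamp_utc = pd.Timestamp(self.timestamp_utc)
        if self.timestamp_utc.tzinfo is None:
            self.timestamp_utc = self.timestamp_utc.tz_localize("UTC")
        shapes = {a.shape for a in self.data.values()} | {
            a.shape for a in self.dqf.values()
        }
        if len(shapes) > 1:
            raise ValueError(f"inconsistent grid shapes in scene: {shapes}")


def extract_pixel(scene: ProductScene, pix: tuple[int, int]) -> dict[str, float]:
    """Values and flags of one (row, col) cell as a flat mapping."""
    row, col = pix
    shape = next(iter(scene.data.values())).shape
    if not (0 <= row < shape[0] and 0 <= col < shape[1]):
        raise IndexError(f"pixel {pix} outside scene of shape {shape}")
    out = {name: arr[row, col] for name, arr in scene.data.items()}
    out.update({name: arr[row, col] for name, arr in scene.dqf.items()})
    return out


def extract_latlon(scene: ProductScene, loc: GeodeticLocation) -> dict[str, float]:
    """Nearest-cell lookup on a geographic-grid scene (no interpolation)."""
    if not isinstance(scene.grid, LatLonGrid):
        raise TypeError("extract_latlon needs a scene on a geographic grid")
    return extract_pixel(scene, scene.grid.cell_for(loc))


# ---------------------------------------------------------------------------
# netCDF-style scene files
# ---------------------------------------------------------------------------

_FILL_INT32 = np.int32(-2147483647)
_DATA_SCALE = 1e-6  # quantisation of packed physical values


def write_l2_scene(scene: ProductScene, path) -> None:
    """Write a scene in the operational-style packed netCDF layout."""
    grid = scene.grid
    coords: dict = {}
    encodings: dict = {}
    if isinstance(grid, FixedGridSpec):
        x = grid.x_offset_rad + np.arange(grid.n_cols) * grid.resolution_rad
        y = grid.y_offset_rad - np.arange(grid.n_rows) * grid.resolution_rad
        coords["y"] = ("y", y, {"units": "rad", "axis": "Y"})
        coords["x"] = ("x", x, {"units": "rad", "axis": "X"})
        # scaled-integer scan-angle coordinates, as in the real files
        encodings["x"] = {
            "dtype": "int32",
            "scale_factor": grid.resolution_rad,
            "add_offset": grid.x_offset_rad,
            "_FillValue": _FILL_INT32,
        }
        encodings["y"] = {
            "dtype": "int32",
            "scale_factor": -grid.resolution_rad,
            "add_offset": grid.y_offset_rad,
            "_FillValue": _FILL_INT32,
        }
        dims = ("y", "x")
    else:
        coords["lat"] = ("lat", grid.lats, {"units": "degrees_north"})
        coords["lon"] = ("lon", grid.lons, {"units": "degrees_east"})
        dims = ("lat", "lon")

    data_vars: dict = {}
    for name, arr in scene.data.items():
        data_vars[name] = (dims, np.asarray(arr, dtype=float))
        encodings[name] = {
            "dtype": "int32",
            "scale_factor": _DATA_SCALE,
            "add_offset": 0.0,
            "_FillValue": _FILL_INT32,
        }
    for name, arr in scene.dqf.items():
        data_vars[name] = (dims, np.asarray(arr, dtype=np.int16))

    if isinstance(grid, FixedGridSpec):
        if scene.satellite is None:
            raise FormatError("fixed-grid scene requires a satellite spec")
        sat = scene.satellite
        data_vars["goes_imager_projection"] = (
            (),
            np.int32(0),
            {
                "grid_mapping_name": "geostationary",
                "longitude_of_projection_origin": sat.sub_satellite_longitude_deg,
                "perspective_point_height": sat.perspective_height_m,
                "semi_major_axis": sat.ellipsoid.semi_major_axis_m,
                "semi_minor_axis": sat.ellipsoid.semi_minor_axis_m,
                "sweep_angle_axis": "x",
            },
        )

    ds = xr.Dataset(
        data_vars,
        coords=coords,
        attrs={
            "product_id": scene.product_id,
            "time_coverage_start": scene.timestamp_utc.strftime(
                "%Y-%m-%dT%H:%M:%S.%f"
            )[:-3]
            + "Z",
            "resolution_rad": (
                grid.resolution_rad if isinstance(grid, FixedGridSpec) else 0.0
            ),
        },
    )
    for name, enc in encodings.items():
        ds[name].encoding.update(enc)
    ds.to_netcdf(path, engine="scipy")


def _grid_from_coords(ds: xr.Dataset) -> FixedGridSpec:
    x = ds["x"].values
    y = ds["y"].values
    res = float(ds.attrs.get("resolution_rad") or 0.0)
    if res <= 0.0:
        if len(x) < 2:
            raise FormatError("cannot infer scan-angle resolution from one column")
        res = float(abs(x[1] - x[0]))
    return FixedGridSpec(res, float(x[0]), float(y[0]), len(x), len(y))


def read_l2_scene(path) -> ProductScene:
    """Read a scene file back to physical units.

    Packed values are unscaled and fill values become NaN.  A fixed-grid
    file without projection metadata is rejected; a product without a
    shipped DQF schema is read with its flags passed through untouched and
    a warning.
    """
    with xr.open_dataset(path, engine="scipy", decode_cf=True) as ds:
        ds = ds.load()
    product_id = str(ds.attrs.get("product_id", ""))
    if not product_id:
        raise FormatError(f"{path}: missing product_id attribute")
    tstr = ds.attrs.get("time_coverage_start")
    if not tstr:
        raise FormatError(f"{path}: missing time_coverage_start attribute")
    timestamp = pd.Timestamp(str(tstr).rstrip("Z")).tz_localize("UTC")

    if "x" in ds.coords and "y" in ds.coords:
        if "goes_imager_projection" not in ds:
            raise FormatError(f"{path}: fixed-grid scene lacks projection metadata")
        proj = ds["goes_imager_projection"].attrs
        try:
            from .geometry import EllipsoidModel

            sat = SatelliteSpec(
                float(proj["longitude_of_projection_origin"]),
                float(proj["perspective_point_height"]),
                EllipsoidModel(
                    float(proj["semi_major_axis"]), float(proj["semi_minor_axis"])
                ),
            )
        except KeyError as exc:
            raise FormatError(f"{path}: projection metadata missing {exc}") from exc
        grid: FixedGridSpec | LatLonGrid = _grid_from_coords(ds)
    elif "lat" in ds.coords and "lon" in ds.coords:
        lats = ds["lat"].values
        lons = ds["lon"].values
        grid = LatLonGrid(
            float(lats[0]),
            float(lons[0]),
            float(abs(lats[1] - lats[0])) if len(lats) > 1 else 1.0,
            float(lons[1] - lons[0]) if len(lons) > 1 else 1.0,
            len(lats),
            len(lons),
        )
        sat = None
    else:
        raise FormatError(f"{path}: no recognisable grid coordinates")

    from .dqf import available_schemas

    if product_id.lower() not in available_schemas():
        warnings.warn(
            f"no DQF schema shipped for product {product_id!r}; "
            "flags passed through undecoded",
            stacklevel=2,
        )

    data: dict[str, np.ndarray] = {}
    dqf: dict[str, np.ndarray] = {}
    for name, var in ds.data_vars.items():
        if name == "goes_imager_projection":
            continue
        if "DQF" in name:
            dqf[name] = var.values.astype(np.int16)
        else:
            data[name] = var.values.astype(float)
    return ProductScene(product_id, timestamp, sat, grid, data, dqf)


# ---------------------------------------------------------------------------
# tower files
# ---------------------------------------------------------------------------

@dataclass
class TowerSeries:
    """Half-hourly (or hourly, flagged) tower records keyed by interval end
    in local standard time."""

    site_id: str
    utc_offset_hours: float
    data: pd.DataFrame
    interval_minutes: int = 30

    @property
    def is_hourly(self) -> bool:
        return self.interval_minutes == 60


def read_tower_csv(path, utc_offset_hours: float, site_id: str = "") -> TowerSeries:
    df = pd.read_csv(path, na_values=[-9999, "-9999", "-9999.0"])
    for col in ("TIMESTAMP_START", "TIMESTAMP_END"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing {col} column")
        df[col] = pd.to_datetime(df[col].astype("int64").astype(str), format="%Y%m%d%H%M")
    end = df["TIMESTAMP_END"]
    bad = np.flatnonzero(end.diff().dt.total_seconds().iloc[1:].to_numpy() <= 0)
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad[:10])
        raise FormatError(f"{path}: non-monotone TIMESTAMP_END at row(s) {rows}")
    if end.duplicated().any():
        raise FormatError(f"{path}: duplicate TIMESTAMP_END values")
    step = (df["TIMESTAMP_END"] - df["TIMESTAMP_START"]).dt.total_seconds() / 60.0
    interval = int(step.mode().iloc[0]) if len(step) else 30
    if interval not in (30, 60):
        raise FormatError(f"{path}: unsupported interval of {interval} minutes")
    out = df.set_index("TIMESTAMP_END").drop(columns=["TIMESTAMP_START"])
    out.index.name = "TIMESTAMP_END"
    return TowerSeries(site_id or str(path), utc_offset_hours, out, interval)


def write_tower_csv(series: TowerSeries, path) -> None:
    df = series.data.copy()
    idx = df.index
    df.insert(0, "TIMESTAMP_END", idx.strftime("%Y%m%d%H%M"))
    start = idx - pd.Timedelta(minutes=series.interval_minutes)
    df.insert(0, "TIMESTAMP_START", start.strftime("%Y%m%d%H%M"))
    df = df.fillna(-9999)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# site metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteInfo:
    """A tower site: identity, location, and fixed local-time offset."""

    site_id: str
    location: GeodeticLocation
    utc_offset_hours: float
    timezone: str = ""
    vegetation_igbp: str | int | None = None
    climate_koeppen: str | None = None


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def _format_timestamp(ts) -> str:
    if pd.isna(ts):
        return ""
    ts = pd.Timestamp(ts)
    if ts.tzinfo is not None:
        ts = ts.tz_localize(None)
    return ts.strftime("%Y-%m-%d %H:%M:%S.") + f"{ts.microsecond // 1000:03d}"


def write_timeseries_csv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write the half-hourly record with the exact output column set.

    Missing values are serialised as empty fields; timestamps as
    ``yyyy-mm-dd hh:mm:ss.ms``.  Column order is fixed and byte-stable.
    """
    missing = [c for c in TABLE2_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    out = df.loc[:, TABLE2_COLUMNS].copy()
    for col in _TIMESTAMP_COLUMNS:
        out[col] = out[col].map(_format_timestamp)
    out.to_csv(path, index=False, float_format=float_format, na_rep="")


def read_timeseries_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _TIMESTAMP_COLUMNS:
        df[col] = pd.to_datetime(df[col])
    return df


def write_site_table(rows: list[dict], path, float_format: str = "%.6g") -> None:
    """Write the static per-site constants table."""
    df = pd.DataFrame(rows)
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    df.loc[:, SITE_TABLE_COLUMNS].to_csv(
        path, index=False, float_format=float_format, na_rep=""
    )
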