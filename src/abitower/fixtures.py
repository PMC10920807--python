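"""Deterministic synthetic scenes and tower series with known ground truth.

The generator emulates the data the pipeline consumes offline: fixed-grid
scenes at the ten-minute full-disk cadence (surface reflectance, imagery,
cloud mask, aerosol detection), hourly snapshot products (downward
shortwave on a geographic grid, surface temperature), and a half-hourly
flux-tower file — all driven by one seeded random generator so identical
configurations yield identical outputs.

The generative model is intentionally simple and fully known:

* clear-sky downward shortwave is ``amplitude * max(0, cos SZA)``;
  a per-half-hour Bernoulli cloud state multiplies it by an attenuation
  factor;
* canopy state follows a seasonal NDVI sinusoid; red reflectance is
  derived from NDVI and a fixed NIR reflectance;
* surface temperature follows the solar cycle around a base temperature;
* the tower sees the same radiation truth through a configurable noise
  model (multiplicative shortwave, additive longwave), and its GPP is
  proportional to NIRvP plus noise;
* quality flags are written from the generative state (clear daytime 8,
  cloudy daytime 16, nighttime 26 for reflectances; snow spans set the
  aerosol-detection snow bit).

Ground truth is returned per site on the half-hourly record lattice.
Hourly products carry truth only on their top-of-hour anchors: the :30
values in the assembled record are interpolation *estimates* by
construction and have no independent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dqf import encode_bitmask, load_schema
from .geometry import (
    FixedGridSpec,
    GeodeticLocation,
    GOES_EAST,
    SatelliteSpec,
    pixel_for_location,
)
from .indices import PAR_FRACTION_OF_DSR
from .products import LatLonGrid, ProductScene, SiteInfo, TowerSeries, write_l2_scene
from .solar import DAYTIME_SZA_THRESHOLD_DEG, solar_angles
from .stats import DEFAULT_EMISSIVITY, STEFAN_BOLTZMANN

__all__ = ["FixtureConfig", "FixtureResult", "generate_scene_stack",
           "generate_tower_series", "golden_small_case", "GOLDEN_SEED"]

GOLDEN_SEED = 20240301

# Two neighbouring mid-latitude towers (a forest/grassland pair ~25 km
# apart, as in paired-site flux studies) so the shared scene window stays
# small while the sites still occupy distinct fixed-grid pixels.
_DEFAULT_SITES = (
    SiteInfo("SYN-WI", GeodeticLocation(43.07, -89.40, 300.0), -6.0, "CST-6",
             "DBF", "Dfb"),
    SiteInfo("SYN-PR", GeodeticLocation(43.20, -89.10, 280.0), -6.0, "CST-6",
             "GRA", "Dfb"),
)


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic benchmark."""

    seed: int = 0
    sites: tuple[SiteInfo, ...] = _DEFAULT_SITES
    start: str = "2022-06-01"
    days: int = 3
    products: tuple[str, ...] = ("BRF", "CMI", "ACM", "ADP", "DSR", "LST")
    satellite: SatelliteSpec = GOES_EAST

    # diurnal radiation model
    dsr_amplitude_w_m2: float = 1000.0
    cloud_probability: float = 0.3
    cloud_attenuation: float = 0.35

    # surface model
    ndvi_base: float = 0.55
    ndvi_amplitude: float = 0.25
    ndvi_peak_doy: int = 200
    nir_reflectance: float = 0.35
    lst_base_k: float = 286.0
    lst_amplitude_k: float = 14.0

    # noise model (tower side)
    sw_noise_sd: float = 0.05  # multiplicative, fraction of signal
    lw_noise_sd_w_m2: float = 5.0  # additive
    gpp_noise_sd: float = 1.0  # additive, umol m^-2 s^-1
    gpp_per_nirvp: float = 0.12  # umol m^-2 s^-1 per W m^-2

    # data-quality blemishes
    dsr_invalid_probability: float = 0.02
    snow_span: tuple[str, str] | None = None

    # grids
    grid_margin_pixels: int = 3
    dsr_grid_resolution_deg: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.cloud_probability <= 1.0:
            raise ValueError("cloud probability must be in [0, 1]")
        if not 0.0 <= self.dsr_invalid_probability <= 1.0:
            raise ValueError("invalid-DQF probability must be in [0, 1]")
        if self.dsr_amplitude_w_m2 <= 0:
            raise ValueError("shortwave amplitude must be positive")

    def noiseless(self) -> "FixtureConfig":
        return replace(self, sw_noise_sd=0.0, lw_noise_sd_w_m2=0.0,
                       gpp_noise_sd=0.0, dsr_invalid_probability=0.0)


@dataclass
class FixtureResult:
    scenes: list[ProductScene]
    truth: dict[str, pd.DataFrame]
    grid: FixedGridSpec
    dsr_grid: LatLonGrid
    pixels: dict[str, tuple[int, int]]
    config: FixtureConfig


# ---------------------------------------------------------------------------
# deterministic site model
# ---------------------------------------------------------------------------

def _window_ends(cfg: FixtureConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(cfg.start)
    return pd.date_range(start + pd.Timedelta(minutes=30),
                         start + pd.Timedelta(days=cfg.days), freq="30min")


def _site_model(cfg: FixtureConfig, site: SiteInfo, rng: np.random.Generator) -> pd.DataFrame:
    """Per-half-hour generative state and truth for one site.

    Indexed by UTC window end.  Cloud and snow states are per window; the
    instantaneous shortwave/temperature models are also evaluated at the
    top-of-hour anchor times used by the hourly products.
    """
    ends = _window_ends(cfg)
    sza_end = solar_angles(site.location, ends).sza_deg
    cloudy = rng.random(len(ends)) < cfg.cloud_probability
    dsr_bad = rng.random(len(ends)) < cfg.dsr_invalid_probability

    doy = ends.dayofyear.to_numpy()
    ndvi = cfg.ndvi_base + cfg.ndvi_amplitude * np.cos(
        2 * np.pi * (doy - cfg.ndvi_peak_doy) / 365.25
    )
    nir = np.full_like(ndvi, cfg.nir_reflectance)
    red = nir * (1.0 - ndvi) / (1.0 + ndvi)

    atten = np.where(cloudy, cfg.cloud_attenuation, 1.0)
    cos_sza = np.clip(np.cos(np.radians(sza_end)), 0.0, None)
    dsr_inst = cfg.dsr_amplitude_w_m2 * cos_sza * atten
    lst_inst = cfg.lst_base_k + cfg.lst_amplitude_k * cos_sza

    daytime = sza_end < DAYTIME_SZA_THRESHOLD_DEG
    snowy = np.zeros(len(ends), dtype=bool)
    if cfg.snow_span is not None:
        lo, hi = (pd.Timestamp(t) for t in cfg.snow_span)
        snowy = (ends >= lo) & (ends <= hi + pd.Timedelta(days=1))

    brf_available = daytime  # retrieval runs (clear or cloudy path) in daylight
    truth_ndvi = np.where(brf_available & ~cloudy & ~snowy, ndvi, np.nan)
    truth_nirv = truth_ndvi * nir

    # hourly-product truth lives only on its top-of-hour anchors
    on_hour = ends.minute == 0
    truth_dsr = np.where(on_hour & ~dsr_bad, dsr_inst, np.nan)
    truth_lst = np.where(on_hour & ~cloudy, lst_inst, np.nan)

    return pd.DataFrame(
        {
            "SZA": sza_end,
            "cloudy": cloudy,
            "snowy": snowy,
            "daytime": daytime,
            "dsr_dqf_invalid": dsr_bad,
            "NDVI_state": ndvi,
            "RED": red,
            "NIR": nir,
            "DSR_inst": dsr_inst,
            "LST_inst": lst_inst,
            "NDVI": truth_ndvi,
            "NIRv": truth_nirv,
            "DSR": truth_dsr,
            "LST": truth_lst,
        },
        index=ends,
    )


def _models(cfg: FixtureConfig) -> dict[str, pd.DataFrame]:
    """Deterministic per-site models; one child rng stream per site."""
    root = np.random.default_rng(cfg.seed)
    streams = root.spawn(len(cfg.sites))
    return {
        site.site_id: _site_model(cfg, site, stream)
        for site, stream in zip(cfg.sites, streams)
    }


# ---------------------------------------------------------------------------
# scene materialisation
# ---------------------------------------------------------------------------

def _window_grid(cfg: FixtureConfig) -> tuple[FixedGridSpec, dict[str, tuple[int, int]]]:
    """A small fixed-grid window covering all sites, cut from the full disk."""
    full = FixedGridSpec.full_disk("2km")
    pix = {
        s.site_id: pixel_for_location(s.location, cfg.satellite, full)
        for s in cfg.sites
    }
    rows = [p[0] for p in pix.values()]
    cols = [p[1] for p in pix.values()]
    m = cfg.grid_margin_pixels
    r0, c0 = min(rows) - m, min(cols) - m
    grid = FixedGridSpec(
        full.resolution_rad,
        float(full.x_center(c0)),
        float(full.y_center(r0)),
        max(cols) - c0 + m + 1,
        max(rows) - r0 + m + 1,
    )
    local = {sid: (r - r0, c - c0) for sid, (r, c) in pix.items()}
    if grid.n_rows * grid.n_cols > 100_000:
        raise ValueError(
            "fixture sites span too large a fixed-grid window "
            f"({grid.n_rows} x {grid.n_cols}); use closer sites or separate configs"
        )
    return grid, local


def _dsr_grid(cfg: FixtureConfig) -> LatLonGrid:
    lats = [s.location.latitude_deg for s in cfg.sites]
    lons = [s.location.longitude_deg for s in cfg.sites]
    d = cfg.dsr_grid_resolution_deg
    lat0 = max(lats) + 2 * d
    lon0 = min(lons) - 2 * d
    n_lat = int(np.ceil((lat0 - (min(lats) - 2 * d)) / d)) + 1
    n_lon = int(np.ceil(((max(lons) + 2 * d) - lon0) / d)) + 1
    return LatLonGrid(lat0, lon0, d, d, n_lat, n_lon)


def _brf_dqf_value(daytime: bool, cloudy: bool, schema) -> int:
    if not daytime:
        # no retrieval, nighttime
        return encode_bitmask({"sza": 1, "retrieval_path": 3}, schema)
    if cloudy:
        return encode_bitmask({"retrieval_path": 2}, schema)  # cloudy path
    return encode_bitmask({"retrieval_path": 1}, schema)  # clear-sky path


def generate_scene_stack(cfg: FixtureConfig, out_dir=None) -> FixtureResult:
    """Materialise the configured products as scenes plus ground truth.

    Scenes are returned in memory; with ``out_dir`` each is also written
    as a netCDF file named ``<product>_<timestamp>.nc``.
    """
    models = _models(cfg)
    grid, pixels = _window_grid(cfg)
    dsr_grid = _dsr_grid(cfg)
    brf_schema = load_schema("brf")
    adp_schema = load_schema("adp")
    sat = cfg.satellite

    start = pd.Timestamp(cfg.start)
    scan_times = pd.date_range(start, start + pd.Timedelta(days=cfg.days),
                               freq="10min", inclusive="left")
    hour_times = pd.date_range(start, start + pd.Timedelta(days=cfg.days),
                               freq="h", inclusive="left")

    # a scan belongs to the half-hour window whose end follows its start;
    # an hourly anchor carries the state of the window ending at it
    windows = {
        sid: m.index.searchsorted(scan_times, side="right")
        for sid, m in models.items()
    }
    hour_windows = {
        sid: np.minimum(m.index.searchsorted(hour_times, side="left"), len(m) - 1)
        for sid, m in models.items()
    }
    hour_sza = {
        site.site_id: solar_angles(site.location, hour_times).sza_deg
        for site in cfg.sites
    }

    shape = (grid.n_rows, grid.n_cols)
    dshape = (dsr_grid.n_lat, dsr_grid.n_lon)
    scenes: list[ProductScene] = []

    def fill(per_site: dict[str, float], background: float, target_shape, sites_pix):
        arr = np.full(target_shape, background, dtype=float)
        for sid, value in per_site.items():
            r, c = sites_pix[sid]
            arr[r, c] = value
        return arr

    dsr_pixels = {
        s.site_id: dsr_grid.cell_for(s.location) for s in cfg.sites
    }

    for k, t in enumerate(scan_times):
        per_site_state = {}
        for sid, m in models.items():
            w = min(windows[sid][k], len(m) - 1)
            per_site_state[sid] = m.iloc[w]

        if "BRF" in cfg.products:
            vals = {b: {} for b in ("BRF1", "BRF2", "BRF3", "BRF5", "BRF6")}
            dq = {}
            for sid, row in per_site_state.items():
                present = bool(row["daytime"])
                dq[sid] = _brf_dqf_value(present, bool(row["cloudy"]), brf_schema)
                red, nir = float(row["RED"]), float(row["NIR"])
                band_vals = {
                    "BRF1": 0.06, "BRF2": red, "BRF3": nir,
                    "BRF5": 0.22, "BRF6": 0.16,
                }
                for b, v in band_vals.items():
                    vals[b][sid] = v if present else np.nan
            scenes.append(ProductScene(
                "brf", t, sat, grid,
                {b: fill(vals[b], np.nan, shape, pixels) for b in vals},
                {"BRF_DQF": fill(dq, 26, shape, pixels).astype(np.int16)},
            ))

        if "CMI" in cfg.products:
            data, dq = {}, {}
            for band, base in (("CMI_C01", 0.08), ("CMI_C02", None), ("CMI_C03", None)):
                per = {}
                for sid, row in per_site_state.items():
                    if band == "CMI_C02":
                        surf = float(row["RED"])
                    elif band == "CMI_C03":
                        surf = float(row["NIR"])
                    else:
                        surf = base
                    toa = 0.62 if row["cloudy"] else surf + 0.04
                    per[sid] = toa
                data[band] = fill(per, 0.1, shape, pixels)
                dq[f"DQF_{band[4:]}"] = np.zeros(shape, dtype=np.int16)
            scenes.append(ProductScene("cmi", t, sat, grid, data, dq))

        if "ACM" in cfg.products:
            per = {sid: float(bool(row["cloudy"]))
                   for sid, row in per_site_state.items()}
            scenes.append(ProductScene(
                "acm", t, sat, grid,
                {"ACM": fill(per, 0.0, shape, pixels)},
                {"ACM_DQF": np.zeros(shape, dtype=np.int16)},
            ))

        if "ADP" in cfg.products:
            aero, dq = {}, {}
            for sid, row in per_site_state.items():
                aero[sid] = 0.0
                dq[sid] = encode_bitmask(
                    {"snow_ice_cloud": int(bool(row["snowy"]) or bool(row["cloudy"]))},
                    adp_schema,
                )
            scenes.append(ProductScene(
                "adp", t, sat, grid,
                {
                    "ADP_aero": fill(aero, 0.0, shape, pixels),
                    "ADP_smk": np.zeros(shape),
                    "ADP_dust": np.zeros(shape),
                },
                {"ADP_DQF": fill(dq, 0, shape, pixels).astype(np.int16)},
            ))

    for k, t in enumerate(hour_times):
        anchor_state = {
            sid: m.iloc[int(hour_windows[sid][k])] for sid, m in models.items()
        }
        if "DSR" in cfg.products:
            vals, dq = {}, {}
            for sid, row in anchor_state.items():
                atten = cfg.cloud_attenuation if row["cloudy"] else 1.0
                cos_sza = max(0.0, float(np.cos(np.radians(hour_sza[sid][k]))))
                vals[sid] = cfg.dsr_amplitude_w_m2 * cos_sza * atten
                dq[sid] = int(row["dsr_dqf_invalid"])
            scenes.append(ProductScene(
                "dsr", t, None, dsr_grid,
                {"DSR": fill(vals, 0.0, dshape, dsr_pixels)},
                {"DSR_DQF": fill(dq, 0, dshape, dsr_pixels).astype(np.int16)},
            ))
        if "LST" in cfg.products:
            vals, dq = {}, {}
            for sid, row in anchor_state.items():
                cos_sza = max(0.0, float(np.cos(np.radians(hour_sza[sid][k]))))
                lst = cfg.lst_base_k + cfg.lst_amplitude_k * cos_sza
                cloudy = bool(row["cloudy"])
                vals[sid] = np.nan if cloudy else lst
                dq[sid] = 2 if cloudy else 0  # cloud bit of the provisional layout
            scenes.append(ProductScene(
                "lst", t, sat, grid,
                {"LST": fill(vals, cfg.lst_base_k, shape, pixels)},
                {"LST_DQF": fill(dq, 0, shape, pixels).astype(np.int16)},
            ))

    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for scene in scenes:
            stamp = scene.timestamp_utc.strftime("%Y%m%dT%H%M%S")
            write_l2_scene(scene, out / f"{scene.product_id}_{stamp}.nc")

    truth = {}
    last_anchor = hour_times[-1]
    for sid, m in models.items():
        table = m.copy()
        # no anchor scene exists past the last generated hour
        beyond = table.index > last_anchor
        table.loc[beyond, ["DSR", "LST"]] = np.nan
        table["PAR"] = table["DSR"] * PAR_FRACTION_OF_DSR
        table["NIRvP"] = table["NIRv"] * table["PAR"]
        truth[sid] = table

    return FixtureResult(scenes, truth, grid, dsr_grid, pixels, cfg)


# ---------------------------------------------------------------------------
# tower series
# ---------------------------------------------------------------------------

def generate_tower_series(cfg: FixtureConfig, site_id: str | None = None,
                          out_path=None) -> tuple[TowerSeries, pd.DataFrame]:
    """Half-hourly tower file consistent with the scene truth.

    SW_IN is the instantaneous shortwave model at the record timestamp
    times multiplicative noise; LW_IN/LW_OUT invert the longwave surface
    temperature estimator at emissivity 0.98 around the temperature truth;
    GPP is proportional to NIRvP truth plus additive noise.
    """
    models = _models(cfg)
    if site_id is None:
        site_id = cfg.sites[0].site_id
    site = next(s for s in cfg.sites if s.site_id == site_id)
    m = models[site_id]
    rng = np.random.default_rng(np.random.default_rng(cfg.seed + 1).integers(2**31))

    n = len(m)
    sw = m["DSR_inst"].to_numpy() * (1.0 + cfg.sw_noise_sd * rng.standard_normal(n))
    lst = m["LST_inst"].to_numpy()
    eps, sigma = DEFAULT_EMISSIVITY, STEFAN_BOLTZMANN
    lw_in = np.full(n, 320.0) + cfg.lw_noise_sd_w_m2 * rng.standard_normal(n)
    lw_out = eps * sigma * lst**4 + (1.0 - eps) * lw_in \
        + cfg.lw_noise_sd_w_m2 * rng.standard_normal(n)
    par = m["DSR_inst"].to_numpy() * PAR_FRACTION_OF_DSR
    nirvp_true = np.nan_to_num(m["NDVI_state"].to_numpy() * m["NIR"].to_numpy()) * par
    gpp = cfg.gpp_per_nirvp * nirvp_true + cfg.gpp_noise_sd * rng.standard_normal(n)

    local_end = m.index + pd.Timedelta(hours=site.utc_offset_hours)
    df = pd.DataFrame(
        {"SW_IN": sw, "LW_IN": lw_in, "LW_OUT": lw_out, "GPP": gpp},
        index=pd.DatetimeIndex(local_end, name="TIMESTAMP_END"),
    )
    series = TowerSeries(site_id, site.utc_offset_hours, df, 30)

    truth = pd.DataFrame(
        {
            "SW_IN_true": m["DSR_inst"].to_numpy(),
            "LST_true": lst,
            "NIRvP_true": nirvp_true,
        },
        index=df.index,
    )
    if out_path is not None:
        from .products import write_tower_csv

        write_tower_csv(series, out_path)
    return series, truth


def golden_small_case() -> FixtureConfig:
    """The bundled miniature benchmark: two sites, three days, no noise.

    The expected pipeline outputs for this configuration are committed
    under ``tests/data/golden`` and serve as a regression reference.
    """
    return FixtureConfig(seed=GOLDEN_SEED, days=3,
                         snow_span=None).noiseless()
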