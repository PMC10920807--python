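"""Temporal fusion: per-scene pixel extractions -> half-hourly records.

The satellite scans the full disk every ten minutes, so three scans fall in
each half-hour window; they are averaged and stamped at the window END,
matching the end-of-interval convention of half-hourly flux-tower files.
Products issued only hourly (DSR, LST) are top-of-hour snapshots; the :30
values between two *consecutive* present hours are filled by monotone
piecewise-cubic interpolation and flagged, and gaps of an hour or more are
never filled.

Window assignment uses the scan START time: scans starting in
[H:00, H:30) belong to the window ending H:30, and the :30 scan opens the
next window.  A window's quality flag is the worst (numerically largest)
flag among the scans that contributed a value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from .dqf import load_schema, snow_mask
from .geometry import FixedGridSpec, pixel_for_location, view_geometry
from .indices import ndvi, nirv, nirvp, par_from_dsr
from .products import (
    DQF_FOR_VARIABLE,
    LatLonGrid,
    ProductScene,
    PRODUCT_VARIABLES,
    SiteInfo,
    TABLE2_COLUMNS,
    extract_latlon,
    extract_pixel,
)
from .solar import solar_angles

__all__ = [
    "CadenceError",
    "WindowError",
    "QualityPolicy",
    "default_policy",
    "no_filtering_policy",
    "halfhour_average",
    "upsample_hourly",
    "apply_quality_filters",
    "assemble_site_timeseries",
    "HOURLY_PRODUCTS",
    "BRF_VZA_LIMIT_DEG",
]

#: Products issued once per hour as top-of-hour snapshots.
HOURLY_PRODUCTS = ("DSR", "LST")

#: The surface-reflectance retrieval stops at this view zenith angle.
BRF_VZA_LIMIT_DEG = 70.0

_BRF_COLUMNS = ("BRF1", "BRF2", "BRF3", "BRF5", "BRF6")
_INDEX_COLUMNS = ("NDVI", "NIRv", "PAR", "NIRvP")


class CadenceError(ValueError):
    """Input series does not have the expected time step."""


class WindowError(ValueError):
    """A scan falls outside the half-hour window being averaged."""


# ---------------------------------------------------------------------------
# half-hour averaging
# ---------------------------------------------------------------------------

def _window_end(ts: pd.Timestamp) -> pd.Timestamp:
    """End stamp of the half-hour window containing scan-start ``ts``."""
    return ts.floor("30min") + pd.Timedelta(minutes=30)


def halfhour_average(scans, is_valid=None) -> dict | None:
    """Average the scans of one half-hour window.

    ``scans`` is an iterable of ``(timestamp, value, dqf)`` triples whose
    timestamps (scan starts) must all fall in the same half-open window
    [H:00, H:30) or [H:30, H+1:00).  ``is_valid(value, dqf)`` may exclude
    scans from the mean; by default any scan with a finite value counts.

    Returns ``{"utc_time": window_end, "value": mean, "dqf": worst,
    "n_scans": k}`` or None for a window with no scans at all.  ``value``
    is NaN when no scan is valid; ``dqf`` is the maximum flag over
    contributing scans (over all scans when none contributed).
    """
    scans = [(pd.Timestamp(t), v, q) for t, v, q in scans]
    if not scans:
        return None
    ends = {_window_end(t) for t, _, _ in scans}
    if len(ends) > 1:
        raise WindowError(f"scans span multiple half-hour windows: {sorted(ends)}")
    if is_valid is None:
        is_valid = lambda v, q: np.isfinite(v)  # noqa: E731
    valid = [(v, q) for _, v, q in scans if is_valid(v, q)]
    if valid:
        value = float(np.mean([v for v, _ in valid]))
        dqf = max(q for _, q in valid)
    else:
        value = float("nan")
        dqf = max(q for _, _, q in scans)
    return {
        "utc_time": ends.pop(),
        "value": value,
        "dqf": dqf,
        "n_scans": len(valid),
    }


# ---------------------------------------------------------------------------
# hourly -> half-hourly upsampling
# ---------------------------------------------------------------------------

def upsample_hourly(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Insert :30 values between consecutive present top-of-hour anchors.

    Interpolation is monotone piecewise-cubic (PCHIP) over each maximal run
    of consecutive hourly anchors, so anchors are reproduced exactly,
    linear stretches interpolate linearly, and inserted values never
    overshoot their bracketing anchors.  Where either bracketing hour is
    missing nothing is inserted.

    Returns ``(half_hourly_values, interpolated_flag)`` on the union of
    anchor and inserted timestamps.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise CadenceError("hourly input must be indexed by timestamps")
    anchors = series.dropna().sort_index()
    offset = anchors.index.minute * 60 + anchors.index.second
    if len(anchors) and (offset != 0).any():
        raise CadenceError("hourly snapshots must fall exactly on the hour")

    out_idx: list[pd.Timestamp] = list(anchors.index)
    out_val: list[float] = [float(v) for v in anchors.to_numpy()]
    interp_flag = [False] * len(anchors)

    if len(anchors) >= 2:
        times = anchors.index
        gaps = (times[1:] - times[:-1]) / pd.Timedelta(hours=1)
        # maximal runs of consecutive hours
        run_start = 0
        for i, gap in enumerate(list(gaps) + [np.inf]):
            if gap == 1.0:
                continue
            run = slice(run_start, i + 1)
            run_start = i + 1
            if run.stop - run.start < 2:
                continue
            t_run = times[run]
            v_run = anchors.to_numpy()[run]
            hours = (t_run - t_run[0]) / pd.Timedelta(hours=1)
            spline = PchipInterpolator(np.asarray(hours, float), v_run)
            mid_hours = np.asarray(hours[:-1], float) + 0.5
            mids = spline(mid_hours)
            for h, v in zip(mid_hours, mids):
                out_idx.append(t_run[0] + pd.Timedelta(hours=float(h)))
                out_val.append(float(v))
                interp_flag.append(True)

    values = pd.Series(out_val, index=pd.DatetimeIndex(out_idx)).sort_index()
    flags = pd.Series(interp_flag, index=pd.DatetimeIndex(out_idx)).sort_index()
    return values, flags


# ---------------------------------------------------------------------------
# quality policy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityPolicy:
    """Which flag predicates blank which columns.

    Raw flag columns are always retained; filtering only sets the affected
    value columns to missing.
    """

    brf_keep_dqf: tuple[int, ...] = (8,)
    dsr_drop_dqf: tuple[int, ...] = (1,)
    snow_mask_indices: bool = True
    enabled: bool = True

    @classmethod
    def from_yaml(cls, path) -> "QualityPolicy":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown quality-policy key(s): {sorted(unknown)}")
        for key in ("brf_keep_dqf", "dsr_drop_dqf"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def default_policy() -> QualityPolicy:
    """Clear-sky daytime reflectances, valid DSR, snow-masked indices."""
    return QualityPolicy()


def no_filtering_policy() -> QualityPolicy:
    return QualityPolicy(enabled=False)


def apply_quality_filters(records: pd.DataFrame, policy: QualityPolicy | None = None) -> pd.DataFrame:
    """Blank value columns whose flags fail the policy.

    BRF bands survive only where BRF_DQF is in the keep set (clear-sky
    daytime retrievals); DSR is dropped where its flag marks an invalid or
    degraded observation; the NIRv family is dropped where the Aerosol
    Detection flag reports snow/ice/cloud-invalid.  Flag columns and all
    other products are untouched.
    """
    if policy is None:
        policy = default_policy()
    out = records.copy()
    if not policy.enabled:
        return out

    if "BRF_DQF" in out.columns:
        flags = out["BRF_DQF"]
        keep = flags.isin(policy.brf_keep_dqf)
        for col in _BRF_COLUMNS:
            if col in out.columns:
                out.loc[~keep, col] = np.nan
    if "DSR_DQF" in out.columns:
        drop = out["DSR_DQF"].isin(policy.dsr_drop_dqf)
        if "DSR" in out.columns:
            out.loc[drop, "DSR"] = np.nan
    if policy.snow_mask_indices and "ADP_DQF" in out.columns:
        schema = load_schema("adp")
        adp = out["ADP_DQF"]
        snowy = adp.notna() & adp.map(
            lambda v: snow_mask(int(v), schema) if np.isfinite(v) else False
        )
        for col in _INDEX_COLUMNS:
            if col in out.columns and col != "PAR":
                out.loc[snowy, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

def _grid_key(grid) -> tuple:
    if isinstance(grid, FixedGridSpec):
        return ("fixed", grid.resolution_rad, grid.x_offset_rad, grid.y_offset_rad,
                grid.n_cols, grid.n_rows)
    return ("latlon", grid.lat0_deg, grid.lon0_deg, grid.dlat_deg, grid.dlon_deg,
            grid.n_lat, grid.n_lon)


def _extract_stack(site: SiteInfo, scenes: list[ProductScene]) -> pd.DataFrame:
    """One row per scene with that scene's pixel values at the site."""
    pix_cache: dict[tuple, tuple[int, int]] = {}
    rows = []
    for scene in scenes:
        key = _grid_key(scene.grid)
        if isinstance(scene.grid, LatLonGrid):
            values = extract_latlon(scene, site.location)
        else:
            if key not in pix_cache:
                pix_cache[key] = pixel_for_location(
                    site.location, scene.satellite, scene.grid
                )
            values = extract_pixel(scene, pix_cache[key])
        row = {"timestamp": scene.timestamp_utc, "product": scene.product_id}
        row.update(values)
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_site_timeseries(
    site: SiteInfo,
    scenes: list[ProductScene],
    policy: QualityPolicy | None = None,
    start: pd.Timestamp | None = None,
    end: pd.Timestamp | None = None,
    include_provenance: bool = False,
) -> pd.DataFrame:
    """Build the half-hourly tower-aligned record for one site.

    Returns a DataFrame with the full dynamic output schema, one row per
    half-hour (stamped at interval end, UTC index).  ``start``/``end``
    bound the UTC interval-end range; by default the span of the provided
    scenes is used.  With ``include_provenance`` extra columns carry the
    per-product contributing-scan counts and interpolation flags.
    """
    if policy is None:
        policy = default_policy()
    if not scenes:
        raise ValueError("no scenes supplied")

    fixed_sats = [s.satellite for s in scenes if s.satellite is not None]
    sat = fixed_sats[0] if fixed_sats else None
    view = view_geometry(site.location, sat) if sat is not None else None
    brf_blocked = view is not None and view.vza_deg >= BRF_VZA_LIMIT_DEG
    if brf_blocked:
        warnings.warn(
            f"site {site.site_id or '?'}: VZA {view.vza_deg:.1f} deg is beyond "
            f"the {BRF_VZA_LIMIT_DEG:.0f} deg reflectance limit; BRF columns "
            "will be empty",
            stacklevel=2,
        )

    stack = _extract_stack(site, scenes)

    if start is None:
        start = _window_end(stack["timestamp"].min())
    if end is None:
        end = _window_end(stack["timestamp"].max())
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    if end.tzinfo is None:
        end = end.tz_localize("UTC")
    index = pd.date_range(start, end, freq="30min")
    out = pd.DataFrame(index=index, columns=TABLE2_COLUMNS, dtype=object)
    out.index.name = "utc_time_end"
    for col in TABLE2_COLUMNS:
        if col not in ("UTC_TIME", "LOCAL_TIME"):
            out[col] = np.nan

    for product, block in stack.groupby("product"):
        carried = PRODUCT_VARIABLES.get(product.upper())
        var_cols = [
            c for c in block.columns
            if c not in ("timestamp", "product")
            and "DQF" not in c
            and (carried is None or c in carried)
            and block[c].notna().any()
        ]
        dqf_cols = [c for c in block.columns if "DQF" in c and block[c].notna().any()]
        block = block.sort_values("timestamp")
        if product.upper() in HOURLY_PRODUCTS:
            on_hour = block[block["timestamp"].dt.minute == 0]
            for col in var_cols:
                hourly = pd.Series(
                    on_hour[col].to_numpy(dtype=float),
                    index=pd.DatetimeIndex(on_hour["timestamp"]),
                )
                values, interp = upsample_hourly(hourly)
                values = values.reindex(index)
                out[col] = values.to_numpy(dtype=float)
                if include_provenance:
                    out[f"{col}_INTERPOLATED"] = (
                        interp.reindex(index).fillna(False).to_numpy()
                    )
                dq = DQF_FOR_VARIABLE.get(col)
                if dq in dqf_cols:
                    dq_hourly = pd.Series(
                        on_hour[dq].to_numpy(dtype=float),
                        index=pd.DatetimeIndex(on_hour["timestamp"]),
                    ).reindex(index)
                    # interpolated half-hours inherit the worst bracketing flag
                    filled = np.fmax(dq_hourly.ffill(limit=1), dq_hourly.bfill(limit=1))
                    out[dq] = filled.where(values.notna()).to_numpy(dtype=float)
        else:
            wend = block["timestamp"].map(_window_end)
            grouped = block.assign(_wend=wend).groupby("_wend")
            for col in var_cols:
                mean = grouped[col].mean().reindex(index)
                out[col] = mean.to_numpy(dtype=float)
                if include_provenance:
                    out[f"{col}_N_SCANS"] = (
                        grouped[col].count().reindex(index).fillna(0).to_numpy(int)
                    )
            for dq in dqf_cols:
                carriers = [
                    c for c in var_cols if DQF_FOR_VARIABLE.get(c) == dq
                ]
                def worst(g: pd.DataFrame) -> float:
                    contributed = g[carriers].notna().any(axis=1) if carriers else (
                        pd.Series(False, index=g.index)
                    )
                    pool = g.loc[contributed, dq]
                    if not len(pool):
                        pool = g[dq]
                    return float(pool.max())
                agg = grouped[[dq] + carriers].apply(worst).reindex(index)
                out[dq] = agg.to_numpy(dtype=float)

    if brf_blocked:
        for col in _BRF_COLUMNS:
            out[col] = np.nan

    out = apply_quality_filters(out, policy)

    # derived indices, computed after fusion and flag filtering
    red = out["BRF2"].to_numpy(dtype=float)
    nir = out["BRF3"].to_numpy(dtype=float)
    out["NDVI"] = ndvi((red, nir))
    out["NIRv"] = nirv((red, nir))
    out["PAR"] = par_from_dsr(out["DSR"].to_numpy(dtype=float))
    out["NIRvP"] = nirvp(out["NIRv"].to_numpy(dtype=float),
                         out["PAR"].to_numpy(dtype=float))
    if policy.enabled and policy.snow_mask_indices and "ADP_DQF" in out.columns:
        schema = load_schema("adp")
        adp = out["ADP_DQF"]
        snowy = adp.notna() & adp.map(
            lambda v: snow_mask(int(v), schema) if np.isfinite(v) else False
        )
        for col in ("NDVI", "NIRv", "NIRvP"):
            out.loc[snowy, col] = np.nan

    naive_utc = index.tz_convert(None)
    angles = solar_angles(site.location, naive_utc)
    out["SZA"] = angles.sza_deg
    out["SAA"] = angles.saa_deg
    out["SOLAR_POS"] = angles.solar_pos_deg

    local = naive_utc + pd.Timedelta(hours=site.utc_offset_hours)
    out["UTC_TIME"] = naive_utc
    out["LOCAL_TIME"] = local
    out["DOY"] = (local.dayofyear - 1).to_numpy()  # 0-based day of year
    out["HOUR"] = local.hour.to_numpy()
    return out
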