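"""Environmental covariate extraction and design-matrix assembly.

Gridded covariates (SST, SSTA, CHL, CURL, depth, daily ice fraction) are
sampled at fix locations, forward-filled along each track, standardized
with pooled moments, reduced to yearly binary ice-presence layers, and
screened for collinearity before entering the movement model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import LineString

from .projection import haversine_km

#: temporal matching kinds for raster layers
TEMPORAL_KINDS = ("static", "daily", "6hourly", "monthly")


@dataclass
class Raster:
    """One covariate layer: an xarray DataArray with dims ([time,] lat, lon)."""

    data: xr.DataArray
    temporal: str = "static"

    def __post_init__(self):
        if self.temporal not in TEMPORAL_KINDS:
            raise ValueError(f"temporal must be one of {TEMPORAL_KINDS}")
        dims = set(self.data.dims)
        if not {"lat", "lon"} <= dims:
            raise ValueError("raster needs lat and lon dims")


@dataclass
class RasterStack:
    layers: dict = field(default_factory=dict)

    def __getitem__(self, name) -> Raster:
        return self.layers[name]

    def __contains__(self, name) -> bool:
        return name in self.layers


def _select_time(ras: Raster, when) -> xr.DataArray:
    da = ras.data
    if ras.temporal == "static" or "time" not in da.dims:
        return da
    times = pd.DatetimeIndex(da["time"].values)
    when = pd.Timestamp(when)
    if when.tzinfo is not None:
        when = when.tz_convert(None)
    if ras.temporal == "monthly":
        match = (times.year == when.year) & (times.month == when.month)
        idx = np.nonzero(match)[0]
        if len(idx) == 0:
            return None
        return da.isel(time=int(idx[0]))
    # daily / 6-hourly: nearest slice at or before the fix time
    pos = times.searchsorted(when, side="right") - 1
    if pos < 0:
        return None
    return da.isel(time=int(pos))


def sample_raster(ras: Raster, lon, lat, when=None) -> float:
    """Bilinear sample of one raster at a fix; NaN when off-grid/masked."""
    da = _select_time(ras, when)
    if da is None:
        return np.nan
    try:
        v = da.interp(lon=float(lon), lat=float(lat), method="linear")
    except (KeyError, ValueError):
        return np.nan
    return float(v)


def sample_track(stack: RasterStack, fixes: pd.DataFrame,
                 names: list[str]) -> pd.DataFrame:
    """Sample each named layer at every fix of a track.

    Returns a DataFrame indexed like ``fixes`` with one column per
    covariate; off-grid fixes yield NaN (counted in a warning).
    """
    out = {}
    n_missing = 0
    lons = fixes["lon"].to_numpy(dtype=float)
    lats = fixes["lat"].to_numpy(dtype=float)
    for name in names:
        ras = stack[name]
        if ras.temporal == "static" or "time" not in ras.data.dims:
            pts_lon = xr.DataArray(lons, dims="pt")
            pts_lat = xr.DataArray(lats, dims="pt")
            vals = ras.data.interp(lon=pts_lon, lat=pts_lat,
                                   method="linear").values.astype(float)
        else:
            vals = np.empty(len(fixes))
            for i, (_, row) in enumerate(fixes.iterrows()):
                vals[i] = sample_raster(ras, row["lon"], row["lat"],
                                        row.get("time"))
        n_missing += int(np.isnan(vals).sum())
        out[name] = vals
    if n_missing:
        warnings.warn(f"{n_missing} missing covariate samples (off-grid or masked)")
    return pd.DataFrame(out, index=fixes.index)


def forward_fill(series: pd.Series, animal_id: str = "?",
                 name: str = "?") -> pd.Series:
    """Fill internal gaps with the previous value; leading gaps take the
    first available value. Entirely-missing series raise."""
    if series.isna().all():
        raise ValueError(f"covariate {name!r} entirely missing for animal {animal_id!r}")
    return series.ffill().bfill()


def evenly_spaced_days(month_length: int, n: int = 10) -> list[int]:
    """Arithmetic day sequence starting day 1, step ceil(len/n), capped at n."""
    step = math.ceil(month_length / n)
    days = list(range(1, month_length + 1, step))[:n]
    return days


def build_ice_binary(daily_ice: Raster, year: int, month: int,
                     lons, lats, threshold: float = 0.0) -> np.ndarray:
    """0/1 ice presence per fix over ten evenly spaced days of a month.

    A location scores 1 iff the ice fraction exceeds ``threshold`` at the
    nearest grid cell on ANY sampled day of the given year/month.
    """
    da = daily_ice.data
    if "time" not in da.dims:
        raise ValueError("daily ice raster needs a time dimension")
    times = pd.DatetimeIndex(da["time"].values)
    in_month = (times.year == year) & (times.month == month)
    if in_month.sum() == 0:
        raise ValueError(f"no ice layers for {year}-{month:02d}")
    month_len = pd.Timestamp(year=year, month=month, day=1).days_in_month
    wanted = evenly_spaced_days(month_len)
    day_idx = [i for i in np.nonzero(in_month)[0] if times[i].day in wanted]
    if len(day_idx) == 0:
        raise ValueError(f"no sampled-day ice layers for {year}-{month:02d}")
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    present = np.zeros(len(lons), dtype=int)
    sub = da.isel(time=day_idx)
    samp = sub.sel(lon=xr.DataArray(lons, dims="pt"),
                   lat=xr.DataArray(lats, dims="pt"), method="nearest")
    present = (np.nan_to_num(samp.values) > threshold).any(axis=0).astype(int)
    return present


def densify_polyline(line: LineString, chord_km: float = 1.0) -> np.ndarray:
    """Vertices of the polyline with every segment split into <= chord_km
    great-circle chords (linear interpolation in lon/lat)."""
    coords = np.asarray(line.coords, dtype=float)
    pts = [coords[0]]
    for a, b in zip(coords[:-1], coords[1:]):
        d = float(haversine_km(a[0], a[1], b[0], b[1]))
        nseg = max(1, int(math.ceil(d / chord_km)))
        for s in range(1, nseg + 1):
            pts.append(a + (b - a) * (s / nseg))
    return np.asarray(pts)


def distance_to_front(lons, lats, front: LineString,
                      chord_km: float = 1.0) -> np.ndarray:
    """Minimum great-circle distance (metres) from fixes to a front polyline."""
    pts = densify_polyline(front, chord_km)
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    out = np.empty(len(lons))
    chunk = 500
    for start in range(0, len(lons), chunk):
        sl = slice(start, start + chunk)
        d = haversine_km(lons[sl, None], lats[sl, None],
                         pts[None, :, 0], pts[None, :, 1])
        out[sl] = d.min(axis=1)
    return out * 1000.0


@dataclass
class StandardizationSpec:
    """Pooled center/scale per continuous covariate."""

    params: dict = field(default_factory=dict)   # name -> (center, scale)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name, (c, s) in self.params.items():
            if name in out.columns:
                out[name] = (out[name] - c) / s
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name, (c, s) in self.params.items():
            if name in out.columns:
                out[name] = out[name] * s + c
        return out

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.params.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationSpec":
        return cls(params={k: (float(v[0]), float(v[1])) for k, v in d.items()})


def standardize(table: pd.DataFrame, continuous: list[str],
                binary: list[str] = ()) -> tuple[StandardizationSpec, pd.DataFrame]:
    """Pooled standardization (all animals, all fixes) of continuous
    covariates; binary covariates pass through unchanged."""
    spec = StandardizationSpec()
    for name in continuous:
        v = np.asarray(table[name], dtype=float)
        c = float(np.nanmean(v))
        s = float(np.nanstd(v, ddof=0))
        if s <= 0:
            raise ValueError(f"covariate {name!r} has zero pooled variance")
        spec.params[name] = (c, s)
    out = spec.transform(table)
    for name in binary:
        vals = set(pd.unique(out[name].dropna()))
        if not vals <= {0, 1, 0.0, 1.0}:
            raise ValueError(f"binary covariate {name!r} has non-0/1 values")
    return spec, out


def correlation_screen(table: pd.DataFrame, columns: list[str],
                       r_thresh: float = 0.5, p_thresh: float = 0.01) -> set:
    """Pairs of covariates too correlated to enter a model together.

    A pair is forbidden iff |Pearson r| >= r_thresh and p < p_thresh.
    Returns a set of frozensets.
    """
    from scipy import stats

    forbidden = set()
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            x = np.asarray(table[a], dtype=float)
            y = np.asarray(table[b], dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            if np.allclose(x[ok], y[ok]):
                forbidden.add(tuple(sorted((a, b))))   # r = 1 exactly
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            if abs(r) >= r_thresh and p < p_thresh:
                forbidden.add(tuple(sorted((a, b))))
    return forbidden
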