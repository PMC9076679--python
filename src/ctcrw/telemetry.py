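"""Telemetry ingestion, filtering, censoring and track summaries.

Argos-style satellite fixes are read into per-animal :class:`Track`
objects, cleaned with a speed filter, censored to the migratory/foraging
portion of each track (off the breeding shelf, reaching the Polar Front
at ~50°S), and summarised into per-animal deployment tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .projection import AzimuthalEquidistant

#: Argos location-class quality ranking, best first.
LC_ORDER = ["3", "2", "1", "0", "A", "B"]

TELEMETRY_COLUMNS = ["id", "date", "lc", "lon", "lat"]
META_COLUMNS = ["id", "sex", "calf", "role", "period"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass
class AnimalMeta:
    """Animal-level metadata and the binary group indicator.

    ``group_G`` encodes the model grouping: for sex grouping, mothers
    (females with calf) are G=1 and males+ (males and undetermined sex)
    are G=0; for tagging-period grouping, the second period is G=1.
    """

    animal_id: str
    sex: str = "U"            # F, M or U
    calf_present: bool = False
    social_role: str = "Un"   # Mo, Ad, Es, Un
    period: int = 1
    group_G: int = 0

    def group_for(self, scheme: str) -> int:
        if scheme == "sex":
            return 1 if self.sex == "F" else 0
        if scheme == "period":
            return 1 if self.period == 2 else 0
        if scheme == "none":
            return 0
        raise ValueError(f"unknown grouping scheme {scheme!r}")


@dataclass
class Track:
    """Ordered telemetry fixes for one animal."""

    meta: AnimalMeta
    fixes: pd.DataFrame = field(repr=False)
    censored: bool = False

    def __len__(self) -> int:
        return len(self.fixes)

    def copy(self) -> "Track":
        return Track(meta=self.meta, fixes=self.fixes.copy(), censored=self.censored)


def _lc_rank(lc) -> int:
    lc = str(lc).strip()
    return LC_ORDER.index(lc) if lc in LC_ORDER else len(LC_ORDER)


def read_tracks(telemetry_table, meta_table) -> list[Track]:
    """Read telemetry and metadata CSVs into one :class:`Track` per animal.

    Fixes are time-sorted; duplicate (animal, timestamp) rows keep the
    better Argos location class (3 > 2 > 1 > 0 > A > B), then the first
    occurrence.
    """
    tel = telemetry_table if isinstance(telemetry_table, pd.DataFrame) \
        else pd.read_csv(telemetry_table)
    meta = meta_table if isinstance(meta_table, pd.DataFrame) \
        else pd.read_csv(meta_table)

    for col in TELEMETRY_COLUMNS:
        if col not in tel.columns:
            raise SchemaError(f"telemetry table is missing required column {col!r}")
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise SchemaError(f"metadata table is missing required column {col!r}")

    tel = tel.copy()
    try:
        tel["time"] = pd.to_datetime(tel["date"], utc=True, format="mixed")
    except (ValueError, TypeError):
        bad = None
        for i, v in enumerate(tel["date"]):
            try:
                pd.to_datetime(v, utc=True)
            except (ValueError, TypeError):
                bad = i
                break
        raise ValueError(f"unparseable timestamp at telemetry row {bad}: "
                         f"{tel['date'].iloc[bad]!r}")
    if tel["lat"].abs().max() > 90:
        raise ValueError("latitude outside [-90, 90]")

    for col in ("smaj", "smin", "eor"):
        if col not in tel.columns:
            tel[col] = np.nan

    meta_by_id = {}
    for _, row in meta.iterrows():
        calf = str(row["calf"]).strip().lower() in ("yes", "true", "1")
        meta_by_id[str(row["id"])] = AnimalMeta(
            animal_id=str(row["id"]), sex=str(row["sex"]).strip(),
            calf_present=calf, social_role=str(row["role"]).strip(),
            period=int(row["period"]))

    tracks = []
    tel["_rank"] = tel["lc"].map(_lc_rank)
    for animal_id, sub in tel.groupby(tel["id"].astype(str), sort=True):
        sub = sub.sort_values(["time", "_rank"], kind="stable")
        sub = sub.drop_duplicates(subset="time", keep="first")
        fixes = sub[["time", "lon", "lat", "lc", "smaj", "smin", "eor"]].reset_index(drop=True)
        fixes["lc"] = fixes["lc"].astype(str)
        m = meta_by_id.get(animal_id, AnimalMeta(animal_id=animal_id))
        tracks.append(Track(meta=m, fixes=fixes))
    return tracks


def project(track: Track, proj: AzimuthalEquidistant | None = None) -> Track:
    """Fill planar ``x``/``y`` (km) columns from lon/lat."""
    proj = proj or AzimuthalEquidistant()
    out = track.copy()
    x, y = proj.forward(out.fixes["lon"].to_numpy(), out.fixes["lat"].to_numpy())
    out.fixes["x"] = x
    out.fixes["y"] = y
    return out


def speed_filter(track: Track, vmax: float = 5.0) -> Track:
    """Iteratively remove fixes implying speeds above ``vmax`` (m/s).

    After removing the later fix of the first offending consecutive pair,
    speeds are recomputed; the pass repeats until no pair exceeds the
    threshold. The first fix is never removed.
    """
    if len(track) < 2:
        warnings.warn(f"{track.meta.animal_id}: fewer than 2 fixes, speed filter skipped")
        return track.copy()
    vmax_kmh = vmax * 3.6
    fx = track.fixes
    if "x" not in fx.columns:
        raise ValueError("speed_filter requires projected fixes (run project first)")
    keep = list(range(len(fx)))
    x = fx["x"].to_numpy()
    y = fx["y"].to_numpy()
    t = (fx["time"] - fx["time"].iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    changed = True
    while changed and len(keep) >= 2:
        changed = False
        for j in range(1, len(keep)):
            i0, i1 = keep[j - 1], keep[j]
            dt = t[i1] - t[i0]
            dist = math.hypot(x[i1] - x[i0], y[i1] - y[i0])
            if dt <= 0 or dist / max(dt, 1e-12) > vmax_kmh:
                del keep[j]
                changed = True
                break
    out = track.copy()
    out.fixes = fx.iloc[keep].reset_index(drop=True)
    if len(out) < 2:
        warnings.warn(f"{track.meta.animal_id}: speed filter removed nearly all fixes")
        out.fixes = out.fixes.iloc[:0]
    return out


@dataclass
class CensorResult:
    track: Track | None
    rejected: bool
    reason: str = ""


def censor_track(track: Track, shelf: Polygon | None, lat_cut: float = -50.0) -> CensorResult:
    """Drop pre-departure fixes on the breeding shelf; reject short tracks.

    Fixes inside the shelf polygon before the first shelf exit are
    removed. Tracks whose retained portion never reaches ``lat_cut``
    (the Polar Front) are rejected with a reason.
    """
    fx = track.fixes
    start = 0
    if shelf is not None and len(fx):
        inside = np.fromiter(
            (shelf.contains(Point(lon, lat))
             for lon, lat in zip(fx["lon"], fx["lat"])), dtype=bool, count=len(fx))
        if inside.all():
            return CensorResult(None, True, "never departed")
        if inside[0]:
            start = int(np.argmin(inside))  # first False
    kept = fx.iloc[start:].reset_index(drop=True)
    if len(kept) == 0 or kept["lat"].min() > lat_cut:
        return CensorResult(None, True, "never reached polar front")
    out = track.copy()
    out.fixes = kept
    out.censored = True
    return CensorResult(out, False)


def crossing_date(track: Track, lat_cut: float = -50.0):
    """First crossing of ``lat_cut`` and whole-day migratory duration.

    The crossing time is linearly interpolated in latitude between the
    bracketing fixes; the duration is the floor of the elapsed days from
    the first retained fix. Returns ``(None, None)`` when the retained
    track is already entirely south of the cut (large-gap case).
    """
    fx = track.fixes
    lat = fx["lat"].to_numpy()
    if len(fx) == 0:
        return None, None
    if lat[0] <= lat_cut:
        return None, None
    below = np.nonzero(lat <= lat_cut)[0]
    if len(below) == 0:
        return None, None
    i = int(below[0])
    t0, t1 = fx["time"].iloc[i - 1], fx["time"].iloc[i]
    frac = (lat_cut - lat[i - 1]) / (lat[i] - lat[i - 1])
    t_cross = t0 + (t1 - t0) * float(frac)
    duration = int(math.floor((t_cross - fx["time"].iloc[0]).total_seconds() / 86400.0))
    return t_cross, duration


def summarize_tracks(tracks: Iterable[Track], lat_cut: float = -50.0,
                     ice08: dict | None = None, ice10: dict | None = None) -> pd.DataFrame:
    """Per-animal deployment summary (Locs, dates, M_time, TD, % ice fixes).

    ``ice08``/``ice10`` optionally map animal id to a per-fix 0/1 array of
    sea-ice presence; the summary then reports the percentage of fixes in
    ice-covered habitat.
    """
    rows = []
    for tr in tracks:
        fx = tr.fixes
        t_cross, m_time = crossing_date(tr, lat_cut)
        td = int(math.floor((fx["time"].iloc[-1] - fx["time"].iloc[0]).total_seconds()
                            / 86400.0)) if len(fx) else np.nan
        row = {
            "id": tr.meta.animal_id,
            "sex": tr.meta.sex,
            "calf": tr.meta.calf_present,
            "role": tr.meta.social_role,
            "period": tr.meta.period,
            "locs": len(fx),
            "start": fx["time"].iloc[0] if len(fx) else pd.NaT,
            "end": fx["time"].iloc[-1] if len(fx) else pd.NaT,
            "date50s": t_cross,
            "m_time": m_time if m_time is not None else np.nan,
            "td": td,
        }
        for name, flags in (("ice08_pct", ice08), ("ice10_pct", ice10)):
            if flags is not None and tr.meta.animal_id in flags:
                v = np.asarray(flags[tr.meta.animal_id], dtype=float)
                row[name] = 100.0 * float(np.mean(v)) if len(v) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def footer_stats(summary: pd.DataFrame,
                 columns: Sequence[str] = ("locs", "m_time", "td")) -> pd.DataFrame:
    """Mean / median / sample-SD footer over a per-animal summary table.

    Missing values (e.g. undefined migratory durations) are excluded
    column-wise. With a single animal the SD is reported as 0.
    """
    out = {}
    for col in columns:
        v = pd.to_numeric(summary[col], errors="coerce").dropna().to_numpy(dtype=float)
        if len(v) == 0:
            out[col] = {"mean": np.nan, "median": np.nan, "sd": np.nan}
        else:
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            out[col] = {"mean": float(np.mean(v)),
                        "median": float(np.median(v)),
                        "sd": sd}
    return pd.DataFrame(out)
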