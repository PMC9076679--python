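"""Synthetic telemetry worlds with known truth.

Everything the analysis pipeline consumes can be generated here:
smooth covariate fields with a latitudinal temperature gradient and a
wiggly sea-ice boundary, a fleet of CTCRW tracks whose log sigma_t and
log beta_t are linear in the standardized covariates (with group
deviations), Argos-class error ellipses, and truth bundles for
parameter-recovery experiments.

Two stock configurations are provided. ``SimConfig.recovery_default``
spreads short tracks across the latitude span so pooled covariate
contrast identifies the link slopes; its true coefficients echo the
magnitudes of the published best pooled model. ``SimConfig.fleet_default``
emulates a Brazil → Southern Ocean migration fleet (22 of 30 animals
reach the Polar Front; fix counts echo the published deployment table)
using a highly persistent velocity process and a southward launch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from scipy import ndimage

from .argos import ellipse_to_sd
from .covariates import Raster, RasterStack, StandardizationSpec, evenly_spaced_days
from .kalman import transition_moments
from .linkfit import (AnimalData, FitResult, LinkCoefficients, ModelSpec,
                      aic_table, enumerate_models, fit)
from .projection import AzimuthalEquidistant

#: Argos class mixture and ellipse scale (median semi-major axis, m)
DEFAULT_CLASS_MIX = {"3": (0.15, 250.0), "2": (0.25, 500.0), "1": (0.25, 1200.0),
                     "0": (0.15, 3000.0), "A": (0.12, 5000.0), "B": (0.08, 8000.0)}

CONTINUOUS_FIELDS = ["SST", "SSTA", "CHL", "CURL", "DEPTH"]


@dataclass
class FieldConfig:
    lon_min: float = -60.0
    lon_max: float = 10.0
    lat_min: float = -68.0
    lat_max: float = -14.0
    resolution: float = 0.5          # degrees
    sst_ref: float = 12.0            # °C at lat_ref
    lat_ref: float = -40.0
    sst_gradient: float = 0.5        # °C per degree latitude
    noise_sd: float = 0.6            # smooth-noise SD on SST/CHL/CURL
    ssta_sd: float = 0.5
    chl_coupling: float = -0.08      # CHL slope on SST (drives the screen)
    ice_boundary_lat: float = -55.0  # August ice edge
    ice_wiggle_deg: float = 3.0
    ice_oct_offset: float = 2.0      # October edge sits this much further south
    years: tuple = (2018,)


@dataclass
class SimConfig:
    """Generator configuration; defaults follow the recovery conditions."""

    n_animals: int = 20
    n_group1: int = 10               # G=1 animals (mothers)
    n_fixes: int = 150               # per animal (int or list)
    mean_gap_h: float = 1.0
    start_lat_range: tuple = (-62.0, -30.0)
    start_lon_range: tuple = (-45.0, -5.0)
    start_date: str = "2018-12-01"
    v0: tuple = (0.0, 0.0)           # initial velocity, km/h
    coefficients: LinkCoefficients = None
    grouping: str = "sex"
    record_covariates: tuple = ()    # extra (non-driving) covariates to log
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    fields: FieldConfig = field(default_factory=FieldConfig)
    seed: int = 0

    def __post_init__(self):
        if self.coefficients is None:
            self.coefficients = LinkCoefficients(
                covariates=["SST", "ICE08"],
                A0=0.0, a0=-0.10, A=[0.37, -0.08], a=[0.06, -0.39],
                B0=-1.50, b0=-0.12, B=[-0.40, 0.47], b=[0.10, 1.00])
        if not (0 <= self.n_group1 <= self.n_animals):
            raise ValueError("n_group1 must be within the fleet size")
        if self.mean_gap_h <= 0 or (np.asarray(self.n_fixes) <= 1).any():
            raise ValueError("rates and lengths must be positive")

    @classmethod
    def recovery_default(cls, seed: int = 0) -> "SimConfig":
        return cls(seed=seed)

    @classmethod
    def fleet_default(cls, seed: int = 0, n_animals: int = 30,
                      n_short: int = 8, long_fixes=(650, 2000),
                      short_fixes=(120, 300)) -> "SimConfig":
        """Migration-shaped fleet: ``n_short`` animals stop transmitting
        before the Polar Front; the rest reach it."""
        rng = np.random.default_rng(seed + 1)
        n_long = n_animals - n_short
        long_fixes = np.linspace(*long_fixes, n_long).astype(int)
        short_fixes = np.linspace(*short_fixes, n_short).astype(int)
        n_fixes = rng.permutation(np.concatenate([long_fixes, short_fixes])).tolist()
        # transit-scale persistence (1/beta of weeks) plus a fast southward
        # launch makes the long tracks migrate past the Polar Front while
        # the short ones lose transmission during migration
        coefs = LinkCoefficients(
            covariates=["SST", "ICE08"],
            A0=-3.2, a0=-0.05, A=[0.25, -0.08], a=[0.05, -0.30],
            B0=-7.6, b0=-0.10, B=[-0.40, 0.47], b=[0.10, 1.00])
        return cls(n_animals=n_animals, n_group1=n_animals // 2,
                   n_fixes=n_fixes, mean_gap_h=1.5,
                   start_lat_range=(-20.5, -18.5), start_lon_range=(-39.5, -37.5),
                   start_date="2018-10-15", v0=(0.5, -6.5),
                   coefficients=coefs, seed=seed)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["coefficients"] = self.coefficients.to_dict()
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        d["coefficients"] = LinkCoefficients.from_dict(d["coefficients"])
        d["fields"] = FieldConfig(**{k: tuple(v) if k == "years" else v
                                     for k, v in d["fields"].items()})
        for key in ("start_lat_range", "start_lon_range", "v0"):
            d[key] = tuple(d[key])
        return cls(**d)


def _smooth_noise(rng, shape, smooth_cells: float, sd: float) -> np.ndarray:
    z = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_cells,
                                mode="nearest")
    s = z.std()
    return z / s * sd if s > 0 else z


def gen_covariate_fields(cfg: SimConfig, seed: int | None = None) -> RasterStack:
    """Deterministic covariate raster stack for a configuration.

    SST carries the latitudinal gradient, CHL is linearly coupled to SST
    (|r| >= 0.5 by construction, to exercise the correlation screen),
    DEPTH is a ramp with a meridional ridge, CURL is negative south of
    the Polar Front, and daily ice fraction is 1 south of a wiggly
    boundary during August and October of each configured year.
    """
    fc = cfg.fields
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    lon = np.arange(fc.lon_min, fc.lon_max + 1e-9, fc.resolution)
    lat = np.arange(fc.lat_min, fc.lat_max + 1e-9, fc.resolution)
    LON, LAT = np.meshgrid(lon, lat)
    shape = LAT.shape

    sst = fc.sst_ref + fc.sst_gradient * (LAT - fc.lat_ref) \
        + _smooth_noise(rng, shape, 3.0, fc.noise_sd)
    ssta = _smooth_noise(rng, shape, 4.0, fc.ssta_sd)
    chl = 1.2 + fc.chl_coupling * sst + _smooth_noise(rng, shape, 3.0,
                                                      0.3 * abs(fc.chl_coupling) * 10)
    depth = -(4200.0 - 2600.0 * np.exp(-((LON + 25.0) / 6.0) ** 2)
              - 800.0 * np.exp(-((LAT + 58.0) / 4.0) ** 2)) \
        + _smooth_noise(rng, shape, 3.0, 150.0)
    curl = -0.8 * (1.0 / (1.0 + np.exp((LAT + 50.0) / 3.0))) \
        + _smooth_noise(rng, shape, 3.0, 0.15)

    coords = {"lat": lat, "lon": lon}
    layers = {name: Raster(xr.DataArray(v, coords=coords, dims=("lat", "lon")),
                           "static")
              for name, v in (("SST", sst), ("SSTA", ssta), ("CHL", chl),
                              ("DEPTH", depth), ("CURL", curl))}

    times, frames = [], []
    for year in fc.years:
        for month, edge in ((8, fc.ice_boundary_lat),
                            (10, fc.ice_boundary_lat - fc.ice_oct_offset)):
            ndays = pd.Timestamp(year=year, month=month, day=1).days_in_month
            for day in range(1, ndays + 1):
                wiggle = fc.ice_wiggle_deg * np.sin(2 * np.pi * LON / 60.0
                                                    + 0.15 * day)
                frames.append((LAT < edge + wiggle).astype(float))
                times.append(pd.Timestamp(year=year, month=month, day=day))
    layers["ICE_FRACTION"] = Raster(
        xr.DataArray(np.stack(frames), coords={"time": pd.DatetimeIndex(times),
                                               **coords},
                     dims=("time", "lat", "lon")), "daily")
    return RasterStack(layers=layers)


class _BilinearSampler:
    """Fast bilinear sampling of a static regular-grid field."""

    def __init__(self, da: xr.DataArray):
        self.lon = da["lon"].values
        self.lat = da["lat"].values
        self.v = da.values

    def __call__(self, lon: float, lat: float) -> float:
        i = np.clip(np.searchsorted(self.lat, lat) - 1, 0, len(self.lat) - 2)
        j = np.clip(np.searchsorted(self.lon, lon) - 1, 0, len(self.lon) - 2)
        ty = (lat - self.lat[i]) / (self.lat[i + 1] - self.lat[i])
        tx = (lon - self.lon[j]) / (self.lon[j + 1] - self.lon[j])
        ty = min(max(ty, 0.0), 1.0)
        tx = min(max(tx, 0.0), 1.0)
        v = self.v
        return ((1 - ty) * ((1 - tx) * v[i, j] + tx * v[i, j + 1])
                + ty * ((1 - tx) * v[i + 1, j] + tx * v[i + 1, j + 1]))


def ice_presence_grid(stack: RasterStack, year: int, month: int) -> xr.DataArray:
    """Binary ice-presence grid over ten evenly spaced days of a month."""
    da = stack["ICE_FRACTION"].data
    times = pd.DatetimeIndex(da["time"].values)
    month_len = pd.Timestamp(year=year, month=month, day=1).days_in_month
    wanted = set(evenly_spaced_days(month_len))
    idx = [i for i, t in enumerate(times)
           if t.year == year and t.month == month and t.day in wanted]
    if not idx:
        raise ValueError(f"no ice layers for {year}-{month:02d}")
    return (da.isel(time=idx).max("time") > 0).astype(float)


def field_standardization(stack: RasterStack,
                          names=CONTINUOUS_FIELDS) -> StandardizationSpec:
    """Pooled center/scale from the field grids (the generating scale)."""
    spec = StandardizationSpec()
    for name in names:
        if name in stack:
            v = stack[name].data.values
            spec.params[name] = (float(np.nanmean(v)), float(np.nanstd(v)))
    return spec


@dataclass
class TruthBundle:
    coefficients: LinkCoefficients
    standardization: StandardizationSpec
    covariate_names: list = field(default_factory=list)
    animals: dict = field(default_factory=dict)
    # per animal: dict(times_h, states, sigma, beta, X, G, sd, crossing_h)


def gen_fleet(cfg: SimConfig, stack: RasterStack | None = None,
              seed: int | None = None):
    """Simulate a fleet end-to-end.

    Returns (telemetry DataFrame, metadata DataFrame, TruthBundle). Each
    animal reads the covariates at its current true position, converts
    them through the link to (sigma_t, beta_t), advances by the exact
    CTCRW transition, and is observed through a class-sampled error
    ellipse. Tracks leaving the field extent are truncated.
    """
    seed = cfg.seed if seed is None else seed
    stack = stack if stack is not None else gen_covariate_fields(cfg, seed)
    std = field_standardization(stack)
    proj = AzimuthalEquidistant()
    fc = cfg.fields
    samplers = {name: _BilinearSampler(stack[name].data)
                for name in CONTINUOUS_FIELDS if name in stack}
    ice_samplers = {}
    covs = list(dict.fromkeys(list(cfg.coefficients.covariates)
                              + list(cfg.record_covariates)))
    drive_cols = [covs.index(c) for c in cfg.coefficients.covariates]
    t0 = pd.Timestamp(cfg.start_date)
    year = t0.year
    for name, month in (("ICE08", 8), ("ICE10", 10)):
        if name in covs:
            ice_samplers[name] = _BilinearSampler(ice_presence_grid(stack, year,
                                                                    month))

    seeds = np.random.SeedSequence([seed, 7]).spawn(cfg.n_animals)
    # interleave groups along the start-latitude spread so group effects
    # are not confounded with latitude (both groups sample the ice zone)
    g_list = []
    n1_left, n0_left = cfg.n_group1, cfg.n_animals - cfg.n_group1
    for a in range(cfg.n_animals):
        if (a % 2 == 0 and n1_left > 0) or n0_left == 0:
            g_list.append(1)
            n1_left -= 1
        else:
            g_list.append(0)
            n0_left -= 1
    n_fixes = cfg.n_fixes if isinstance(cfg.n_fixes, (list, tuple, np.ndarray)) \
        else [cfg.n_fixes] * cfg.n_animals
    classes = list(cfg.class_mix.keys())
    probs = np.array([cfg.class_mix[c][0] for c in classes], dtype=float)
    probs = probs / probs.sum()

    tel_rows, meta_rows = [], []
    truth = TruthBundle(coefficients=cfg.coefficients, standardization=std,
                        covariate_names=list(covs))
    for a in range(cfg.n_animals):
        rng = np.random.default_rng(seeds[a])
        G = g_list[a]
        aid = f"sim-{a:03d}"
        frac = a / max(cfg.n_animals - 1, 1)
        lat0 = cfg.start_lat_range[0] + frac * (cfg.start_lat_range[1]
                                                - cfg.start_lat_range[0])
        lon0 = cfg.start_lon_range[0] + (a * 0.37 % 1.0) * (cfg.start_lon_range[1]
                                                            - cfg.start_lon_range[0])
        x0, y0 = proj.forward(lon0, lat0)
        n = int(n_fixes[a])
        gaps = np.maximum(rng.exponential(cfg.mean_gap_h, size=n - 1), 0.05)
        times_h = np.concatenate([[0.0], np.cumsum(gaps)])
        state = np.array([float(x0), cfg.v0[0], float(y0), cfg.v0[1]])
        states = np.empty((n, 4))
        X = np.empty((n, len(covs)))
        sig = np.empty(n - 1)
        bet = np.empty(n - 1)
        sds = np.empty((n, 2))
        obs = np.empty((n, 2))
        truncated_at = n
        for i in range(n):
            lon_t, lat_t = proj.inverse(state[0], state[2])
            if not (fc.lon_min <= lon_t <= fc.lon_max
                    and fc.lat_min <= lat_t <= fc.lat_max):
                truncated_at = i
                break
            row = []
            for name in covs:
                if name in ice_samplers:
                    row.append(1.0 if ice_samplers[name](lon_t, lat_t) > 0.5
                               else 0.0)
                else:
                    c, s = std.params[name]
                    row.append((samplers[name](lon_t, lat_t) - c) / s)
            X[i] = row
            states[i] = state
            # observation through a class-sampled error ellipse
            lc = classes[rng.choice(len(classes), p=probs)]
            smaj = cfg.class_mix[lc][1] * rng.lognormal(0.0, 0.3)
            smin = smaj * rng.uniform(0.4, 1.0)
            eor = rng.uniform(0.0, 180.0)
            err = ellipse_to_sd(smaj, smin, eor)
            sds[i] = (err.sd_x, err.sd_y)
            obs[i, 0] = state[0] + rng.normal(0.0, err.sd_x)
            obs[i, 1] = state[2] + rng.normal(0.0, err.sd_y)
            lon_o, lat_o = proj.inverse(obs[i, 0], obs[i, 1])
            tel_rows.append({"id": aid,
                             "date": (t0 + pd.Timedelta(hours=times_h[i]))
                             .isoformat(),
                             "lc": lc, "lon": float(lon_o), "lat": float(lat_o),
                             "smaj": smaj, "smin": smin, "eor": eor})
            if i == n - 1:
                break
            mu1, mu2 = cfg.coefficients.mu(X[i:i + 1, drive_cols], G)
            sig[i] = math.exp(float(mu1[0]))
            bet[i] = math.exp(float(mu2[0]))
            dt = times_h[i + 1] - times_h[i]
            T, Q = transition_moments(bet[i], sig[i], dt)
            l11 = math.sqrt(max(Q[0, 0], 0.0))
            l21 = Q[0, 1] / l11 if l11 > 0 else 0.0
            l22 = math.sqrt(max(Q[1, 1] - l21 * l21, 0.0))
            for ax in (0, 2):
                z = rng.standard_normal(2)
                prev = state[ax:ax + 2]
                mean = T @ prev
                state[ax] = mean[0] + l11 * z[0]
                state[ax + 1] = mean[1] + l21 * z[0] + l22 * z[1]
        m = truncated_at
        lat_true = proj.inverse(states[:m, 0], states[:m, 2])[1]
        below = np.nonzero(lat_true <= -50.0)[0]
        crossing_h = float(times_h[below[0]]) if len(below) else None
        truth.animals[aid] = {
            "times_h": times_h[:m], "states": states[:m], "X": X[:m],
            "sigma": sig[:max(m - 1, 0)], "beta": bet[:max(m - 1, 0)],
            "sd": sds[:m], "G": G, "crossing_h": crossing_h,
            "truncated": m < n,
        }
        meta_rows.append({"id": aid, "sex": "F" if G == 1 else "M",
                          "calf": "Yes" if G == 1 else "No",
                          "role": "Mo" if G == 1 else "Es",
                          "period": 2 if year >= 2016 else 1})
    telemetry = pd.DataFrame(tel_rows)
    meta = pd.DataFrame(meta_rows)
    return telemetry, meta, truth


def truth_to_animal_data(truth: TruthBundle,
                         observed: dict | None = None) -> list[AnimalData]:
    """AnimalData built from a truth bundle (true covariates, known SDs).

    ``observed`` optionally maps animal id to an (n, 2) array of observed
    planar positions; the true positions are used otherwise.
    """
    out = []
    for aid, t in truth.animals.items():
        n = len(t["times_h"])
        if n < 3:
            continue
        xy = observed[aid] if observed is not None else t["states"][:, [0, 2]]
        out.append(AnimalData(animal_id=aid, xy=np.asarray(xy, dtype=float),
                              sd=t["sd"], dt=np.diff(t["times_h"]),
                              X=t["X"], G=t["G"]))
    return out


def observed_xy(telemetry: pd.DataFrame,
                proj: AzimuthalEquidistant | None = None) -> dict:
    """Per-animal observed planar positions from a telemetry table."""
    proj = proj or AzimuthalEquidistant()
    out = {}
    for aid, sub in telemetry.groupby("id", sort=True):
        x, y = proj.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        out[aid] = np.column_stack([x, y])
    return out


def recovery_experiment(cfg: SimConfig, n_replicates: int, seed: int,
                        compute_se: bool = True) -> dict:
    """Repeatedly simulate and refit; report bias, RMSE and SE coverage.

    Coverage is the fraction of replicates with the truth inside
    +-1.96 SE. With a single replicate the coverage fields are omitted.
    """
    spec = ModelSpec(covariates=tuple(cfg.coefficients.covariates),
                     grouping=cfg.grouping)
    grouped = cfg.grouping != "none"
    names = _coef_names(cfg.coefficients.covariates, grouped)
    true_vec = _coef_vector(cfg.coefficients, grouped)
    ests, ses = [], []
    child = np.random.SeedSequence(seed).spawn(n_replicates)
    for r in range(n_replicates):
        rseed = int(child[r].generate_state(1)[0] % (2 ** 31))
        stack = gen_covariate_fields(cfg, rseed)
        tel, meta, truth = gen_fleet(cfg, stack, rseed)
        fleet = truth_to_animal_data(truth, observed_xy(tel))
        res = fit(fleet, spec, mode="P", compute_se=compute_se)
        ests.append(_coef_vector(res.coefficients, grouped))
        ses.append(_se_vector(res.se, len(cfg.coefficients.covariates), grouped)
                   if compute_se else np.full(len(true_vec), np.nan))
    est = np.asarray(ests)
    se = np.asarray(ses)
    report = {"n_replicates": n_replicates, "coefficients": {}}
    for j, name in enumerate(names):
        entry = {"truth": float(true_vec[j]),
                 "mean_estimate": float(est[:, j].mean()),
                 "bias": float(est[:, j].mean() - true_vec[j]),
                 "rmse": float(np.sqrt(np.mean((est[:, j] - true_vec[j]) ** 2)))}
        if n_replicates > 1 and compute_se and np.isfinite(se[:, j]).all():
            inside = np.abs(est[:, j] - true_vec[j]) <= 1.96 * se[:, j]
            entry["coverage"] = float(np.mean(inside))
        report["coefficients"][name] = entry
    return report


def selection_config(seed: int = 0) -> SimConfig:
    """Conditions for the AIC covariate-set selection experiment.

    Truth drives sigma/beta through DEPTH and ICE08 (ungrouped); SST is
    recorded as a decoy so the enumerator can offer wrong and superset
    models.
    """
    coefs = LinkCoefficients(
        covariates=["DEPTH", "ICE08"],
        A0=0.0, A=[0.30, -0.20], B0=-1.5, B=[-0.30, 0.50])
    return SimConfig(n_animals=12, n_group1=6, n_fixes=120, mean_gap_h=1.0,
                     grouping="none", coefficients=coefs,
                     record_covariates=("SST",), seed=seed)


def aic_selection_experiment(cfg: SimConfig, pool, n_fleets: int, seed: int,
                             forbidden=()) -> dict:
    """Fit every admissible covariate subset to replicate fleets and count
    how often the true set attains delta-AIC = 0."""
    true_set = tuple(sorted(cfg.coefficients.covariates))
    specs = enumerate_models(pool, forbidden, groupings=(cfg.grouping,))
    child = np.random.SeedSequence(seed).spawn(n_fleets)
    wins = 0
    tables = []
    for r in range(n_fleets):
        rseed = int(child[r].generate_state(1)[0] % (2 ** 31))
        stack = gen_covariate_fields(cfg, rseed)
        tel, meta, truth = gen_fleet(cfg, stack, rseed)
        fleet = truth_to_animal_data(truth, observed_xy(tel))
        idx = {c: i for i, c in enumerate(truth.covariate_names)}
        results = [fit(fleet, s, mode="P", compute_se=False,
                       covariate_index=idx) for s in specs]
        table = aic_table(results)
        tables.append(table)
        best_model = table.iloc[0]["model"]
        best_set = tuple(sorted(best_model.split("+")))
        wins += int(best_set == true_set)
    return {"n_fleets": n_fleets, "true_set": true_set, "wins": wins,
            "win_fraction": wins / n_fleets, "tables": tables}


def _coef_names(covariates, grouped):
    names = ["A0"] + [f"A_{c}" for c in covariates]
    names += ["B0"] + [f"B_{c}" for c in covariates]
    if grouped:
        names += ["a0"] + [f"a_{c}" for c in covariates]
        names += ["b0"] + [f"b_{c}" for c in covariates]
    return names


def _coef_vector(coefs: LinkCoefficients, grouped):
    v = [coefs.A0, *coefs.A, coefs.B0, *coefs.B]
    if grouped:
        v += [coefs.a0, *coefs.a, coefs.b0, *coefs.b]
    return np.asarray(v, dtype=float)


def _se_vector(se: dict, k: int, grouped):
    if not se:
        return np.full(2 * (1 + k) * (2 if grouped else 1), np.nan)
    v = [se["A0"], *np.atleast_1d(se["A"]), se["B0"], *np.atleast_1d(se["B"])]
    if grouped:
        v += [se["a0"], *np.atleast_1d(se["a"]),
              se["b0"], *np.atleast_1d(se["b"])]
    return np.asarray(v, dtype=float)
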