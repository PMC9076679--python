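"""End-to-end analysis orchestration.

``run_pipeline`` chains the stages simulate → ingest → errors →
covariates → select → classify → predict → summarize into a run
directory with a provenance manifest (config hash, seed, input/output
checksums). Every stage can also be driven individually through the
``ctcrw`` command-line interface.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import covariates as cov
from . import telemetry as tio
from .argos import ellipse_to_sd, fit_class_gamma, impute_sd
from .kalman import smooth_states
from .linkfit import AnimalData, ModelSpec, aic_table, enumerate_models, fit, \
    linear_predictors
from .prediction import multi_year_summary, predict_grid
from .projection import AzimuthalEquidistant
from .simulate import CONTINUOUS_FIELDS, SimConfig, gen_covariate_fields, \
    gen_fleet, ice_presence_grid


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "ctcrw_run"
    seed: int = 0
    telemetry: str | None = None      # CSV paths; None -> synthetic fleet
    meta: str | None = None
    sim: SimConfig = field(default_factory=lambda: SimConfig.fleet_default(
        n_animals=6, n_short=1, long_fixes=(550, 750), short_fixes=(150, 150)))
    vmax_ms: float = 5.0
    lat_cut: float = -50.0
    pool: tuple = ("SST", "ICE08", "DEPTH")
    groupings: tuple = ("none",)
    extra_forbidden: tuple = ()

    def to_yaml(self) -> str:
        d = asdict(self)
        d["sim"] = yaml.safe_load(self.sim.to_yaml()) if self.sim else None
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        sim = d.pop("sim", None)
        rc = cls(**{k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in d.items()})
        if sim is not None:
            rc.sim = SimConfig.from_yaml(yaml.safe_dump(sim))
        return rc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    cfg_dict = yaml.safe_load(config.to_yaml())
    cfg_dict.pop("out_dir", None)   # the hash covers the science, not paths
    manifest = {"config_hash": hashlib.sha256(
        yaml.safe_dump(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed, "inputs": {}, "outputs": {}}

    def log(stage, msg):
        log_lines.append(f"[{stage}] {msg}")

    def emit(name, path):
        manifest["outputs"][name] = _sha256(Path(path))

    proj = AzimuthalEquidistant()
    try:
        stage = "simulate"
        config.sim.seed = config.seed
        stack = gen_covariate_fields(config.sim, config.seed)
        if config.telemetry is None:
            tel, meta, truth = gen_fleet(config.sim, stack, config.seed)
            tel_path, meta_path = out / "telemetry.csv", out / "meta.csv"
            tel.to_csv(tel_path, index=False)
            meta.to_csv(meta_path, index=False)
            with open(out / "truth_coefficients.json", "w") as fh:
                json.dump(truth.coefficients.to_dict(), fh, indent=1)
            emit("telemetry.csv", tel_path)
            emit("meta.csv", meta_path)
            log(stage, f"simulated fleet of {config.sim.n_animals}")
        else:
            tel_path, meta_path = Path(config.telemetry), Path(config.meta)
            for p in (tel_path, meta_path):
                if not p.exists():
                    raise FileNotFoundError(str(p))
                manifest["inputs"][p.name] = _sha256(p)

        stage = "ingest"
        tracks = tio.read_tracks(str(tel_path), str(meta_path))
        tracks = [tio.project(t, proj) for t in tracks]
        tracks = [tio.speed_filter(t, config.vmax_ms) for t in tracks]
        kept = []
        for t in tracks:
            res = tio.censor_track(t, shelf=None, lat_cut=config.lat_cut)
            if res.rejected:
                log(stage, f"{t.meta.animal_id} rejected: {res.reason}")
            else:
                kept.append(res.track)
        if not kept:
            raise ValueError("no tracks retained after censoring")
        log(stage, f"retained {len(kept)} of {len(tracks)} tracks")

        stage = "errors"
        have_ellipse = []
        sds = {}
        for t in kept:
            fx = t.fixes
            ok = fx["smaj"].notna() & (fx["smaj"] > 0)
            have_ellipse.append(ok)
        train = []
        for t, ok in zip(kept, have_ellipse):
            fx = t.fixes[ok]
            for _, r in fx.iterrows():
                e = ellipse_to_sd(r["smaj"], r["smin"], r["eor"])
                train.append({"lc": r["lc"], "lat": r["lat"],
                              "sd": 0.5 * (e.sd_x + e.sd_y)})
        err_model = fit_class_gamma(pd.DataFrame(train)) if train else None
        for t, ok in zip(kept, have_ellipse):
            fx = t.fixes
            arr = np.empty((len(fx), 2))
            rng = np.random.default_rng(
                abs(hash((config.seed, t.meta.animal_id))) % (2 ** 31))
            for i, (_, r) in enumerate(fx.iterrows()):
                if ok.iloc[i]:
                    e = ellipse_to_sd(r["smaj"], r["smin"], r["eor"])
                else:
                    e = impute_sd(r["lc"], r["lat"], err_model, rng)
                arr[i] = (e.sd_x, e.sd_y)
            sds[t.meta.animal_id] = arr
        if err_model is not None:
            (out / "error_model.json").write_text(err_model.to_json())
            emit("error_model.json", out / "error_model.json")

        stage = "covariates"
        year = pd.Timestamp(config.sim.start_date).year
        ice_grids = {"ICE08": ice_presence_grid(stack, year, 8),
                     "ICE10": ice_presence_grid(stack, year, 10)}
        frames = []
        for t in kept:
            names = [c for c in config.pool if c in CONTINUOUS_FIELDS]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = cov.sample_track(stack, t.fixes, names)
            for c in vals.columns:
                vals[c] = cov.forward_fill(vals[c], t.meta.animal_id, c)
            for name, grid in ice_grids.items():
                if name in config.pool:
                    vals[name] = (grid.sel(
                        lon=xr_pts(t.fixes["lon"]), lat=xr_pts(t.fixes["lat"]),
                        method="nearest").values > 0).astype(float)
            vals.insert(0, "id", t.meta.animal_id)
            frames.append(vals)
        table = pd.concat(frames, ignore_index=True)
        continuous = [c for c in config.pool if c in CONTINUOUS_FIELDS]
        binary = [c for c in config.pool if c.startswith("ICE")]
        std_spec, table_std = cov.standardize(table, continuous, binary)
        forbidden = cov.correlation_screen(table_std, continuous)
        forbidden |= {tuple(sorted(p)) for p in config.extra_forbidden}
        if {"ICE08", "ICE10"} <= set(config.pool):
            forbidden.add(("ICE08", "ICE10"))
        table_std.to_csv(out / "covariates.csv", index=False)
        emit("covariates.csv", out / "covariates.csv")
        (out / "standardization.json").write_text(
            json.dumps(std_spec.to_dict(), indent=1))
        log(stage, f"forbidden pairs: {sorted(forbidden)}")

        stage = "select"
        fleet = []
        pool = list(config.pool)
        for t in kept:
            sub = table_std[table_std["id"] == t.meta.animal_id]
            xy = t.fixes[["x", "y"]].to_numpy(dtype=float)
            dt = np.diff((t.fixes["time"] - t.fixes["time"].iloc[0])
                         .dt.total_seconds().to_numpy()) / 3600.0
            fleet.append(AnimalData(
                animal_id=t.meta.animal_id, xy=xy, sd=sds[t.meta.animal_id],
                dt=dt, X=sub[pool].to_numpy(dtype=float),
                G=t.meta.group_for("sex" if "sex" in config.groupings
                                   else "none")))
        specs = enumerate_models(pool, forbidden, config.groupings)
        idx = {c: i for i, c in enumerate(pool)}
        results = [fit(fleet, s, mode="P", compute_se=False,
                       covariate_index=idx) for s in specs]
        table_aic = aic_table(results)
        table_aic.to_csv(out / "aic.csv", index=False)
        emit("aic.csv", out / "aic.csv")
        best = min(results, key=lambda r: (r.aic, r.spec.name))
        best = fit(fleet, best.spec, mode="P", compute_se=True,
                   covariate_index=idx)
        (out / "best_fit.json").write_text(json.dumps(best.to_dict(), indent=1))
        emit("best_fit.json", out / "best_fit.json")
        log(stage, f"best model: {best.spec.name}")

        stage = "classify"
        rows = []
        for t, d in zip(kept, fleet):
            cols = [idx[c] for c in best.spec.covariates]
            params = linear_predictors(best.coefficients, d.X[:, cols], d.G,
                                       d.dt)
            sm = smooth_states(d.xy, d.sd, params)
            n1 = len(d.xy) - 1
            rows.append(pd.DataFrame({
                "id": d.animal_id, "time": t.fixes["time"].iloc[:n1],
                "lat": t.fixes["lat"].iloc[:n1],
                "sigma": params.sigma, "p": params.p,
                "speed": sm["speed"][:n1]}))
        beh = pd.concat(rows, ignore_index=True)
        series = bh.behavior_series(beh["sigma"], beh["p"], beh["speed"])
        beh = pd.concat([beh, series[["sigma_q", "p_q", "ars_sigma", "ars_p",
                                      "ars_joint"]]], axis=1)
        beh.to_csv(out / "behavior.csv", index=False)
        emit("behavior.csv", out / "behavior.csv")

        stage = "predict"
        rasters = {}
        for c in best.spec.covariates:
            if c in CONTINUOUS_FIELDS:
                rasters[c] = stack[c].data
            elif c in ice_grids:
                rasters[c] = ice_grids[c]
        yearly = [predict_grid(best, rasters, std_spec, G=0)]
        summary = multi_year_summary(yearly)
        pred_df = summary.to_dataframe().reset_index()
        pred_df.to_csv(out / "prediction.csv", index=False)
        emit("prediction.csv", out / "prediction.csv")

        stage = "summarize"
        summ = tio.summarize_tracks(kept, config.lat_cut)
        summ.to_csv(out / "track_summary.csv", index=False)
        emit("track_summary.csv", out / "track_summary.csv")
        foot = tio.footer_stats(summ)
        foot.to_csv(out / "track_summary_footer.csv")
        emit("track_summary_footer.csv", out / "track_summary_footer.csv")
    except Exception as e:  # noqa: BLE001 - stage attribution
        (out / "run.log").write_text("\n".join(log_lines + [f"FAILED: {e}"]))
        raise PipelineError(stage, str(e)) from e

    (out / "run.log").write_text("\n".join(log_lines))
    (out / "config.yaml").write_text(config.to_yaml())
    manifest["inputs"]["config.yaml"] = _sha256(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def xr_pts(values):
    import xarray as xr
    return xr.DataArray(np.asarray(values, dtype=float), dims="pt")
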