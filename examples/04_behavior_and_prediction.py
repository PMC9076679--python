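"""Classify area-restricted search and map expected movement parameters.

Uses the shipped best pooled-model coefficients over a synthetic January
covariate field: expected sigma (velocity scale) and p = 3/beta
(persistence) are predicted per 0.5° cell for each sex group, binned into
quartiles, and the joint lowest-quartile (ARS) area is reported.
"""

import warnings

import numpy as np

import ctcrw

warnings.filterwarnings("ignore")

cfg = ctcrw.SimConfig.recovery_default(seed=1)
stack = ctcrw.gen_covariate_fields(cfg, 1)
std = ctcrw.field_standardization(stack)

# the best published model uses DEPTH+SST+CURL+SSTA+ICE08
coefs, _ = ctcrw.datasets.best_pmodel()
rasters = {name: stack[name].data for name in ("DEPTH", "SST", "CURL", "SSTA")}
rasters["ICE08"] = ctcrw.ice_presence_grid(stack, cfg.fields.years[0], 8)

for G, label in ((0, "males+"), (1, "mothers")):
    ds = ctcrw.predict_grid(coefs, rasters, std, G=G)
    out = ctcrw.multi_year_summary([ds])
    ars = float(out["ars_joint"].mean())
    south = out["ars_joint"].where(out["ars_joint"]).mean("lon")
    lat_ars = out["lat"].values[np.nan_to_num(south.values) > 0]
    print(f"{label:8s}: median predicted p "
          f"{float(np.nanmedian(out['p_mean'])):8.2f} h, "
          f"median sigma {float(np.nanmedian(out['sigma_mean'])):8.1f}; "
          f"joint-ARS fraction {ars:.3f}, "
          f"ARS latitudes {lat_ars.min():.1f} to {lat_ars.max():.1f}")
# the joint-ARS mask marks cells in the lowest quartile of BOTH sigma and
# p - candidate foraging habitat; it concentrates at the cold, icy south
# of the domain, more strongly for mothers (larger ice deviations).
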