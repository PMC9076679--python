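"""Grid-based spatial prediction of expected movement parameters.

A fitted pooled model is evaluated over a regular lon/lat grid of
covariate rasters (one snapshot per year), yielding expected sigma and
persistence p = 3/beta fields per group, then summarised across years as
mean, coefficient of variation, quartile bins and a joint lowest-quartile
(ARS) mask.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .behavior import classify_quartiles
from .covariates import StandardizationSpec
from .linkfit import FitResult, LinkCoefficients


def predict_grid(fit_result, rasters: dict, std_spec: StandardizationSpec,
                 G: int = 0, training_range: dict | None = None) -> xr.Dataset:
    """Expected sigma and p per grid cell for one year's conditions.

    ``rasters`` maps each model covariate to a 2-D DataArray (lat, lon) on
    a common grid (continuous covariates raw — they are standardized here
    with the training spec; ICE binaries as 0/1). Cells with any missing
    covariate are missing in the output. ``training_range`` optionally
    maps covariate -> (min, max) on the standardized scale; cells outside
    it are flagged in ``extrapolated``.
    """
    coefs = fit_result.coefficients if isinstance(fit_result, FitResult) \
        else fit_result
    assert isinstance(coefs, LinkCoefficients)
    missing = [c for c in coefs.covariates if c not in rasters]
    if missing:
        raise ValueError(f"covariates absent from raster stack: {missing}")
    ref = rasters[coefs.covariates[0]]
    shape = ref.shape
    cols = []
    extrap = np.zeros(shape, dtype=bool)
    for name in coefs.covariates:
        da = rasters[name]
        if da.shape != shape:
            raise ValueError(f"raster {name!r} not on the common grid")
        v = np.asarray(da.values, dtype=float)
        if name in std_spec.params:
            c, s = std_spec.params[name]
            v = (v - c) / s
        if training_range and name in training_range:
            lo, hi = training_range[name]
            extrap |= (v < lo) | (v > hi)
        cols.append(v.ravel())
    X = np.column_stack(cols)
    ok = np.isfinite(X).all(axis=1)
    mu1 = np.full(X.shape[0], np.nan)
    mu2 = np.full(X.shape[0], np.nan)
    mu1[ok], mu2[ok] = coefs.mu(X[ok], G)
    sigma = np.exp(mu1).reshape(shape)
    p = (3.0 / np.exp(mu2)).reshape(shape)
    ds = xr.Dataset(
        {"sigma": (ref.dims, sigma), "p": (ref.dims, p),
         "extrapolated": (ref.dims, extrap & np.isfinite(sigma))},
        coords=ref.coords)
    ds.attrs["group_G"] = G
    ds.attrs["extrapolated_fraction"] = (
        float(extrap[np.isfinite(sigma)].mean()) if np.isfinite(sigma).any() else 0.0)
    return ds


def multi_year_summary(yearly: list[xr.Dataset]) -> xr.Dataset:
    """Cell-wise mean, CV (sample SD / mean), quartile bins of the mean
    and the joint lowest-quartile (ARS co-occurrence) mask across years."""
    if not yearly:
        raise ValueError("no yearly fields given")
    out = {}
    for var in ("sigma", "p"):
        stack = xr.concat([ds[var] for ds in yearly], dim="year")
        mean = stack.mean("year", skipna=True)
        if len(yearly) > 1:
            sd = stack.std("year", ddof=1, skipna=True)
            cv = sd / mean
        else:
            cv = xr.zeros_like(mean)
        out[f"{var}_mean"] = mean
        out[f"{var}_cv"] = cv
        q = np.full(mean.shape, np.nan)
        finite = np.isfinite(mean.values)
        if finite.any():
            q[finite] = classify_quartiles(mean.values[finite])
        out[f"{var}_quartile"] = (mean.dims, q)
    ds = xr.Dataset(out, coords=yearly[0].coords)
    ds["ars_joint"] = (ds["sigma_quartile"] == 1) & (ds["p_quartile"] == 1)
    return ds
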