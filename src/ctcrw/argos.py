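"""Argos location-error model.

Newer tags report an error ellipse per fix (semi-major/semi-minor axes in
metres, orientation from north); these are decomposed into independent
per-axis Gaussian standard deviations for the observation model. Older
tags report only a location class, so per-class gamma regressions of the
ellipse-derived SDs on latitude are fitted to the newer data and used to
randomly impute SDs for the older fixes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special

#: ellipse axes are treated as 1-sigma extents split evenly between axes
ELLIPSE_SD_FACTOR = 1.0 / np.sqrt(2.0)
MIN_SD_KM = 0.05


@dataclass
class ObservationError:
    sd_x: float  # km
    sd_y: float  # km
    source: str = "ellipse"   # ellipse | imputed


def ellipse_to_sd(semi_major_m, semi_minor_m, orientation_deg,
                  floor_km: float = MIN_SD_KM) -> ObservationError:
    """Per-axis SDs (km) from an Argos error ellipse.

    With the orientation ``c`` measured clockwise from north,
    sd_x^2 = (M^2 sin^2 c + m^2 cos^2 c)/2 and
    sd_y^2 = (M^2 cos^2 c + m^2 sin^2 c)/2, so a circular ellipse of
    radius r yields isotropic SDs r/sqrt(2).
    """
    M, m = float(semi_major_m), float(semi_minor_m)
    if M < 0 or m < 0:
        raise ValueError("ellipse axes must be non-negative")
    if M < m:
        raise ValueError("semi_major must be >= semi_minor")
    if M == 0.0:
        warnings.warn("zero error ellipse; applying minimum-SD floor")
        return ObservationError(floor_km, floor_km, "ellipse")
    c = np.radians(float(orientation_deg))
    sd_x = np.sqrt((M ** 2 * np.sin(c) ** 2 + m ** 2 * np.cos(c) ** 2) / 2.0) / 1000.0
    sd_y = np.sqrt((M ** 2 * np.cos(c) ** 2 + m ** 2 * np.sin(c) ** 2) / 2.0) / 1000.0
    return ObservationError(max(sd_x, floor_km * 1e-6), max(sd_y, floor_km * 1e-6),
                            "ellipse")


@dataclass
class ClassErrorModel:
    """Per-class gamma regressions of SD (km) on latitude.

    Each class maps to (gamma0, gamma1, nu): mean SD = exp(g0 + g1*lat),
    gamma shape nu. A pooled model over all classes is kept as fallback.
    """

    classes: dict = field(default_factory=dict)
    pooled: tuple | None = None

    def mean_sd(self, loc_class: str, lat: float) -> float:
        g0, g1, _ = self._params(loc_class)
        return float(np.exp(g0 + g1 * lat))

    def _params(self, loc_class: str):
        lc = str(loc_class)
        if lc in self.classes:
            return self.classes[lc]
        if self.pooled is None:
            raise ValueError(f"no model for class {lc!r} and no pooled fallback")
        warnings.warn(f"location class {lc!r} absent from error model; "
                      "using pooled fallback")
        return self.pooled

    def to_json(self) -> str:
        return json.dumps({"classes": self.classes, "pooled": self.pooled})

    @classmethod
    def from_json(cls, s: str) -> "ClassErrorModel":
        d = json.loads(s)
        return cls(classes={k: tuple(v) for k, v in d["classes"].items()},
                   pooled=tuple(d["pooled"]) if d["pooled"] else None)


def _gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile MLE of the gamma shape given fitted means."""
    r = y / mu
    s = float(np.mean(r - np.log(r))) - 1.0
    if s <= 0:
        return 1e6  # effectively zero dispersion
    f = lambda nu: np.log(nu) - special.digamma(nu) - s
    lo, hi = 1e-3, 1e8
    try:
        return float(optimize.brentq(f, lo, hi))
    except ValueError:
        return 1e6


def _fit_one(lat: np.ndarray, sd: np.ndarray):
    X = sm.add_constant(lat)
    model = sm.GLM(sd, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit()
    mu = np.asarray(res.fittedvalues)
    nu = _gamma_shape_mle(sd, mu)
    return float(res.params[0]), float(res.params[1]), nu


def fit_class_gamma(df, min_per_class: int = 10) -> ClassErrorModel:
    """Fit per-class gamma regressions (log link, latitude slope).

    ``df`` needs columns ``lc`` (location class), ``lat`` (degrees) and
    ``sd`` (km, > 0). Classes with fewer than ``min_per_class`` fixes are
    skipped with a warning and served by the pooled model.
    """
    sd = np.asarray(df["sd"], dtype=float)
    if np.any(sd <= 0):
        raise ValueError("SDs must be strictly positive")
    model = ClassErrorModel()
    model.pooled = _fit_one(np.asarray(df["lat"], dtype=float), sd)
    for lc, sub in df.groupby(df["lc"].astype(str)):
        if len(sub) < min_per_class:
            warnings.warn(f"class {lc!r}: only {len(sub)} fixes, skipped "
                          "(pooled fallback)")
            continue
        model.classes[str(lc)] = _fit_one(np.asarray(sub["lat"], dtype=float),
                                          np.asarray(sub["sd"], dtype=float))
    return model


def impute_sd(loc_class, lat, model: ClassErrorModel, rng) -> ObservationError:
    """Draw one SD from the class/latitude gamma model, applied to both axes.

    ``rng`` is a seeded ``numpy.random.Generator``; identical generator
    state reproduces the draw.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    g0, g1, nu = model._params(loc_class)
    mean = np.exp(g0 + g1 * float(lat))
    draw = float(rng.gamma(shape=nu, scale=mean / nu))
    draw = max(draw, 1e-6)
    return ObservationError(draw, draw, "imputed")
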