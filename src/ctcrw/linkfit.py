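"""Covariate link model and maximum-likelihood fitting.

The CTCRW movement parameters are linked to standardized environmental
covariates through log-linear predictors, optionally with group-deviation
terms for a binary group indicator G (e.g. mothers vs males+):

    log(sigma_t) = (A0 + a0 G) + sum_j (A_j + a_j G) X_jt
    log(beta_t)  = (B0 + b0 G) + sum_j (B_j + b_j G) X_jt

The link-noise SDs eps1/eps2 are fixed at 0.001; the default fit treats
the link as deterministic (the 0.001 limit), which makes the marginal
likelihood an exact Kalman-filter computation. Models are fitted either
per animal (I-models) or jointly with complete pooling (P-models), and
candidate covariate sets are ranked by AIC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize

from .kalman import MovementParams, _filter_1d, DEFAULT_INIT_POS_VAR

EPS_LINK = 0.001


@dataclass
class LinkCoefficients:
    """Full parameter vector of the link model.

    ``covariates`` fixes the ordering of the slope vectors. Deviation
    terms (a0, a, b0, b) are zero for ungrouped models.
    """

    covariates: list[str]
    A0: float = 0.0
    B0: float = 0.0
    A: np.ndarray = None
    B: np.ndarray = None
    a0: float = 0.0
    b0: float = 0.0
    a: np.ndarray = None
    b: np.ndarray = None
    eps1: float = EPS_LINK
    eps2: float = EPS_LINK

    def __post_init__(self):
        k = len(self.covariates)
        for name in ("A", "B", "a", "b"):
            v = getattr(self, name)
            v = np.zeros(k) if v is None else np.asarray(v, dtype=float)
            if len(v) != k:
                raise ValueError(f"{name} must have length {k}")
            setattr(self, name, v)

    def mu(self, X: np.ndarray, G: int) -> tuple[np.ndarray, np.ndarray]:
        """Linear predictors (mu1, mu2) for a design matrix X (n, k)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.covariates):
            raise ValueError("design matrix does not match covariate list")
        mu1 = self.A0 + self.a0 * G + X @ (self.A + self.a * G)
        mu2 = self.B0 + self.b0 * G + X @ (self.B + self.b * G)
        return mu1, mu2

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "A0": self.A0, "a0": self.a0, "A": self.A.tolist(), "a": self.a.tolist(),
            "B0": self.B0, "b0": self.b0, "B": self.B.tolist(), "b": self.b.tolist(),
            "eps1": self.eps1, "eps2": self.eps2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinkCoefficients":
        return cls(covariates=list(d["covariates"]), A0=d["A0"], a0=d.get("a0", 0.0),
                   A=np.asarray(d["A"]), a=np.asarray(d.get("a", np.zeros(len(d["A"])))),
                   B0=d["B0"], b0=d.get("b0", 0.0), B=np.asarray(d["B"]),
                   b=np.asarray(d.get("b", np.zeros(len(d["B"])))),
                   eps1=d.get("eps1", EPS_LINK), eps2=d.get("eps2", EPS_LINK))


def linear_predictors(coefs: LinkCoefficients, X: np.ndarray, G: int,
                      delta: np.ndarray, rng=None) -> MovementParams:
    """Movement parameters for one animal's inter-fix intervals.

    ``X`` holds standardized covariates at each fix (n, k); parameters are
    anchored at the interval's starting fix, so rows 0..n-2 drive the n-1
    intervals of length ``delta``. In the default deterministic-link mode
    sigma_t = exp(mu1), beta_t = exp(mu2); passing a ``rng`` draws the
    latent Normal(0, eps) link noise instead.
    """
    X = np.asarray(X, dtype=float)
    mu1, mu2 = coefs.mu(X[:-1], G)
    if rng is not None:
        mu1 = mu1 + rng.normal(0.0, coefs.eps1, size=mu1.shape)
        mu2 = mu2 + rng.normal(0.0, coefs.eps2, size=mu2.shape)
    return MovementParams(sigma=np.exp(mu1), beta=np.exp(mu2), delta=delta)


@dataclass
class AnimalData:
    """Per-animal inputs to the likelihood."""

    animal_id: str
    xy: np.ndarray        # (n, 2) projected positions, km
    sd: np.ndarray        # (n, 2) observation SDs, km
    dt: np.ndarray        # (n-1,) interval lengths, h
    X: np.ndarray         # (n, k) standardized covariates at fixes
    G: int = 0


@dataclass
class ModelSpec:
    covariates: tuple[str, ...]
    grouping: str = "none"   # none | sex | period

    @property
    def name(self) -> str:
        tag = "" if self.grouping == "none" else f"+{self.grouping.upper()}"
        return "+".join(self.covariates) + tag


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: LinkCoefficients
    se: dict = dc_field(default_factory=dict)
    loglik: float = np.nan
    aic: float = np.nan
    n_params: int = 0
    converged: bool = False
    mode: str = "P"
    animal_ids: list = dc_field(default_factory=list)

    def movement_params(self, data: AnimalData) -> MovementParams:
        return linear_predictors(self.coefficients, data.X, data.G, data.dt)

    def to_dict(self) -> dict:
        return {
            "spec": {"covariates": list(self.spec.covariates),
                     "grouping": self.spec.grouping},
            "coefficients": self.coefficients.to_dict(),
            "se": {k: (np.asarray(v).tolist() if np.ndim(v) else float(v))
                   for k, v in self.se.items()},
            "loglik": float(self.loglik), "aic": float(self.aic),
            "n_params": int(self.n_params), "converged": bool(self.converged),
            "mode": self.mode, "animal_ids": list(self.animal_ids),
        }


def _pack(coefs: LinkCoefficients, grouped: bool) -> np.ndarray:
    base = [coefs.A0, *coefs.A, coefs.B0, *coefs.B]
    if grouped:
        base += [coefs.a0, *coefs.a, coefs.b0, *coefs.b]
    return np.array(base, dtype=float)


def _unpack(theta: np.ndarray, covariates: list[str], grouped: bool) -> LinkCoefficients:
    k = len(covariates)
    A0, A = theta[0], theta[1:1 + k]
    B0, B = theta[1 + k], theta[2 + k:2 + 2 * k]
    if grouped:
        off = 2 + 2 * k
        a0, a = theta[off], theta[off + 1:off + 1 + k]
        b0, b = theta[off + 1 + k], theta[off + 2 + k:off + 2 + 2 * k]
    else:
        a0 = b0 = 0.0
        a = b = np.zeros(k)
    return LinkCoefficients(covariates=list(covariates), A0=A0, A=A, B0=B0, B=B,
                            a0=a0, a=a, b0=b0, b=b)


def fleet_loglik(theta: np.ndarray, fleet: list[AnimalData], covariates: list[str],
                 grouped: bool, init_var_pos: float = DEFAULT_INIT_POS_VAR) -> float:
    """Sum of per-animal Kalman log-likelihoods at packed coefficients."""
    coefs = _unpack(theta, covariates, grouped)
    total = 0.0
    for d in fleet:
        mu1, mu2 = coefs.mu(d.X[:-1], d.G)
        sigma = np.exp(np.clip(mu1, -30, 30))
        beta = np.exp(np.clip(mu2, -30, 30))
        for ax in range(2):
            ll, bad = _filter_1d(np.ascontiguousarray(d.xy[:, ax]),
                                 np.ascontiguousarray(d.sd[:, ax]),
                                 beta, sigma, d.dt, init_var_pos)
            if bad >= 0 or not np.isfinite(ll):
                return -np.inf
            total += ll
    return total


def _initial_thetas(fleet: list[AnimalData], k: int, grouped: bool) -> list[np.ndarray]:
    """Candidate starts: zero slopes, intercepts from a coarse beta grid
    with sigma moment-matched to the empirical velocity variance."""
    vels = [np.diff(d.xy, axis=0) / d.dt[:, None] for d in fleet]
    v = np.vstack(vels)
    var_v = max(float(np.var(v)), 1e-6)
    n = 2 * (1 + k) * (2 if grouped else 1)
    out = []
    for beta0 in (3e-4, 3e-3, 3e-2, 0.3, 1.0):
        sigma0 = np.sqrt(2.0 * beta0 * var_v)
        theta = np.zeros(n)
        theta[0] = np.log(sigma0)
        theta[1 + k] = np.log(beta0)
        out.append(theta)
    return out


def _hessian(f, theta, step=1e-4):
    """Central finite-difference Hessian of a scalar function."""
    k = len(theta)
    H = np.empty((k, k))
    h = step * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _coef_se(theta_names, se_vec, covariates, grouped):
    se = {}
    k = len(covariates)
    se["A0"] = se_vec[0]; se["A"] = se_vec[1:1 + k]
    se["B0"] = se_vec[1 + k]; se["B"] = se_vec[2 + k:2 + 2 * k]
    if grouped:
        off = 2 + 2 * k
        se["a0"] = se_vec[off]; se["a"] = se_vec[off + 1:off + 1 + k]
        se["b0"] = se_vec[off + 1 + k]; se["b"] = se_vec[off + 2 + k:off + 2 + 2 * k]
    return se


def _fit_pooled(fleet: list[AnimalData], spec: ModelSpec, covariates: list[str],
                compute_se: bool, init_var_pos: float, mode: str) -> FitResult:
    grouped = spec.grouping != "none"
    if grouped:
        gs = {d.G for d in fleet}
        if gs != {0, 1}:
            raise ValueError("grouped P-model requires both groups present")
    nll = lambda th: -fleet_loglik(th, fleet, covariates, grouped, init_var_pos)
    candidates = _initial_thetas(fleet, len(covariates), grouped)
    theta0 = min(candidates, key=nll)
    opts = {"maxiter": 600, "ftol": 1e-11, "gtol": 1e-7}
    # central-difference gradients: one-sided differences are too noisy
    # along the curved sigma/beta trade-off valley of this likelihood
    lbfgs = lambda th: optimize.minimize(nll, th, method="L-BFGS-B",
                                         jac="3-point", options=opts)
    best = lbfgs(theta0)
    # re-polish from a jittered incumbent plus a simplex pass: L-BFGS can
    # stall in shallow local optima along the beta-saturation ridge
    rng = np.random.default_rng(0)
    res = lbfgs(best.x + rng.normal(0, 0.2, len(theta0)))
    if res.fun < best.fun:
        best = res
    nm = optimize.minimize(nll, best.x, method="Nelder-Mead",
                           options={"maxiter": 150 * len(theta0),
                                    "fatol": 1e-9, "xatol": 1e-7})
    if nm.fun < best.fun - 1e-9:
        res = lbfgs(nm.x)
        best = res if res.fun < nm.fun else nm
    theta = best.x
    ll = -best.fun
    # convergence: gradient small relative to the likelihood magnitude
    jac = getattr(best, "jac", None)
    gnorm = float(np.max(np.abs(jac))) if jac is not None else np.inf
    converged = bool(best.success) or gnorm < 1e-4 * max(1.0, abs(ll))
    coefs = _unpack(theta, covariates, grouped)
    n_params = len(theta)
    se = {}
    if compute_se:
        H = _hessian(nll, theta)
        with np.errstate(invalid="ignore"):
            try:
                cov = np.linalg.pinv(H)
                d = np.diag(cov).copy()
                d[d < 0] = np.nan
                se = _coef_se(None, np.sqrt(d), covariates, grouped)
            except np.linalg.LinAlgError:
                se = {}
    return FitResult(spec=spec, coefficients=coefs, se=se, loglik=ll,
                     aic=2 * n_params - 2 * ll, n_params=n_params,
                     converged=converged, mode=mode,
                     animal_ids=[d.animal_id for d in fleet])


def fit(fleet: list[AnimalData], spec: ModelSpec, mode: str = "P",
        compute_se: bool = True,
        init_var_pos: float = DEFAULT_INIT_POS_VAR,
        covariate_index: dict[str, int] | None = None):
    """Maximum-likelihood fit of the link model.

    ``mode="P"`` pools all animals into one fit (one :class:`FitResult`);
    ``mode="I"`` fits each animal independently and returns a list.
    ``covariate_index`` maps covariate names to columns of ``AnimalData.X``
    (defaults to the order in ``spec.covariates``). Covariates with zero
    variance for an animal (I-mode) are dropped for that animal.
    """
    idx = covariate_index or {c: i for i, c in enumerate(spec.covariates)}
    sub_fleet = []
    for d in fleet:
        cols = [idx[c] for c in spec.covariates]
        sub_fleet.append(AnimalData(d.animal_id, d.xy, d.sd, d.dt,
                                    np.asarray(d.X, dtype=float)[:, cols],
                                    d.G))
    if mode == "P":
        return _fit_pooled(sub_fleet, spec, list(spec.covariates),
                           compute_se, init_var_pos, "P")
    if mode != "I":
        raise ValueError("mode must be 'I' or 'P'")
    results = []
    for d in sub_fleet:
        keep = [j for j in range(d.X.shape[1]) if np.var(d.X[:, j]) > 1e-12]
        covs = [spec.covariates[j] for j in keep]
        if len(covs) < len(spec.covariates):
            dropped = sorted(set(spec.covariates) - set(covs))
            warnings.warn(f"{d.animal_id}: zero-variance covariates dropped: {dropped}")
        di = AnimalData(d.animal_id, d.xy, d.sd, d.dt, d.X[:, keep], 0)
        ispec = ModelSpec(covariates=tuple(covs), grouping="none")
        results.append(_fit_pooled([di], ispec, covs, compute_se,
                                   init_var_pos, "I"))
    return results


def enumerate_models(pool, forbidden_pairs=(), groupings=("none",)) -> list[ModelSpec]:
    """All non-empty covariate subsets avoiding forbidden pairs, crossed
    with the grouping schemes."""
    pool = list(pool)
    forbidden = {frozenset(p) for p in forbidden_pairs}
    specs = []
    for r in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            if any(frozenset(p) <= set(combo) for p in forbidden):
                continue
            for g in groupings:
                specs.append(ModelSpec(covariates=tuple(combo), grouping=g))
    return specs


def aic_table(results: list[FitResult]) -> pd.DataFrame:
    """Rank fits by AIC (ascending) with ΔAIC; ties sort by model name."""
    rows = [{"model": r.spec.name, "k": r.n_params, "loglik": r.loglik,
             "aic": r.aic, "converged": r.converged} for r in results]
    df = pd.DataFrame(rows)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df.sort_values(["aic", "model"], kind="stable").reset_index(drop=True)


def ice_effect_ratio(fit_result, target: str = "sigma", group: str = "reference",
                     ice_covariate: str | None = None) -> float:
    """Ratio of the expected parameter in ice-free vs ice-covered habitat.

    Evaluates exp(-(C_ice + c_ice * G)) at reference covariate values,
    where C/c is the ICE slope and its group deviation of the sigma (A/a)
    or beta (B/b) predictor, and G = 0 for the reference group, 1 for the
    deviated group.
    """
    coefs = fit_result.coefficients if isinstance(fit_result, FitResult) else fit_result
    names = coefs.covariates
    if ice_covariate is None:
        ice = [c for c in names if c.upper().startswith("ICE")]
        if not ice:
            raise ValueError("fitted model has no ICE covariate")
        ice_covariate = ice[0]
    if ice_covariate not in names:
        raise ValueError(f"fitted model has no {ice_covariate} coefficient")
    j = names.index(ice_covariate)
    G = {"reference": 0, "deviated": 1}[group]
    if target == "sigma":
        return float(np.exp(-(coefs.A[j] + coefs.a[j] * G)))
    if target == "beta":
        return float(np.exp(-(coefs.B[j] + coefs.b[j] * G)))
    raise ValueError("target must be 'sigma' or 'beta'")
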