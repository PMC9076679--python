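"""Behavioural classification and descriptive track analyses.

Area-restricted search (ARS) is proxied by the lowest quartile of the
persistence time scale p_t = 3/beta_t and of the velocity scale sigma_t,
pooled across animals. The module also provides speed comparisons with a
Wilcoxon rank-sum test, migratory-duration statistics, and 95% minimum
convex polygon areas for the feeding grounds.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon


def classify_quartiles(values) -> np.ndarray:
    """Quartile labels 1..4 by pooled empirical quartiles, ties to the
    lower label (all-equal input is all Q1)."""
    v = np.asarray(values, dtype=float)
    q1, q2, q3 = np.quantile(v[np.isfinite(v)], [0.25, 0.5, 0.75])
    labels = 1 + (v > q1).astype(int) + (v > q2).astype(int) + (v > q3).astype(int)
    return labels


def behavior_series(sigma: np.ndarray, p: np.ndarray,
                    speed: np.ndarray | None = None) -> pd.DataFrame:
    """Pooled quartile classes for sigma and p plus ARS flags.

    The marginal ARS flags mark the lowest quartile of each variable;
    ``ars_joint`` requires both.
    """
    df = pd.DataFrame({"sigma": sigma, "p": p})
    if speed is not None:
        df["speed"] = speed
    df["sigma_q"] = classify_quartiles(df["sigma"])
    df["p_q"] = classify_quartiles(df["p"])
    df["ars_sigma"] = df["sigma_q"] == 1
    df["ars_p"] = df["p_q"] == 1
    df["ars_joint"] = df["ars_sigma"] & df["ars_p"]
    return df


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_v = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def rank_sum_test(x, y, exact_max_n: int = 16):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns (W, p) where W is the Mann–Whitney U statistic for sample x
    (the convention R's wilcox.test reports as W). Small samples
    (n1 + n2 <= ``exact_max_n``) use exact enumeration over all group
    assignments (tie-safe); larger samples use the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    W = r1 - n1 * (n1 + 1) / 2.0   # Mann–Whitney U for x
    if n1 + n2 <= exact_max_n:
        dev = abs(W - n1 * n2 / 2.0)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - n1 * n2 / 2.0) >= dev - 1e-12:
                count += 1
            total += 1
        return W, count / total
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return W, 1.0
    z = (abs(W - n1 * n2 / 2.0) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    from scipy.stats import norm
    return W, 2.0 * norm.sf(z)


def _describe(v: np.ndarray) -> dict:
    return {"n": len(v), "mean": float(np.mean(v)), "median": float(np.median(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "min": float(np.min(v)), "max": float(np.max(v))}


def speed_stats(df: pd.DataFrame, group_col: str = "group",
                lat_col: str = "lat", speed_col: str = "speed",
                lat_cut: float = -50.0):
    """Descriptive speed table per (group, side of lat_cut) stratum plus a
    rank-sum comparison of the two groups within each side."""
    df = df.copy()
    df["side"] = np.where(df[lat_col] > lat_cut, "north", "south")
    rows = []
    tests = {}
    for (g, side), sub in df.groupby([group_col, "side"]):
        v = np.asarray(sub[speed_col], dtype=float)
        if len(v) == 0:
            warnings.warn(f"empty stratum ({g}, {side}) omitted")
            continue
        rows.append({"group": g, "side": side, **_describe(v)})
    groups = sorted(df[group_col].unique())
    if len(groups) == 2:
        for side in ("north", "south"):
            a = df[(df[group_col] == groups[0]) & (df["side"] == side)][speed_col]
            b = df[(df[group_col] == groups[1]) & (df["side"] == side)][speed_col]
            if len(a) and len(b):
                W, p = rank_sum_test(a.to_numpy(), b.to_numpy())
                tests[side] = {"W": W, "p": p,
                               "groups": (groups[0], groups[1])}
    return pd.DataFrame(rows), tests


def migration_duration_stats(summary: pd.DataFrame,
                             grouping: str = "all") -> pd.DataFrame:
    """Mean/median/SD/range of migratory duration (days), NA excluded.

    ``grouping``: 'all', 'sex' (mothers = females vs males+), or 'period'.
    Expects a per-animal summary with columns m_time, sex, period.
    """
    df = summary.copy()
    df = df[pd.to_numeric(df["m_time"], errors="coerce").notna()]
    df["m_time"] = df["m_time"].astype(float)
    if grouping == "all":
        groups = {"all": df}
    elif grouping == "sex":
        groups = {"mothers": df[df["sex"] == "F"],
                  "males+": df[df["sex"] != "F"]}
    elif grouping == "period":
        groups = {f"period{p}": df[df["period"] == p] for p in (1, 2)}
    else:
        raise ValueError("grouping must be all, sex or period")
    rows = []
    for name, sub in groups.items():
        if len(sub) == 0:
            continue
        rows.append({"group": name, **_describe(sub["m_time"].to_numpy())})
    return pd.DataFrame(rows)


def mcp_area(xy: np.ndarray, coverage: float = 0.95):
    """Minimum convex polygon of the given coverage fraction of points.

    The (1-coverage) fraction of points farthest from the centroid is
    dropped (standard home-range convention); the convex hull of the rest
    is returned with its planar area in km^2 (input in projected km).
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 points for an MCP")
    centroid = xy.mean(axis=0)
    d = np.hypot(*(xy - centroid).T)
    n_keep = max(3, int(math.ceil(coverage * len(xy))))
    keep = np.argsort(d, kind="stable")[:n_keep]
    pts = xy[keep]
    hull = ConvexHull(pts)
    poly = Polygon(pts[hull.vertices])
    return poly, float(hull.volume)   # 2-D ConvexHull volume == area
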