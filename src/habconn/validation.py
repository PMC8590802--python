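"""Disperser-based evaluation of competing connectivity maps.

Each candidate disperser location (a "used" point, 1) is matched with a
small set of random "available" points (0's) inside a 5 km disc, and the
connectivity decile at every point is extracted from each candidate map.
A random-intercept logistic regression (location as the grouping factor)
of used/available on decile scores each map; AICc weights over the three
fits give the mixing weights for the final averaged connectivity map.

The mixed model's marginal likelihood integrates the per-location random
intercept with adaptive Gauss-Hermite quadrature centered and scaled at
the conditional mode (one quadrature node reduces to the Laplace
approximation).  The integrand is log-concave in the random effect, so the
inner Newton step is globally convergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit

from .geodata import Grid, PointSet
from .poprsf import aicc, akaike_weights

__all__ = [
    "MatchedSets",
    "MixedLogisticFit",
    "build_matched_sets",
    "fit_mixed_logistic",
    "rank_and_average_maps",
]


@dataclass
class MatchedSets:
    """Used/available rows with per-map deciles.

    ``table`` columns: location_id, used (1/0), x, y, then one decile
    column per map name.  ``dropped`` lists locations that could not be
    matched (e.g. disc outside the map extent).
    """

    table: pd.DataFrame
    map_names: list[str]
    dropped: list[str]


def build_matched_sets(
    dispersers: PointSet,
    maps: dict[str, Grid],
    buffer_m: float = 5000.0,
    n_avail: int = 3,
    seed=0,
    max_tries: int = 200,
) -> MatchedSets:
    """Match each used location with ``n_avail`` uniform points in its disc.

    Candidate available points falling outside the map extent or on nodata
    are redrawn; a location whose disc cannot supply valid points (or whose
    own cell is invalid) is dropped and reported.
    """
    rng = np.random.default_rng(seed)
    names = list(maps)
    ref = maps[names[0]]
    for nm in names[1:]:
        ref.require_same_geometry(maps[nm])
    rows, dropped = [], []
    for _, rec in dispersers.df.iterrows():
        loc_id = str(rec["id"])
        pts = [(rec["x"], rec["y"], 1)]
        if not bool(ref.contains(rec["x"], rec["y"])):
            dropped.append(loc_id)
            continue
        got = 0
        for _ in range(max_tries):
            if got >= n_avail:
                break
            u = rng.random(2)
            r = buffer_m * np.sqrt(u[0])
            th = 2 * np.pi * u[1]
            x, y = rec["x"] + r * np.cos(th), rec["y"] + r * np.sin(th)
            if not bool(ref.contains(x, y)):
                continue
            i, j = ref.cell_of(x, y)
            if not ref.valid_mask()[i, j]:
                continue
            pts.append((x, y, 0))
            got += 1
        if got < n_avail:
            dropped.append(loc_id)
            continue
        for x, y, used in pts:
            row = {"location_id": loc_id, "used": used, "x": x, "y": y}
            for nm in names:
                row[f"decile_{nm}"] = float(maps[nm].sample(x, y))
            rows.append(row)
    if not rows:
        raise ValueError("no matched sets could be built")
    return MatchedSets(pd.DataFrame(rows), names, dropped)


@dataclass
class MixedLogisticFit:
    """Random-intercept logistic regression of used/available on one decile."""

    map_name: str
    intercept: float
    slope: float
    sigma: float  # SD of the per-location random intercept
    llf: float
    k: int
    n: int
    aicc: float
    n_groups: int
    converged: bool


def _group_matrices(groups: np.ndarray, y: np.ndarray, x: np.ndarray):
    """Pad per-group rows into (G, max_m) matrices with a validity mask."""
    uniq, inv = np.unique(groups, return_inverse=True)
    counts = np.bincount(inv)
    G, M = uniq.size, int(counts.max())
    Y = np.zeros((G, M))
    X = np.zeros((G, M))
    W = np.zeros((G, M), bool)
    slot = np.zeros(uniq.size, int)
    for r, g in enumerate(inv):
        c = slot[g]
        Y[g, c] = y[r]
        X[g, c] = x[r]
        W[g, c] = True
        slot[g] += 1
    return Y, X, W


def _marginal_llf(params, Y, X, W, nodes, weights) -> float:
    """Sum over groups of log integral of the Bernoulli likelihood against
    the random-intercept density, by mode-centered Gauss-Hermite."""
    b0, b1, log_sigma = params
    sigma = np.exp(log_sigma)
    A = b0 + b1 * X  # (G, M) linear predictor without the random effect
    z = np.zeros(Y.shape[0])
    for _ in range(50):  # Newton for the per-group conditional mode
        p = expit(A + sigma * z[:, None])
        g1 = sigma * ((Y - p) * W).sum(axis=1) - z
        g2 = -(sigma**2) * (p * (1 - p) * W).sum(axis=1) - 1.0
        step = g1 / g2
        z = z - step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(A + sigma * z[:, None])
    h2 = (sigma**2) * (p * (1 - p) * W).sum(axis=1) + 1.0  # -h''(z_hat)
    tau = 1.0 / np.sqrt(h2)
    # integral ~ sqrt(2) tau sum_k w_k exp(t_k^2) exp(h(z_hat + sqrt(2) tau t_k))
    zk = z[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]  # (G, K)
    eta = A[:, :, None] + sigma * zk[:, None, :]  # (G, M, K)
    ll_obs = np.where(
        W[:, :, None], Y[:, :, None] * eta - np.logaddexp(0.0, eta), 0.0
    ).sum(axis=1)
    h = ll_obs - 0.5 * zk**2 - 0.5 * np.log(2 * np.pi)  # (G, K)
    hmax = h.max(axis=1, keepdims=True)
    integ = np.sqrt(2.0) * tau * (
        weights[None, :] * np.exp(nodes[None, :] ** 2 + h - hmax)
    ).sum(axis=1)
    return float(np.sum(np.log(integ) + hmax.ravel()))


def fit_mixed_logistic(
    matched: MatchedSets, map_name: str, n_nodes: int = 7
) -> MixedLogisticFit:
    """Fit used ~ decile + (1 | location) by marginal maximum likelihood.

    ``n_nodes`` Gauss-Hermite nodes are centered at the conditional mode of
    each location's random intercept; ``n_nodes=1`` is the Laplace
    approximation.  k = 3 (intercept, slope, random-intercept SD).
    """
    col = f"decile_{map_name}"
    if col not in matched.table.columns:
        raise KeyError(f"no decile column for map {map_name!r}")
    df = matched.table
    y = df["used"].to_numpy(float)
    x = df[col].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError(f"decile values for map {map_name!r} show no variation")
    groups = df["location_id"].to_numpy()
    if pd.unique(groups).size < 2:
        raise ValueError("need >= 2 locations")
    Y, X, W = _group_matrices(groups, y, x)
    nodes, weights = hermgauss(n_nodes)
    # start from the plain logistic fit with a small random-effect SD
    xc = x - x.mean()
    b1_0 = 0.0
    b0_0 = np.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
    res = minimize(
        lambda p: -_marginal_llf(p, Y, X, W, nodes, weights),
        x0=np.array([b0_0 - b1_0 * x.mean(), b1_0, np.log(0.25)]),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000},
    )
    if not res.success:
        raise RuntimeError(f"mixed logistic fit did not converge: {res.message}")
    b0, b1, log_sigma = res.x
    llf = -float(res.fun)
    k, n = 3, len(y)
    del xc
    return MixedLogisticFit(
        map_name=map_name,
        intercept=float(b0),
        slope=float(b1),
        sigma=float(np.exp(log_sigma)),
        llf=llf,
        k=k,
        n=n,
        aicc=aicc(llf, k, n),
        n_groups=Y.shape[0],
        converged=bool(res.success),
    )


def rank_and_average_maps(
    fits: list[MixedLogisticFit], maps: dict[str, Grid]
) -> tuple[dict[str, float], Grid]:
    """Akaike weights over the fits and the weighted average of the maps.

    Each map is first normalized to unit mean over its valid cells (the raw
    current maps are on incomparable scales), then averaged with the AICc
    weights.  Requires all fits to share the matched data and all maps to
    share geometry.
    """
    if len({f.n for f in fits}) != 1:
        raise ValueError("fits must be on identical matched sets")
    names = [f.map_name for f in fits]
    ref = maps[names[0]]
    for nm in names[1:]:
        if not ref.same_geometry(maps[nm]):
            from .geodata import GeometryError

            raise GeometryError(f"map {nm!r} geometry differs")
    a = np.array([f.aicc for f in fits])
    w = akaike_weights(a - a.min())
    weights = {nm: float(wi) for nm, wi in zip(names, w)}
    mask = ref.valid_mask()
    for nm in names[1:]:
        mask &= maps[nm].valid_mask()
    avg = np.zeros(ref.shape)
    for nm in names:
        vals = maps[nm].values
        mean = vals[mask].mean()
        if mean <= 0:
            raise ValueError(f"map {nm!r} has nonpositive mean; cannot normalize")
        avg[mask] += weights[nm] * vals[mask] / mean
    out = np.where(mask, avg, ref.nodata)
    return weights, Grid(out, ref.cell_size, ref.origin, ref.nodata, ref.crs_tag)
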