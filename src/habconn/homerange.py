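"""Individual-level (within home range) habitat selection.

Home ranges are 95% isopleths of a bivariate Gaussian kernel density
estimate of each animal's fixes (reference bandwidth per axis).  Used
fixes are contrasted against an equal number of availability points drawn
uniformly within the isopleth, and selection is estimated with a
distribution-weighted use-availability likelihood: each animal contributes
equal total weight regardless of its fix count, so well-collared
individuals do not dominate the pooled fit.  The exponential form scores
relative selection w(x) = exp(beta.x); the logistic form returns bounded
selection probabilities; the two are compared by consistent AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, kruskal

from .covariates import CovariateStack
from .geodata import Grid, PointSet
from .poprsf import SeparationError

__all__ = [
    "HomeRange",
    "RSFFit",
    "filter_individuals",
    "kde_home_range",
    "kruskal_wallis",
    "sample_availability",
    "fit_weighted_rsf",
    "caic",
    "compare_forms",
    "rss_use_curve",
]


@dataclass
class HomeRange:
    """95% (by default) utilization-distribution isopleth of one animal."""

    individual_id: str
    mask_grid: Grid  # 1 inside the isopleth, 0 outside, on a local grid
    area_km2: float
    bandwidth: tuple[float, float]
    n_fixes: int
    isopleth: float = 0.95
    sex: str | None = None
    study_area: str | None = None


def filter_individuals(
    telemetry: PointSet, min_fixes: int = 30, exclude: tuple = ()
) -> tuple[PointSet, pd.DataFrame]:
    """Keep resident individuals with more than ``min_fixes`` fixes.

    ``exclude`` lists individual ids flagged as dispersers.  Returns the
    filtered PointSet and a per-individual report (kept/why dropped).
    """
    df = telemetry.df
    if df["individual_id"].isna().all():
        raise ValueError("telemetry has no individual ids")
    counts = df.groupby("individual_id").size()
    rows = []
    keep_ids = []
    for ind, cnt in counts.items():
        if ind in exclude:
            rows.append((ind, cnt, "dropped: disperser"))
        elif cnt <= min_fixes:
            rows.append((ind, cnt, f"dropped: <= {min_fixes} fixes"))
        else:
            rows.append((ind, cnt, "kept"))
            keep_ids.append(ind)
    report = pd.DataFrame(rows, columns=["individual_id", "n_fixes", "status"])
    out = telemetry.subset(df["individual_id"].isin(keep_ids))
    if len(out) == 0:
        raise ValueError("no individuals left after filtering")
    return out, report


def _href(xy: np.ndarray) -> tuple[float, float]:
    """Per-axis reference bandwidth h_i = sigma_i * n^(-1/6)."""
    n = len(xy)
    sx = xy[:, 0].std(ddof=1)
    sy = xy[:, 1].std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate fixes (zero spread); provide an explicit bandwidth")
    f = n ** (-1.0 / 6.0)
    return sx * f, sy * f


def kde_home_range(
    fixes: PointSet | np.ndarray,
    isopleth: float = 0.95,
    bandwidth: tuple[float, float] | float | None = None,
    grid_res: int = 200,
    pad_bandwidths: float = 4.0,
    individual_id: str = "",
    min_fixes: int = 1,
) -> HomeRange:
    """Home range as the smallest cell set holding ``isopleth`` of the KDE mass.

    The density is a product-Gaussian KDE evaluated on a local grid
    extending ``pad_bandwidths`` bandwidths beyond the fixes at
    >= ``grid_res`` cells per axis; the area is the cell count times the
    cell area.
    """
    xy = fixes.xy if isinstance(fixes, PointSet) else np.asarray(fixes, float)
    if len(xy) < min_fixes:
        raise ValueError(f"need >= {min_fixes} fixes, got {len(xy)}")
    if bandwidth is None:
        if len(xy) < 5:
            raise ValueError("need >= 5 fixes for a reference bandwidth")
        hx, hy = _href(xy)
    elif np.isscalar(bandwidth):
        hx = hy = float(bandwidth)
    else:
        hx, hy = map(float, bandwidth)
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    x0 = xmin - pad_bandwidths * hx
    x1 = xmax + pad_bandwidths * hx
    y0 = ymin - pad_bandwidths * hy
    y1 = ymax + pad_bandwidths * hy
    cell = max((x1 - x0), (y1 - y0)) / grid_res
    nx = int(np.ceil((x1 - x0) / cell))
    ny = int(np.ceil((y1 - y0) / cell))
    xs = x0 + (np.arange(nx) + 0.5) * cell
    ys = y0 + (np.arange(ny) + 0.5) * cell
    # separable Gaussian KDE as a matrix product: D = Gy @ Gx.T / (n 2 pi hx hy)
    Gx = np.exp(-0.5 * ((xs[:, None] - xy[None, :, 0]) / hx) ** 2)
    Gy = np.exp(-0.5 * ((ys[:, None] - xy[None, :, 1]) / hy) ** 2)
    dens = (Gy @ Gx.T) / (len(xy) * 2 * np.pi * hx * hy)
    mass = dens * cell * cell
    order = np.argsort(mass.ravel())[::-1]
    csum = np.cumsum(mass.ravel()[order])
    target = isopleth * mass.sum()  # normalize for truncation to the local grid
    n_in = int(np.searchsorted(csum, target) + 1)
    sel = order[:n_in]
    maskv = np.zeros(mass.size)
    maskv[sel] = 1.0
    mask = maskv.reshape(ny, nx)
    area_km2 = n_in * (cell / 1000.0) ** 2
    grid = Grid(mask, cell, (x0, y0), nodata=-9999)
    kwargs = {}
    if isinstance(fixes, PointSet):
        for col in ("sex", "study_area"):
            vals = fixes.df[col].dropna().unique()
            kwargs[col] = vals[0] if len(vals) else None
        if not individual_id:
            inds = fixes.individuals()
            individual_id = str(inds[0]) if inds else ""
    return HomeRange(
        individual_id=individual_id,
        mask_grid=grid,
        area_km2=float(area_km2),
        bandwidth=(hx, hy),
        n_fixes=len(xy),
        isopleth=isopleth,
        **kwargs,
    )


def kruskal_wallis(values, group_labels):
    """Rank-based k-sample test; returns (H, df, p) with tie correction."""
    values = np.asarray(values, float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    res = kruskal(*groups)
    df = len(groups) - 1
    return float(res.statistic), df, float(chi2.sf(res.statistic, df))


def sample_availability(
    home_range: HomeRange, n: int, seed=0, within: Grid | None = None
) -> PointSet:
    """n uniform points inside the isopleth mask (cell choice + in-cell jitter).

    ``within`` optionally restricts the draw to the extent of another grid
    (e.g. the covariate landscape) when the isopleth spills past its edge.
    """
    rng = np.random.default_rng(seed)
    g = home_range.mask_grid
    inside = np.flatnonzero(g.values.ravel() > 0.5)
    if inside.size == 0:
        raise ValueError("empty home-range mask")
    xs_parts, ys_parts = [], []
    got = 0
    for _ in range(200):
        m = max(n - got, 32)
        cells = rng.choice(inside, size=m, replace=True)
        ii, jj = np.unravel_index(cells, g.shape)
        s = g.cell_size
        px = g.origin[0] + (jj + rng.uniform(0, 1, m)) * s
        py = g.origin[1] + (ii + rng.uniform(0, 1, m)) * s
        if within is not None:
            ok = within.contains(px, py)
            px, py = px[ok], py[ok]
        take = min(n - got, px.size)
        xs_parts.append(px[:take])
        ys_parts.append(py[:take])
        got += take
        if got >= n:
            break
    else:
        raise RuntimeError(
            f"could not place {n} availability points inside the constraint extent"
        )
    x = np.concatenate(xs_parts)
    y = np.concatenate(ys_parts)
    return PointSet.from_arrays(
        x,
        y,
        "available",
        ids=[f"{home_range.individual_id}_av{k}" for k in range(n)],
        individual_id=home_range.individual_id,
    )


@dataclass
class RSFFit:
    """A fitted within-home-range selection model."""

    form: str  # "exponential_RSF" | "logistic_RSPF"
    terms: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    weighting: str
    llf: float
    k: int
    n_effective: int
    caic: float

    def score(self, X: np.ndarray) -> np.ndarray:
        """Selection score at covariate rows: exp(beta.x) (relative) for the
        exponential RSF, expit(b0 + beta.x) (probability) for the RSPF."""
        X = np.asarray(X, float)
        eta = X @ np.array([self.coef[t] for t in self.terms])
        if self.form == "exponential_RSF":
            return np.exp(eta)
        return expit(self.coef["intercept"] + eta)


def _observation_weights(ind_ids: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "none":
        return np.ones(len(ind_ids))
    if scheme != "distribution":
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    ids, counts = np.unique(ind_ids, return_counts=True)
    n_total, n_ind = len(ind_ids), len(ids)
    per = {i: n_total / (n_ind * c) for i, c in zip(ids, counts)}
    return np.array([per[i] for i in ind_ids])


def fit_weighted_rsf(
    used: PointSet,
    available: PointSet,
    stack: CovariateStack,
    terms=None,
    form: str = "exponential_RSF",
    weighting: str = "distribution",
    weights: np.ndarray | None = None,
) -> RSFFit:
    """Use-availability likelihood with per-observation weights.

    With ``weighting='distribution'`` each individual's observations get
    weight N_total / (I * n_i) so every animal contributes equal total
    weight; ``'none'`` pools observations unweighted.  Explicit ``weights``
    override the scheme.  Every used individual must contribute availability
    points.
    """
    if form not in ("exponential_RSF", "logistic_RSPF"):
        raise ValueError(f"unknown form {form!r}")
    terms = list(terms or stack.names)
    used_inds = set(used.df["individual_id"].dropna())
    avail_inds = set(available.df["individual_id"].dropna())
    missing = used_inds - avail_inds
    if used_inds and missing:
        raise ValueError(f"individuals lacking availability points: {sorted(missing, key=str)}")
    Xu = stack.sample(used.df["x"], used.df["y"], terms)
    Xa = stack.sample(available.df["x"], available.df["y"], terms)
    X = np.vstack([Xu, Xa])
    y = np.r_[np.ones(len(Xu)), np.zeros(len(Xa))]
    ind = np.r_[used.df["individual_id"].astype(str), available.df["individual_id"].astype(str)]
    w = np.asarray(weights, float) if weights is not None else _observation_weights(ind, weighting)
    Xc = np.column_stack([np.ones(len(y)), X])
    res = sm.GLM(y, Xc, family=sm.families.Binomial(), var_weights=w).fit(maxiter=200)
    mu = res.fittedvalues
    if np.all((mu > 1 - 1e-10) == (y == 1)) and np.all((mu < 1e-10) == (y == 0)):
        raise SeparationError("perfect separation in weighted RSF fit")
    k = Xc.shape[1]
    n_eff = len(y)
    names = ("intercept",) + tuple(terms)
    return RSFFit(
        form=form,
        terms=tuple(terms),
        coef=dict(zip(names, res.params)),
        se=dict(zip(names, res.bse)),
        weighting=weighting if weights is None else "explicit",
        llf=float(res.llf),
        k=k,
        n_effective=n_eff,
        caic=caic(float(res.llf), k, n_eff),
    )


def caic(llf: float, k: int, n: int) -> float:
    """Consistent AIC: -2 LL + k (ln n + 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * llf + k * (np.log(n) + 1.0)


def compare_forms(fits: list[RSFFit]) -> RSFFit:
    """Pick the fit with the lowest CAIC; all fits must share the data."""
    if len({f.n_effective for f in fits}) != 1:
        raise ValueError("compared fits must use identical data (n differs)")
    return min(fits, key=lambda f: f.caic)


def rss_use_curve(
    fit: RSFFit,
    available: PointSet,
    stack: CovariateStack,
    covariate: str,
    frac: float = 0.75,
) -> pd.DataFrame:
    """Use-probability curve: fitted score at available points against one
    covariate, with a local-regression (lowess) smooth.

    The curve depicts probability of *use* under the current availability of
    the other covariates: change the availability and the curve changes too.
    """
    if covariate not in fit.terms:
        raise KeyError(f"covariate {covariate!r} not in fitted terms {fit.terms}")
    terms = list(fit.terms)
    X = stack.sample(available.df["x"], available.df["y"], terms)
    scores = fit.score(X)
    xv = X[:, terms.index(covariate)]
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sm_xy = lowess(scores, xv, frac=frac, it=1)
    out = pd.DataFrame({"x": xv, "fitted": scores})
    out = out.sort_values("x").reset_index(drop=True)
    out["smooth"] = np.interp(out["x"], sm_xy[:, 0], sm_xy[:, 1])
    return out
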