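"""Population-level habitat selection (use-availability logistic RSF).

Presence records are contrasted against pseudo-absences drawn uniformly
outside an exclusion buffer around every presence (buffer radius = radius
of a circle with the mean home-range area).  Candidate logistic models are
ranked by AICc, models within a delta cutoff of the best are averaged on
the probability scale, and predictive skill is summarised by AUC and
repeated split-sample accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from scipy.special import expit

from .covariates import CovariateStack
from .geodata import Grid, PointSet

__all__ = [
    "FittedModel",
    "buffer_radius_from_area",
    "generate_pseudo_absences",
    "build_design",
    "fit_logistic",
    "aicc",
    "akaike_weights",
    "rank_models",
    "model_average_predict",
    "auc_roc",
    "kfold_accuracy",
]


@dataclass
class FittedModel:
    """A fitted candidate model with its information-theoretic bookkeeping."""

    terms: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    llf: float
    k: int
    n: int
    aicc: float
    delta: float = np.nan
    weight: float = np.nan
    label: str = ""

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        b, s = self.coef[term], self.se[term]
        return b - z * s, b + z * s

    def predict_eta(self, X: np.ndarray) -> np.ndarray:
        beta = np.array([self.coef["intercept"]] + [self.coef[t] for t in self.terms])
        return np.column_stack([np.ones(len(X)), X]) @ beta


def buffer_radius_from_area(area_km2: float, round_to: float = 100.0):
    """Radius (m) of a circle whose area equals ``area_km2``.

    Returns ``(radius_m, rounded_m)``: e.g. a 99.7 km^2 mean home range
    gives 5633 m, rounded to 5600 m.
    """
    if area_km2 <= 0:
        raise ValueError(f"area must be > 0, got {area_km2}")
    r = math.sqrt(area_km2 * 1e6 / math.pi)
    return r, round(r / round_to) * round_to


def generate_pseudo_absences(
    presences: PointSet,
    extent_grid: Grid,
    ratio: float = 4.0,
    buffer_m: float = 5600.0,
    seed=0,
    max_iter: int = 1000,
) -> PointSet:
    """Uniform random points over the valid extent, all at least ``buffer_m``
    from every presence; count = ratio x n_presences (rejection sampling)."""
    rng = np.random.default_rng(seed)
    n_needed = int(round(ratio * len(presences)))
    tree = cKDTree(presences.xy)
    xmin, ymin, xmax, ymax = extent_grid.extent
    mask = extent_grid.valid_mask()
    xs, ys = [], []
    got = 0
    for _ in range(max_iter):
        m = max((n_needed - got) * 3, 256)
        x = rng.uniform(xmin, xmax, m)
        y = rng.uniform(ymin, ymax, m)
        i, j = extent_grid.cell_of(x, y)
        ok = mask[i, j]
        x, y = x[ok], y[ok]
        if x.size:
            d, _ = tree.query(np.column_stack([x, y]), k=1)
            x, y = x[d >= buffer_m], y[d >= buffer_m]
        take = min(n_needed - got, x.size)
        xs.append(x[:take])
        ys.append(y[:take])
        got += take
        if got >= n_needed:
            break
    else:
        raise RuntimeError(
            f"pseudo-absence sampling attained only {got}/{n_needed} points; "
            "free area outside buffers may be (nearly) empty"
        )
    if got == 0:
        raise RuntimeError("free area outside presence buffers is empty")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return PointSet.from_arrays(x, y, "pseudo_absence", ids=[f"abs{k}" for k in range(got)])


def build_design(
    presences: PointSet, absences: PointSet, stack: CovariateStack, terms=None
) -> pd.DataFrame:
    """Use-availability table: response 1/0 plus covariates sampled at points."""
    terms = list(terms or stack.names)
    Xp = stack.sample(presences.df["x"], presences.df["y"], terms)
    Xa = stack.sample(absences.df["x"], absences.df["y"], terms)
    df = pd.DataFrame(np.vstack([Xp, Xa]), columns=terms)
    df.insert(0, "response", np.r_[np.ones(len(presences)), np.zeros(len(absences))].astype(int))
    return df


class SeparationError(RuntimeError):
    pass


def fit_logistic(data: pd.DataFrame, terms) -> FittedModel:
    """Maximum-likelihood binomial GLM (logit link) of response on ``terms``.

    Raises on rank-deficient designs and on (quasi-)perfect separation,
    naming the offending term where identifiable.
    """
    terms = tuple(terms)
    y = data["response"].to_numpy(float)
    X = data[list(terms)].to_numpy(float) if terms else np.empty((len(data), 0))
    Xc = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise np.linalg.LinAlgError(f"design matrix rank-deficient for terms {terms}")
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    mu = res.fittedvalues
    eps = 1e-10
    if terms and (np.all((mu > 1 - eps) == (y == 1)) and np.all((mu < eps) == (y == 0))):
        worst = terms[int(np.argmax(np.abs(res.params[1:])))]
        raise SeparationError(f"perfect separation; term {worst!r} separates the classes")
    k = Xc.shape[1]
    n = len(y)
    names = ("intercept",) + terms
    coef = dict(zip(names, res.params))
    se = dict(zip(names, res.bse))
    return FittedModel(
        terms=terms,
        coef=coef,
        se=se,
        llf=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        label=" + ".join(terms) if terms else "null",
    )


def aicc(llf: float, k: int, n: int) -> float:
    """AICc = -2 LL + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(deltas) -> np.ndarray:
    """exp(-delta/2), normalized to sum to one."""
    d = np.asarray(deltas, float)
    rel = np.exp(-d / 2.0)
    return rel / rel.sum()


def rank_models(models: list[FittedModel]) -> list[FittedModel]:
    """Order by AICc; attach delta-AICc and Akaike weights."""
    if not models:
        raise ValueError("empty model set")
    models = sorted(models, key=lambda m: m.aicc)
    best = models[0].aicc
    deltas = np.array([m.aicc - best for m in models])
    w = akaike_weights(deltas)
    for m, d, wi in zip(models, deltas, w):
        m.delta = float(d)
        m.weight = float(wi)
    return models


def model_table(models: list[FittedModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [m.label for m in models],
            "k": [m.k for m in models],
            "log_likelihood": [m.llf for m in models],
            "aicc": [m.aicc for m in models],
            "delta_aicc": [m.delta for m in models],
            "weight": [m.weight for m in models],
        }
    )


def model_average_predict(
    models: list[FittedModel], stack: CovariateStack, delta_cutoff: float = 2.0
) -> Grid:
    """Akaike-weight-averaged probability surface over models within
    ``delta_cutoff`` of the best (weights renormalized over that set)."""
    ranked = rank_models(list(models))
    kept = [m for m in ranked if m.delta <= delta_cutoff]
    w = np.array([m.weight for m in kept])
    w = w / w.sum()
    geom = stack.geometry()
    mask = stack.valid_mask()
    H = np.zeros(geom.shape)
    for m, wi in zip(kept, w):
        X = stack.design_matrix(list(m.terms), mask)
        p = expit(m.predict_eta(X))
        H[mask] += wi * p
    out = np.where(mask, H, geom.nodata)
    return Grid(out, geom.cell_size, geom.origin, geom.nodata, geom.crs_tag)


def auc_roc(scores, labels) -> float:
    """Rank-statistic (Mann-Whitney) AUC with tie correction."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def kfold_accuracy(
    data: pd.DataFrame,
    terms,
    train_frac: float = 0.95,
    reps: int = 1000,
    seed=0,
    threshold: float = 0.5,
):
    """Repeated split-sample classification accuracy.

    Each rep refits on a ``train_frac`` subsample and scores the held-out
    fraction at the given probability threshold; splits lacking a class are
    redrawn.  Returns (mean accuracy, per-rep accuracies).
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError(f"cannot split n={n} at train_frac={train_frac}")
    y = data["response"].to_numpy(int)
    accs = np.empty(reps)
    for rep in range(reps):
        for _ in range(100):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if len(set(y[tr])) == 2:
                break
        else:
            raise RuntimeError("could not find a split with both classes in training data")
        fit = fit_logistic(data.iloc[tr], terms)
        X = data.iloc[te][list(terms)].to_numpy(float)
        pred = (expit(fit.predict_eta(X)) >= threshold).astype(int)
        accs[rep] = float(np.mean(pred == y[te]))
    return float(accs.mean()), accs


def build_candidate_models(
    scale_sets: dict[str, list[str]], extra_terms: list[str] | None = None
) -> list[tuple[str, ...]]:
    """Candidate term lists: one scale per land-cover variable per model,
    optional shared terms (e.g. distance to main roads), plus a null model."""
    import itertools

    extra = tuple(extra_terms or ())
    cands: list[tuple[str, ...]] = [()]
    names = list(scale_sets)
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            for choice in itertools.product(*[scale_sets[c] for c in combo]):
                cands.append(extra + tuple(choice))
    return cands
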