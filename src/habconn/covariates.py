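"""Raster covariates for habitat-selection models.

Land-cover composition is summarised with square moving windows whose edge
is the square root of the window area (a 7 km^2 window on a 30 m raster has
an edge of 2.65 km, i.e. 89 cells after rounding to an odd count), the scale
at which daily movements and home-range-fraction areas are expressed.
Distances are exact Euclidean distances between cell centers; road density
is kilometers of road per square kilometer inside the same square windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, box

from .geodata import GeometryError, Grid, LineSet

__all__ = [
    "CovariateStack",
    "window_edge_cells",
    "window_proportion",
    "rasterize_lines",
    "distance_to",
    "road_density",
    "scale_covariates",
    "correlation_screen",
]


def window_edge_cells(window_area_km2: float, cell_size_m: float) -> int:
    """Odd cell count of the square window with the given area.

    The window edge is sqrt(area); e.g. 7 km^2 -> 2.646 km -> 88.2 cells at
    30 m, rounded to the nearest odd count, 89.
    """
    if window_area_km2 <= 0:
        raise ValueError(f"window area must be > 0, got {window_area_km2}")
    edge_m = math.sqrt(window_area_km2) * 1000.0
    n = edge_m / cell_size_m
    if n < 1:
        raise ValueError(
            f"window edge {edge_m:.0f} m is smaller than one {cell_size_m:.0f} m cell"
        )
    odd = 2 * round((n - 1) / 2) + 1
    return int(max(odd, 1))


def _window_mean(arr: np.ndarray, valid: np.ndarray, edge: int) -> np.ndarray:
    """Mean of ``arr`` over valid cells in an edge x edge window, truncated at
    the grid boundary (proportions are taken over the available cells)."""
    a = np.where(valid, arr, 0.0)
    ssum = ndimage.uniform_filter(a, size=edge, mode="constant", cval=0.0) * edge * edge
    cnt = ndimage.uniform_filter(valid.astype(float), size=edge, mode="constant", cval=0.0)
    cnt = cnt * edge * edge
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ssum / cnt
    return out, cnt


def window_proportion(landcover: Grid, cls, window_area_km2: float) -> Grid:
    """Fraction of in-window, valid cells equal to ``cls``.

    Windows are square with edge sqrt(area) rounded to an odd cell count and
    truncated at the grid boundary; nodata cells are excluded from both the
    numerator and the denominator.
    """
    edge = window_edge_cells(window_area_km2, landcover.cell_size)
    valid = landcover.valid_mask()
    indicator = (landcover.values == cls).astype(float)
    prop, cnt = _window_mean(indicator, valid, edge)
    prop = np.clip(prop, 0.0, 1.0)
    prop[cnt < 0.5] = np.nan
    prop[~valid] = np.nan
    out = np.where(np.isnan(prop), landcover.nodata, prop)
    return Grid(out, landcover.cell_size, landcover.origin, landcover.nodata, landcover.crs_tag)


def rasterize_lines(lines: LineSet, grid_geom: Grid, classes=None) -> np.ndarray:
    """Boolean mask of cells crossed by any line of the given classes.

    A cell counts as crossed when the polyline intersects its half-open
    square; implemented by exact segment/box intersection.
    """
    feats = lines.features if classes is None else lines.of_class(*classes).features
    mask = np.zeros(grid_geom.shape, bool)
    s = grid_geom.cell_size
    x0, y0 = grid_geom.origin
    nr, nc = grid_geom.shape
    for f in feats:
        coords = f["coords"]
        for (xa, ya), (xb, yb) in zip(coords[:-1], coords[1:]):
            j0 = int(np.floor((min(xa, xb) - x0) / s))
            j1 = int(np.floor((max(xa, xb) - x0) / s))
            i0 = int(np.floor((min(ya, yb) - y0) / s))
            i1 = int(np.floor((max(ya, yb) - y0) / s))
            seg = LineString([(xa, ya), (xb, yb)])
            for i in range(max(i0, 0), min(i1, nr - 1) + 1):
                for j in range(max(j0, 0), min(j1, nc - 1) + 1):
                    cell = box(x0 + j * s, y0 + i * s, x0 + (j + 1) * s, y0 + (i + 1) * s)
                    if seg.intersects(cell):
                        mask[i, j] = True
    return mask


def distance_to(source, grid_geom: Grid, classes=None) -> Grid:
    """Euclidean distance (m) from each cell center to the nearest source cell.

    ``source`` may be a LineSet (rasterized first), a boolean cell mask, or a
    Grid whose nonzero valid cells are sources.
    """
    if isinstance(source, LineSet):
        mask = rasterize_lines(source, grid_geom, classes)
    elif isinstance(source, Grid):
        grid_geom.require_same_geometry(source)
        mask = source.valid_mask() & (source.values != 0)
    else:
        mask = np.asarray(source, bool)
        if mask.shape != grid_geom.shape:
            raise GeometryError("source mask shape does not match grid")
    if not mask.any():
        raise ValueError("empty source set: no cells to measure distance to")
    dist = ndimage.distance_transform_edt(~mask, sampling=grid_geom.cell_size)
    return Grid(dist, grid_geom.cell_size, grid_geom.origin, grid_geom.nodata, grid_geom.crs_tag)


def _cell_lengths(lines: LineSet, grid_geom: Grid, classes=None) -> np.ndarray:
    """Exact length (m) of line per cell, by segment/cell-box clipping."""
    feats = lines.features if classes is None else lines.of_class(*classes).features
    out = np.zeros(grid_geom.shape)
    s = grid_geom.cell_size
    x0, y0 = grid_geom.origin
    nr, nc = grid_geom.shape
    for f in feats:
        coords = f["coords"]
        for (xa, ya), (xb, yb) in zip(coords[:-1], coords[1:]):
            seg = LineString([(xa, ya), (xb, yb)])
            j0 = int(np.floor((min(xa, xb) - x0) / s))
            j1 = int(np.floor((max(xa, xb) - x0) / s))
            i0 = int(np.floor((min(ya, yb) - y0) / s))
            i1 = int(np.floor((max(ya, yb) - y0) / s))
            for i in range(max(i0, 0), min(i1, nr - 1) + 1):
                for j in range(max(j0, 0), min(j1, nc - 1) + 1):
                    cell = box(x0 + j * s, y0 + i * s, x0 + (j + 1) * s, y0 + (i + 1) * s)
                    L = seg.intersection(cell).length
                    if L > 0:
                        out[i, j] += L
    return out


def road_density(lines: LineSet, grid_geom: Grid, window_area_km2: float, classes=None) -> Grid:
    """Kilometers of road per km^2 within the square window around each cell."""
    edge = window_edge_cells(window_area_km2, grid_geom.cell_size)
    km_per_cell = _cell_lengths(lines, grid_geom, classes) / 1000.0
    ssum = ndimage.uniform_filter(km_per_cell, size=edge, mode="constant", cval=0.0)
    ssum = ssum * edge * edge
    cnt = ndimage.uniform_filter(np.ones(grid_geom.shape), size=edge, mode="constant", cval=0.0)
    area_km2 = cnt * edge * edge * (grid_geom.cell_size / 1000.0) ** 2
    dens = ssum / area_km2
    return Grid(dens, grid_geom.cell_size, grid_geom.origin, grid_geom.nodata, grid_geom.crs_tag)


@dataclass
class CovariateStack:
    """Named covariate grids sharing one geometry, with scaling metadata.

    ``means``/``sds`` hold the statistics used by :func:`scale_covariates`
    so that predictions on new data can reuse the training scaling.
    """

    grids: dict[str, Grid]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        names = list(self.grids)
        if names:
            ref = self.grids[names[0]]
            for nm in names[1:]:
                ref.require_same_geometry(self.grids[nm])

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def geometry(self) -> Grid:
        return next(iter(self.grids.values()))

    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.geometry().shape, bool)
        for g in self.grids.values():
            m &= g.valid_mask()
        return m

    def design_matrix(self, names=None, mask=None) -> np.ndarray:
        """(n_cells, n_covariates) matrix over valid (or given-mask) cells.

        An explicit empty name list yields a zero-column matrix (null model).
        """
        names = self.names if names is None else list(names)
        if mask is None:
            mask = self.valid_mask()
        n = int(np.count_nonzero(mask))
        if not names:
            return np.empty((n, 0))
        return np.column_stack([self.grids[nm].values[mask] for nm in names])

    def sample(self, x, y, names=None) -> np.ndarray:
        names = self.names if names is None else list(names)
        if not names:
            return np.empty((len(np.asarray(x, float)), 0))
        return np.column_stack([self.grids[nm].sample(x, y) for nm in names])


def scale_covariates(stack: CovariateStack) -> CovariateStack:
    """Center and scale each covariate to mean 0, SD 1 over valid cells.

    The per-covariate mean and SD are retained on the returned stack so the
    same transform can be applied to points or held-out data.  A constant
    covariate cannot be scaled and raises a ValueError naming it.
    """
    mask = None
    out, means, sds = {}, {}, {}
    for name, g in stack.grids.items():
        if mask is None:
            mask = stack.valid_mask()
        vals = g.values[mask]
        mu, sd = float(np.mean(vals)), float(np.std(vals))
        if sd == 0:
            raise ValueError(f"covariate {name!r} is constant; cannot scale")
        z = np.where(mask, (g.values - mu) / sd, g.nodata)
        out[name] = g.with_values(z)
        means[name], sds[name] = mu, sd
    return CovariateStack(out, means, sds)


def apply_scaling(values: np.ndarray, names, means: dict, sds: dict) -> np.ndarray:
    """Apply stored training mean/SD to a raw design matrix (columns = names)."""
    values = np.asarray(values, float).copy()
    for k, nm in enumerate(names):
        values[:, k] = (values[:, k] - means[nm]) / sds[nm]
    return values


def correlation_screen(stack: CovariateStack, threshold: float = 0.7):
    """All pairwise Pearson correlations over shared valid cells.

    Returns ``(corr DataFrame, flagged pairs)`` where flagged pairs have
    |r| > threshold and are candidates for removal before modeling.
    """
    import pandas as pd

    names = stack.names
    if len(names) < 2:
        raise ValueError("correlation screen needs at least two covariates")
    X = stack.design_matrix()
    r = np.corrcoef(X, rowvar=False)
    corr = pd.DataFrame(r, index=names, columns=names)
    flagged = [
        (names[a], names[b], float(r[a, b]))
        for a in range(len(names))
        for b in range(a + 1, len(names))
        if abs(r[a, b]) > threshold
    ]
    return corr, flagged
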