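"""Shared spatial data model and file I/O.

All raster quantities (land cover, covariates, suitability, resistance,
current density) live in :class:`Grid`; point data (sightings, telemetry,
dispersers, availability draws) in :class:`PointSet`; roads and streams in
:class:`LineSet`.

Conventions
-----------
Coordinates are projected meters.  ``Grid.origin`` is the lower-left corner
of the lower-left cell and row index increases with y (Cartesian y-up); the
ESRI ASCII dialect stores the northernmost row first, so arrays are flipped
on read/write.  Cells are half-open: cell (i, j) covers
``[x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "PointSet",
    "LineSet",
    "GridFormatError",
    "GeometryError",
    "POINT_ROLES",
    "LINE_CLASSES",
    "read_grid",
    "write_grid",
    "read_points",
    "write_points",
    "read_lines",
    "write_lines",
]

POINT_ROLES = frozenset(
    {"presence", "pseudo_absence", "telemetry", "disperser", "available"}
)
LINE_CLASSES = frozenset({"high_traffic", "other_road", "stream"})

DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Raised on a malformed raster file."""


class GeometryError(ValueError):
    """Raised when grids with incompatible geometry are combined."""


@dataclass(frozen=True)
class Grid:
    """Regular single-band raster on a square-cell lattice.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row index increasing with y.
    cell_size : float
        Cell edge length in meters.
    origin : tuple of float
        ``(x0, y0)`` of the lower-left corner.
    nodata : float
        Sentinel marking invalid cells; excluded from all statistics.
    crs_tag : str
        Opaque CRS label carried through I/O (no reprojection is done).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA
    crs_tag: str = ""

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise GeometryError(f"grid values must be 2-D, got shape {v.shape}")
        if not self.cell_size > 0:
            raise GeometryError(f"cell_size must be > 0, got {self.cell_size}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))
        self.values.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in map units."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def valid_mask(self) -> np.ndarray:
        v = self.values
        if np.issubdtype(v.dtype, np.floating):
            return ~(np.isclose(v, self.nodata) | np.isnan(v))
        return v != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    def same_geometry(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
        )

    def require_same_geometry(self, other: "Grid") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"grid geometry mismatch: {self.shape}/{self.cell_size}/{self.origin}"
                f" vs {other.shape}/{other.cell_size}/{other.origin}"
            )

    def with_values(self, values: np.ndarray) -> "Grid":
        """Same geometry, new values."""
        if np.asarray(values).shape != self.shape:
            raise GeometryError("with_values: shape changed")
        return replace(self, values=np.asarray(values))

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the half-open cell containing (x, y)."""
        x0, y0 = self.origin
        j = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        i = np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        return i, j

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid-free center coordinate vectors (xs, ys)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def sample(self, x, y):
        """Values at point locations; points outside raise GeometryError."""
        inside = self.contains(x, y)
        if not np.all(inside):
            raise GeometryError(f"{int((~inside).sum())} point(s) outside grid extent")
        i, j = self.cell_of(x, y)
        return self.values[i, j]


POINT_COLUMNS = ["id", "x", "y", "role", "individual_id", "timestamp", "sex", "study_area"]


@dataclass
class PointSet:
    """Point records (sightings, telemetry fixes, availability draws...).

    Backed by a DataFrame with columns ``id, x, y, role`` and optional
    ``individual_id, timestamp, sex, study_area``.  Ids must be unique,
    coordinates finite and roles drawn from :data:`POINT_ROLES`.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        for col in ("id", "x", "y", "role"):
            if col not in df.columns:
                raise ValueError(f"PointSet missing required column {col!r}")
        for col in POINT_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df["x"] = pd.to_numeric(df["x"])
        df["y"] = pd.to_numeric(df["y"])
        if not np.all(np.isfinite(df["x"])) or not np.all(np.isfinite(df["y"])):
            bad = df.loc[~(np.isfinite(df["x"]) & np.isfinite(df["y"])), "id"].tolist()
            raise ValueError(f"non-finite coordinates for ids {bad}")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate point ids {dupes[:5]}")
        bad_roles = set(df["role"]) - POINT_ROLES
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}; allowed {sorted(POINT_ROLES)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(float)

    def subset(self, mask) -> "PointSet":
        return PointSet(self.df.loc[mask].reset_index(drop=True))

    def by_role(self, role: str) -> "PointSet":
        return self.subset(self.df["role"] == role)

    def individuals(self) -> list:
        ids = self.df["individual_id"].dropna().unique().tolist()
        return sorted(ids, key=str)

    @staticmethod
    def from_arrays(x, y, role, ids=None, **extra) -> "PointSet":
        x = np.asarray(x, float)
        if ids is None:
            ids = [f"p{k}" for k in range(len(x))]
        data = {"id": ids, "x": x, "y": np.asarray(y, float), "role": role}
        data.update(extra)
        return PointSet(pd.DataFrame(data))

    @staticmethod
    def concat(parts: list["PointSet"]) -> "PointSet":
        return PointSet(pd.concat([p.df for p in parts], ignore_index=True))


@dataclass
class LineSet:
    """Polyline features (roads, streams) in map units."""

    features: list[dict] = field(default_factory=list)
    # each feature: {"class": str, "coords": ndarray (k, 2)} with k >= 2

    def __post_init__(self):
        feats = []
        for f in self.features:
            cls = f["class"]
            if cls not in LINE_CLASSES:
                raise ValueError(f"unknown line class {cls!r}; allowed {sorted(LINE_CLASSES)}")
            coords = np.asarray(f["coords"], float)
            if coords.ndim != 2 or coords.shape[0] < 2 or coords.shape[1] != 2:
                raise ValueError("each line needs >= 2 (x, y) vertices")
            feats.append({"class": cls, "coords": coords})
        self.features = feats

    def __len__(self) -> int:
        return len(self.features)

    def of_class(self, *classes: str) -> "LineSet":
        return LineSet([f for f in self.features if f["class"] in classes])

    def total_length(self) -> float:
        return float(
            sum(np.hypot(*np.diff(f["coords"], axis=0).T).sum() for f in self.features)
        )


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_grid(path, format: str = "esri_ascii") -> Grid:
    """Read a raster; only the ESRI ASCII dialect is supported."""
    if format != "esri_ascii":
        raise GridFormatError(f"unsupported raster format {format!r}")
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"malformed header line: {line!r}") from exc
            n_header += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path}: missing header keys {missing}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    body = " ".join(lines[n_header:])
    try:
        flat = np.array(body.split(), dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"{path}: non-numeric raster body ({exc})") from exc
    if flat.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} values, found {flat.size}"
        )
    values = flat.reshape(nrows, ncols)[::-1]  # file stores north row first
    return Grid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=nodata,
    )


def write_grid(grid: Grid, path, format: str = "esri_ascii") -> None:
    if format != "esri_ascii":
        raise GridFormatError(f"unsupported raster format {format!r}")
    v = grid.values[::-1]  # north row first on disk
    is_int = np.issubdtype(v.dtype, np.integer)
    nodata = int(grid.nodata) if is_int else grid.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        if is_int:
            np.savetxt(fh, v, fmt="%d")
        else:
            np.savetxt(fh, v, fmt="%.10g")


# ---------------------------------------------------------------------------
# Point I/O (CSV / GeoJSON)


class MissingCoordinateError(ValueError):
    def __init__(self, bad_ids, n_total):
        self.bad_ids = list(bad_ids)
        self.n_total = n_total
        super().__init__(
            f"{len(self.bad_ids)} of {n_total} rows lack coordinates; "
            f"first offenders: {self.bad_ids[:10]}"
        )


def read_points(path, drop_missing: bool = False) -> PointSet:
    """Read points from CSV (columns id,x,y,role,...) or GeoJSON.

    Rows with missing/blank coordinates raise :class:`MissingCoordinateError`
    listing the offending ids, unless ``drop_missing`` is set, in which case
    they are removed (the removal count is available on ``.attrs``).
    """
    path = str(path)
    if path.endswith((".json", ".geojson")):
        with open(path) as fh:
            gj = json.load(fh)
        rows = []
        for feat in gj["features"]:
            props = dict(feat.get("properties") or {})
            geom = feat.get("geometry")
            if geom and geom.get("type") == "Point":
                props["x"], props["y"] = geom["coordinates"][:2]
            rows.append(props)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = ~(np.isfinite(df["x"]) & np.isfinite(df["y"]))
    n_dropped = int(bad.sum())
    if n_dropped:
        if not drop_missing:
            raise MissingCoordinateError(df.loc[bad, "id"].tolist(), len(df))
        df = df.loc[~bad]
    ps = PointSet(df.reset_index(drop=True))
    ps.df.attrs["n_dropped_missing"] = n_dropped
    return ps


def write_points(points: PointSet, path) -> None:
    path = str(path)
    cols = [c for c in POINT_COLUMNS if points.df[c].notna().any() or c in ("id", "x", "y", "role")]
    if path.endswith((".json", ".geojson")):
        feats = []
        for _, row in points.df.iterrows():
            props = {c: row[c] for c in cols if c not in ("x", "y") and pd.notna(row[c])}
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                    "properties": props,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        points.df[cols].to_csv(path, index=False)


def read_lines(path) -> LineSet:
    """Read polylines from GeoJSON (LineString features with a 'class' property)."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = []
    for feat in gj["features"]:
        geom = feat["geometry"]
        if geom["type"] != "LineString":
            raise ValueError(f"expected LineString, got {geom['type']}")
        feats.append(
            {"class": feat["properties"]["class"], "coords": np.asarray(geom["coordinates"])}
        )
    return LineSet(feats)


def write_lines(lines: LineSet, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": f["coords"].tolist()},
            "properties": {"class": f["class"]},
        }
        for f in lines.features
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
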