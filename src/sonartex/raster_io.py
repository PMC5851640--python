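"""Raster and polygon I/O plus point-cloud gridding.

Conventions (used by every module downstream):

* Grids are row-major with row 0 the northernmost row; cells are addressed
  ``(row, col)``, 0-based.
* ``IntensityRaster.origin`` is the easting/northing of the *outer* corner of
  cell ``(0, 0)`` — i.e. the north-west corner of the grid.
* Polygons are evaluated against cell centres, and a later-listed polygon
  takes precedence over an earlier one where they overlap.

Rasters are stored as ESRI ASCII grids (single band, 8-bit grey levels,
explicit nodata value) with an optional ``.prj`` sidecar carrying the CRS tag
verbatim; polygons as GeoJSON with ``class`` and ``role`` properties; point
clouds as ``easting,northing,intensity`` CSV.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely import contains_xy
from shapely.geometry import Polygon, shape

DEFAULT_VOCABULARY = ("sand", "gravel", "boulders")
ROLES = ("calibration", "validation", "exclusion")

GriddingMethod = Literal["nearest", "idw", "gaussian"]


class FormatError(ValueError):
    """Raised for unreadable or structurally invalid files."""


class VocabularyError(ValueError):
    """Raised when a polygon carries a class label outside the declared set."""


@dataclass(frozen=True)
class SonarPointCloud:
    """Georeferenced side-scan intensity samples (one point per ping/bin)."""

    easting: np.ndarray
    northing: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.easting, dtype=float)
        n = np.asarray(self.northing, dtype=float)
        v = np.asarray(self.intensity, dtype=float)
        if e.size == 0:
            raise ValueError("point cloud is empty")
        if not (e.shape == n.shape == v.shape):
            raise ValueError("easting, northing, intensity must have equal length")
        if not (np.isfinite(e).all() and np.isfinite(n).all()):
            raise ValueError("non-finite coordinates in point cloud")
        object.__setattr__(self, "easting", e)
        object.__setattr__(self, "northing", n)
        object.__setattr__(self, "intensity", v)

    def __len__(self) -> int:
        return self.easting.size


@dataclass(frozen=True)
class IntensityRaster:
    """Gridded 8-bit echogram with a validity mask.

    ``values`` are grey levels in 0–255 and are meaningful only where
    ``valid_mask`` is true; masked cells hold 0 by convention.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    cell_size: float = 0.25
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        m = np.asarray(self.valid_mask, dtype=bool)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("raster must be a 2-D grid of shape >= 1x1")
        if m.shape != v.shape:
            raise ValueError("valid_mask shape must match values shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if v.size and m.any():
            vv = v[m]
            if vv.min() < 0 or vv.max() > 255:
                raise ValueError("grey levels must lie in 0-255")
        out = np.where(m, v, 0).astype(np.uint8)
        object.__setattr__(self, "values", out)
        object.__setattr__(self, "valid_mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Easting/northing of every cell centre, each shaped like the grid."""
        rows, cols = self.shape
        e0, n0 = self.origin
        east = e0 + (np.arange(cols) + 0.5) * self.cell_size
        north = n0 - (np.arange(rows) + 0.5) * self.cell_size
        ee, nn = np.meshgrid(east, north)
        return ee, nn

    def with_mask(self, mask: np.ndarray) -> "IntensityRaster":
        return replace(self, values=self.values, valid_mask=np.asarray(mask, bool))


@dataclass(frozen=True)
class SubstratePolygon:
    geometry: Polygon
    class_label: str | None
    role: str = "calibration"


@dataclass
class SubstratePolygonSet:
    """Visually delineated substrate patches plus exclusion regions."""

    polygons: list[SubstratePolygon]
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        for p in self.polygons:
            if p.role not in ROLES:
                raise VocabularyError(f"unknown polygon role {p.role!r}")
            if p.role != "exclusion" and p.class_label not in self.vocabulary:
                raise VocabularyError(
                    f"unknown class label {p.class_label!r}; "
                    f"vocabulary is {self.vocabulary}"
                )

    def with_role(self, role: str) -> "SubstratePolygonSet":
        return SubstratePolygonSet(
            [p for p in self.polygons if p.role == role], self.vocabulary
        )

    def label_points(
        self,
        easting: np.ndarray,
        northing: np.ndarray,
        roles: Sequence[str] = ("calibration", "validation"),
    ) -> np.ndarray:
        """Class index (into ``vocabulary``) per point; -1 where unlabeled.

        Points are tested against each polygon in list order so the
        last-listed polygon wins where polygons overlap.
        """
        e = np.asarray(easting, float).ravel()
        n = np.asarray(northing, float).ravel()
        out = np.full(e.shape, -1, dtype=int)
        for p in self.polygons:
            if p.role not in roles:
                continue
            inside = contains_xy(p.geometry, e, n)
            out[inside] = self.vocabulary.index(p.class_label)
        return out.reshape(np.asarray(easting).shape)


def grid_point_cloud(
    cloud: SonarPointCloud,
    cell_size: float = 0.25,
    method: GriddingMethod = "nearest",
    search_radius: float | None = None,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
    crs_tag: str = "",
) -> IntensityRaster:
    """Resample an intensity point cloud onto a regular grid.

    Each grid node (cell centre) takes, within ``search_radius``:

    * ``nearest`` — the intensity of the nearest point (KD-tree query; exact
      distance ties broken by lowest point index),
    * ``idw`` — the inverse-distance-squared weighted mean of all neighbours,
    * ``gaussian`` — a Gaussian-kernel weighted mean with bandwidth
      ``search_radius / 2``.

    Nodes with no point within the radius are nodata.  ``search_radius``
    defaults to ``2 * cell_size``.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if search_radius is None:
        search_radius = 2.0 * cell_size
    if search_radius <= 0:
        raise ValueError("search_radius must be positive")

    if origin is None:
        origin = (float(cloud.easting.min()), float(cloud.northing.max()))
    if shape is None:
        nrows = max(1, int(np.ceil((cloud.northing.max() - cloud.northing.min()) / cell_size)))
        ncols = max(1, int(np.ceil((cloud.easting.max() - cloud.easting.min()) / cell_size)))
        shape = (nrows, ncols)

    tmp = IntensityRaster(
        np.zeros(shape, np.uint8), np.zeros(shape, bool), cell_size, origin, crs_tag
    )
    ee, nn = tmp.cell_centers()
    nodes = np.column_stack([ee.ravel(), nn.ravel()])
    pts = np.column_stack([cloud.easting, cloud.northing])
    tree = cKDTree(pts)

    values = np.zeros(nodes.shape[0], float)
    valid = np.zeros(nodes.shape[0], bool)

    if method == "nearest":
        # query a handful of neighbours so exact-distance ties can be broken
        # deterministically by lowest point index
        k = min(8, len(cloud))
        dist, idx = tree.query(nodes, k=k, distance_upper_bound=search_radius)
        dist = np.atleast_2d(dist.T).T
        idx = np.atleast_2d(idx.T).T
        has = np.isfinite(dist[:, 0])
        tied = np.isclose(dist, dist[:, :1], rtol=1e-12, atol=1e-12) & np.isfinite(dist)
        pick = np.where(tied, idx, len(cloud))
        best = pick.min(axis=1)
        valid = has
        values[has] = cloud.intensity[best[has]]
    elif method in ("idw", "gaussian"):
        neighbors = tree.query_ball_point(nodes, search_radius)
        sigma = search_radius / 2.0
        for i, nb in enumerate(neighbors):
            if not nb:
                continue
            nb = np.asarray(nb)
            d = np.hypot(
                cloud.easting[nb] - nodes[i, 0], cloud.northing[nb] - nodes[i, 1]
            )
            if method == "idw":
                if (d == 0).any():
                    w = (d == 0).astype(float)
                else:
                    w = 1.0 / d**2
            else:
                w = np.exp(-0.5 * (d / sigma) ** 2)
            values[i] = np.average(cloud.intensity[nb], weights=w)
            valid[i] = True
    else:
        raise ValueError(f"unknown gridding method {method!r}")

    grid = np.clip(np.rint(values), 0, 255).reshape(shape)
    return IntensityRaster(grid, valid.reshape(shape), cell_size, origin, crs_tag)


# ---------------------------------------------------------------------------
# file formats

_NODATA = -9999


def write_raster(raster: IntensityRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (values as integers, masked cells nodata)."""
    path = Path(path)
    rows, cols = raster.shape
    e0, n0 = raster.origin
    yll = n0 - rows * raster.cell_size
    body = np.where(raster.valid_mask, raster.values.astype(int), _NODATA)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {cols}\nnrows {rows}\n"
            f"xllcorner {float(e0)!r}\nyllcorner {float(yll)!r}\n"
            f"cellsize {float(raster.cell_size)!r}\nNODATA_value {_NODATA}\n"
        )
        for row in body:
            fh.write(" ".join(str(v) for v in row) + "\n")
    prj = path.with_suffix(".prj")
    if raster.crs_tag:
        prj.write_text(raster.crs_tag)
    elif prj.exists():
        prj.unlink()


def read_raster(path: str | Path) -> IntensityRaster:
    """Read an ESRI ASCII grid written by :func:`write_raster` (or a GIS)."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    try:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if not data_lines and key in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                ):
                    header[key] = float(parts[1])
                else:
                    data_lines.append(line)
    except OSError as exc:
        raise FormatError(f"cannot read raster {path}: {exc}") from exc
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing ESRI ASCII header field {req!r}")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", _NODATA)
    try:
        grid = np.loadtxt(data_lines, dtype=float).reshape(rows, cols)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed grid body: {exc}") from exc
    mask = grid != nodata
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + rows * cell)
    prj = path.with_suffix(".prj")
    crs = prj.read_text() if prj.exists() else ""
    return IntensityRaster(np.where(mask, grid, 0), mask, cell, origin, crs)


def read_polygons(
    path: str | Path, vocabulary: Sequence[str] = DEFAULT_VOCABULARY
) -> SubstratePolygonSet:
    """Read substrate polygons from GeoJSON.

    Each feature needs a polygon geometry and a ``class`` property from the
    vocabulary (unless ``role`` is ``exclusion``); ``role`` defaults to
    ``calibration``.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read polygons {path}: {exc}") from exc
    feats = doc.get("features") if isinstance(doc, dict) else None
    if feats is None:
        raise FormatError(f"{path}: not a GeoJSON FeatureCollection")
    polys = []
    for feat in feats:
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        polys.append(
            SubstratePolygon(
                geometry=geom,
                class_label=props.get("class"),
                role=props.get("role", "calibration"),
            )
        )
    return SubstratePolygonSet(polys, tuple(vocabulary))


def write_polygons(polys: SubstratePolygonSet, path: str | Path) -> None:
    feats = []
    for p in polys.polygons:
        feats.append(
            {
                "type": "Feature",
                "geometry": p.geometry.__geo_interface__,
                "properties": {"class": p.class_label, "role": p.role},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )


def read_point_cloud(path: str | Path) -> SonarPointCloud:
    """Read an ``easting,northing,intensity`` CSV (header optional)."""
    e, n, v = [], [], []
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                vals = [float(x) for x in row[:3]]
            except ValueError:
                continue  # header line
            e.append(vals[0])
            n.append(vals[1])
            v.append(vals[2])
    if not e:
        raise FormatError(f"{path}: no data rows")
    return SonarPointCloud(np.array(e), np.array(n), np.array(v))


def write_point_cloud(cloud: SonarPointCloud, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["easting", "northing", "intensity"])
        for e, n, v in zip(cloud.easting, cloud.northing, cloud.intensity):
            w.writerow([repr(float(e)), repr(float(n)), repr(float(v))])


def rasterize_polygons(
    polys: SubstratePolygonSet, raster: IntensityRaster
) -> tuple[np.ndarray, IntensityRaster]:
    """Burn substrate polygons onto the raster lattice by cell-centre test.

    Returns ``(labels, masked_raster)`` where ``labels`` holds the class index
    (into ``polys.vocabulary``) per cell, -1 where no polygon covers the cell
    centre, and ``masked_raster`` has cells under exclusion-role polygons
    removed from ``valid_mask``.  Later-listed polygons take precedence.
    """
    ee, nn = raster.cell_centers()
    labels = polys.label_points(ee, nn)
    mask = raster.valid_mask.copy()
    for p in polys.polygons:
        if p.role == "exclusion":
            mask &= ~contains_xy(p.geometry, ee.ravel(), nn.ravel()).reshape(ee.shape)
    labels[~mask] = -1
    return labels, raster.with_mask(mask)
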