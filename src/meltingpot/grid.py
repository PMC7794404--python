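"""Gridded-landscape containers: rasters, layer stacks and binary maps.

A :class:`Raster` is a rectangular grid of cell values with an origin, a cell
size and a nodata marker.  Row 0 is the northernmost row and values sit at
cell centres.  Grids come in two metrics:

* projected (``projected=True``) — x/y coordinates in km, planar distances;
* geographic — x/y are lon/lat in degrees, great-circle (haversine) distances.

Synthetic worlds use the projected convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0088


class GeometryError(ValueError):
    """Raised when rasters that must share geometry do not."""


@dataclass(frozen=True)
class GridGeometry:
    """Placement of a raster grid: origin is the centre of cell (rows-1, 0),
    i.e. the lower-left cell, following the ESRI ASCII ``xllcenter`` convention."""

    rows: int
    cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    projected: bool = True

    def cell_center(self, row, col):
        """x, y of the centre of cell (row, col); row 0 is the northern edge."""
        x = self.x_origin + np.asarray(col) * self.cell_size
        y = self.y_origin + (self.rows - 1 - np.asarray(row)) * self.cell_size
        return x, y

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell whose footprint contains (x, y)."""
        col = int(np.floor((x - self.x_origin) / self.cell_size + 0.5))
        row = int(self.rows - 1 - np.floor((y - self.y_origin) / self.cell_size + 0.5))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.cell_of(x, y)
        return 0 <= row < self.rows and 0 <= col < self.cols

    def all_centers(self):
        """(rows*cols, 2) array of x, y cell-centre coordinates, row-major."""
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        x, y = self.cell_center(rr.ravel(), cc.ravel())
        return np.column_stack([x, y])


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between (lon, lat) points, vectorised."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def point_distance(x1, y1, x2, y2, projected: bool):
    """Planar (km) distance on projected grids, haversine on lon/lat grids."""
    if projected:
        return np.hypot(np.asarray(x2) - x1, np.asarray(y2) - y1)
    return haversine_km(x1, y1, x2, y2)


@dataclass
class Raster:
    """One gridded layer.  ``values`` is float (rows, cols); nodata cells hold
    ``nodata`` and are excluded from every statistic."""

    geometry: GridGeometry
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.rows, self.geometry.cols):
            raise GeometryError(
                f"values shape {self.values.shape} does not match geometry "
                f"({self.geometry.rows}, {self.geometry.cols})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.values) & (self.values != self.nodata)

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(self.geometry, values, self.nodata)

    def same_geometry(self, other: "Raster") -> bool:
        return self.geometry == other.geometry


class BinaryMap(Raster):
    """Raster whose valid cells are 0 or 1."""

    def __post_init__(self):
        super().__post_init__()
        valid = self.mask
        vals = self.values[valid]
        if not np.all((vals == 0) | (vals == 1)):
            raise ValueError("BinaryMap values must be 0 or 1 outside nodata")

    @property
    def cell_set(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.mask & (self.values == 1))
        return set(zip(rows.tolist(), cols.tolist()))

    def count(self) -> int:
        return int(np.sum(self.mask & (self.values == 1)))


@dataclass
class ConsensusMap:
    """Binary consensus across GCM maps plus the per-cell agreement count."""

    binary: BinaryMap
    agreement: np.ndarray  # int array, number of maps voting 1

    @property
    def geometry(self) -> GridGeometry:
        return self.binary.geometry

    @property
    def values(self) -> np.ndarray:
        return self.binary.values

    def count(self) -> int:
        return self.binary.count()


@dataclass
class EnvStack:
    """Named set of raster layers sharing one geometry."""

    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self):
        geoms = {r.geometry for r in self.layers.values()}
        if len(geoms) > 1:
            raise GeometryError("EnvStack layers must share geometry")

    @property
    def geometry(self) -> GridGeometry:
        if not self.layers:
            raise ValueError("empty EnvStack")
        return next(iter(self.layers.values())).geometry

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"missing layers: {missing}")
        return EnvStack({n: self.layers[n] for n in names})

    def design_matrix(self, rows, cols, names=None) -> np.ndarray:
        """Extract an (n_points, n_layers) matrix of layer values at cells."""
        names = list(names) if names is not None else self.names
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        return np.column_stack([self.layers[n].values[rows, cols] for n in names])

    def valid_mask(self, names=None) -> np.ndarray:
        names = names if names is not None else self.names
        m = np.ones((self.geometry.rows, self.geometry.cols), dtype=bool)
        for n in names:
            m &= self.layers[n].mask
        return m


def require_same_geometry(*rasters):
    geoms = {r.geometry for r in rasters}
    if len(geoms) > 1:
        raise GeometryError("rasters do not share grid geometry")
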