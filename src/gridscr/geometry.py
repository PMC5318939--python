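"""Planar coordinates and the sampling grid of "conceptual traps".

Opportunistic boat-based fishing has no fixed trap stations, so the spatial
capture-recapture model lays a regular lattice of square cells over the study
area and treats each habitat cell as a detector: a capture anywhere inside a
cell is assigned to the cell's center point.  The union of active cells is the
state space ``S`` over which latent activity centers live.

Coordinates are kilometres east/north of a per-study reference point, obtained
from latitude/longitude by a local equirectangular projection.  At atoll scale
(tens of km) the projection distortion is far below the 2-km cell size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.geometry.base import BaseGeometry

__all__ = [
    "KM_PER_DEG",
    "PlanarPoint",
    "StudyGrid",
    "OffGridError",
    "project_coords",
    "unproject_coords",
    "build_grid",
    "assign_to_cell",
]

#: Kilometres per degree of latitude (spherical earth, mean radius).
KM_PER_DEG = 111.320


class PlanarPoint(NamedTuple):
    """A point in the local planar frame, km east (x) / north (y) of the reference."""

    x: float
    y: float


class OffGridError(ValueError):
    """A location falls outside every active grid cell."""


def _check_finite(*vals: float) -> None:
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite coordinate: {v!r}")


def project_coords(lat, lon, ref_lat: float, ref_lon: float):
    """Project latitude/longitude (degrees) to local planar km.

    Equirectangular projection centred on ``(ref_lat, ref_lon)``::

        x = (lon - ref_lon) * 111.320 * cos(ref_lat)
        y = (lat - ref_lat) * 111.320

    The reference point maps to the origin and an exact inverse exists
    (:func:`unproject_coords`).  Scalar inputs return a :class:`PlanarPoint`;
    array inputs return ``(x, y)`` arrays.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    _check_finite(lat, lon, ref_lat, ref_lon)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")
    x = (lon - ref_lon) * KM_PER_DEG * math.cos(math.radians(ref_lat))
    y = (lat - ref_lat) * KM_PER_DEG
    if x.ndim == 0:
        return PlanarPoint(float(x), float(y))
    return x, y


def unproject_coords(x, y, ref_lat: float, ref_lon: float):
    """Inverse of :func:`project_coords`; returns (lat, lon) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(x, y, ref_lat, ref_lon)
    lat = ref_lat + y / KM_PER_DEG
    lon = ref_lon + x / (KM_PER_DEG * math.cos(math.radians(ref_lat)))
    if lat.ndim == 0:
        return float(lat), float(lon)
    return lat, lon


@dataclass(frozen=True)
class StudyGrid:
    """Regular lattice of square cells with a habitat mask.

    Cells sit on a lattice with lower-left corner ``origin`` and spacing
    ``cell_size`` (km).  ``active`` flags which lattice cells belong to the
    state space S.  Active cells are indexed 0..J-1 row-major from the
    (xmin, ymin) corner (x varies fastest); exported cell labels are 1-based.
    Cell membership uses half-open intervals ``[x0, x0 + cell_size)`` in both
    axes, so a point on a shared edge belongs to the cell whose lower boundary
    it touches.
    """

    origin: tuple[float, float]
    nx: int
    ny: int
    cell_size: float
    active: np.ndarray  # bool, shape (ny, nx)
    ref_latlon: tuple[float, float] | None = None
    cell_labels: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        act = np.asarray(self.active, dtype=bool)
        if act.shape != (self.ny, self.nx):
            raise ValueError("active mask shape does not match lattice dims")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not act.any():
            raise ValueError("grid has no active cells")
        object.__setattr__(self, "active", act)
        iy, ix = np.nonzero(act)
        order = np.lexsort((ix, iy))  # row-major from ymin
        ix, iy = ix[order], iy[order]
        cx = self.origin[0] + (ix + 0.5) * self.cell_size
        cy = self.origin[1] + (iy + 0.5) * self.cell_size
        centers = np.column_stack([cx, cy])
        lattice_to_active = np.full(self.ny * self.nx, -1, dtype=np.int64)
        lattice_to_active[iy * self.nx + ix] = np.arange(ix.size)
        object.__setattr__(self, "_cell_centers", centers)
        object.__setattr__(self, "_lattice_to_active", lattice_to_active)

    # -- basic properties -------------------------------------------------
    @property
    def n_cells(self) -> int:
        """Number of active cells J."""
        return int(self.active.sum())

    @property
    def cell_centers(self) -> np.ndarray:
        """(J, 2) array of active-cell center coordinates, km."""
        return self._cell_centers

    @property
    def cell_area(self) -> float:
        """Area of one cell, km^2."""
        return self.cell_size**2

    @property
    def total_area(self) -> float:
        """Area of the state space S, km^2."""
        return self.n_cells * self.cell_area

    @property
    def habitat_mask(self) -> frozenset:
        """Set of active lattice indices (iy * nx + ix)."""
        return frozenset(np.nonzero(self.active.ravel())[0].tolist())

    @property
    def bounding_extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the lattice, km."""
        x0, y0 = self.origin
        return (x0, x0 + self.nx * self.cell_size, y0, y0 + self.ny * self.cell_size)

    # -- point operations -------------------------------------------------
    def lattice_index(self, x, y):
        """(ix, iy) lattice coordinates of points; may be out of range."""
        x0, y0 = self.origin
        ix = np.floor((np.asarray(x, float) - x0) / self.cell_size).astype(np.int64)
        iy = np.floor((np.asarray(y, float) - y0) / self.cell_size).astype(np.int64)
        return ix, iy

    def assign(self, x, y):
        """Active-cell index for each point; -1 where off-grid/inactive."""
        ix, iy = self.lattice_index(x, y)
        inside = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        out = np.full(np.shape(ix), -1, dtype=np.int64)
        flat = iy[inside] * self.nx + ix[inside]
        out[inside] = self._lattice_to_active[flat]
        return out

    def contains(self, x, y) -> np.ndarray:
        """True where the point lies in an active cell."""
        return self.assign(x, y) >= 0

    def sample_uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n points uniformly over S (equal-area cells)."""
        j = rng.integers(0, self.n_cells, size=n)
        offs = rng.uniform(-0.5, 0.5, size=(n, 2)) * self.cell_size
        return self.cell_centers[j] + offs

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """All lattice cells as a table: cell_id (1-based, active only), x, y, active."""
        rows = []
        x0, y0 = self.origin
        for iy in range(self.ny):
            for ix in range(self.nx):
                a = self.active[iy, ix]
                j = self._lattice_to_active[iy * self.nx + ix]
                rows.append(
                    {
                        "cell_id": int(j) + 1 if a else 0,
                        "x_center": x0 + (ix + 0.5) * self.cell_size,
                        "y_center": y0 + (iy + 0.5) * self.cell_size,
                        "active": bool(a),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cell_size: float | None = None) -> "StudyGrid":
        """Rebuild a grid from a cell-center table (active rows only needed)."""
        df = pd.read_csv(path)
        if "active" in df.columns:
            df = df[df["active"].astype(bool)]
        if df.empty:
            raise ValueError("grid file contains no active cells")
        centers = df[["x_center", "y_center"]].to_numpy(float)
        if cell_size is None:
            cell_size = _infer_spacing(centers)
        return build_grid(centers=centers, cell_size=cell_size)


def _infer_spacing(centers: np.ndarray) -> float:
    for axis in (0, 1):
        u = np.unique(np.round(centers[:, axis], 9))
        if u.size > 1:
            return float(np.min(np.diff(u)))
    raise ValueError("cannot infer cell size from a single cell; pass cell_size")


def _as_polygon(mask) -> BaseGeometry:
    if isinstance(mask, BaseGeometry):
        return mask
    if isinstance(mask, dict):  # GeoJSON-style
        if mask.get("type") != "Polygon":
            raise ValueError("only Polygon GeoJSON masks are supported")
        coords = mask["coordinates"]
        return Polygon(coords[0], coords[1:])
    raise TypeError("mask must be a shapely geometry or GeoJSON Polygon dict")


def build_grid(
    mask=None,
    cell_size: float = 2.0,
    *,
    centers=None,
    ref_latlon: tuple[float, float] | None = None,
) -> StudyGrid:
    """Build a :class:`StudyGrid` from a habitat mask polygon or cell centers.

    Parameters
    ----------
    mask
        Habitat polygon (shapely geometry or GeoJSON-style Polygon dict).  The
        lattice covers the polygon's extent starting at its (xmin, ymin); a
        cell is active iff its square has positive-area intersection with the
        mask (cells merely touching an edge are inactive).  A zero-area mask
        (point) activates the single cell containing it.
    cell_size
        Cell edge length in km (default 2.0).
    centers
        Alternative to ``mask``: explicit (J, 2) active-cell center
        coordinates lying on a regular lattice.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if centers is not None:
        centers = np.asarray(centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2 or centers.shape[0] == 0:
            raise ValueError("centers must be a non-empty (J, 2) array")
        x0 = float(centers[:, 0].min()) - cell_size / 2
        y0 = float(centers[:, 1].min()) - cell_size / 2
        ix = np.round((centers[:, 0] - x0) / cell_size - 0.5).astype(int)
        iy = np.round((centers[:, 1] - y0) / cell_size - 0.5).astype(int)
        lat_x = x0 + (ix + 0.5) * cell_size
        lat_y = y0 + (iy + 0.5) * cell_size
        if not (
            np.allclose(lat_x, centers[:, 0], atol=1e-6 * cell_size)
            and np.allclose(lat_y, centers[:, 1], atol=1e-6 * cell_size)
        ):
            raise ValueError("cell centers do not lie on a regular lattice")
        nx, ny = int(ix.max()) + 1, int(iy.max()) + 1
        active = np.zeros((ny, nx), dtype=bool)
        active[iy, ix] = True
        return StudyGrid((x0, y0), nx, ny, cell_size, active, ref_latlon)

    if mask is None:
        raise ValueError("provide a mask polygon or explicit cell centers")
    poly = _as_polygon(mask)
    if poly.is_empty:
        raise ValueError("empty mask")
    xmin, ymin, xmax, ymax = poly.bounds
    nx = max(1, math.ceil((xmax - xmin) / cell_size - 1e-9))
    ny = max(1, math.ceil((ymax - ymin) / cell_size - 1e-9))
    active = np.zeros((ny, nx), dtype=bool)
    degenerate = poly.area == 0
    for iy in range(ny):
        for ix in range(nx):
            cell = box(
                xmin + ix * cell_size,
                ymin + iy * cell_size,
                xmin + (ix + 1) * cell_size,
                ymin + (iy + 1) * cell_size,
            )
            if degenerate:
                active[iy, ix] = cell.intersects(poly)
            else:
                active[iy, ix] = cell.intersection(poly).area > 1e-12
    return StudyGrid((xmin, ymin), nx, ny, cell_size, active, ref_latlon)


def assign_to_cell(p: PlanarPoint | tuple, grid: StudyGrid) -> int:
    """Active-cell index containing point ``p``.

    Raises :class:`OffGridError` if the point is outside every active cell;
    callers loading field data drop such records with a warning.
    """
    j = int(grid.assign(p[0], p[1]))
    if j < 0:
        raise OffGridError(f"point ({p[0]:.4f}, {p[1]:.4f}) km is outside the active grid")
    return j
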