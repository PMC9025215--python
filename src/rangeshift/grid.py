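"""Lightweight north-up geographic grid and raster containers.

All rasters in the pipeline live on a shared regular lon/lat grid
(WGS84, EPSG:4326) described by a :class:`GridSpec`. Raster data are plain
2-D ``numpy`` arrays (row 0 = northernmost row); missing cells are NaN.
Persistence uses the ESRI ASCII grid format, which keeps every artifact
plain-text and diffable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = float(np.pi * EARTH_RADIUS_KM / 180.0)  # 111.19 km


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular north-up lon/lat grid.

    Parameters
    ----------
    nrows, ncols
        Grid dimensions. Row 0 is the northernmost row.
    xmin, ymin
        Western and southern *edges* of the grid, decimal degrees.
    cellsize
        Cell width/height in decimal degrees.
    """

    nrows: int
    ncols: int
    xmin: float
    ymin: float
    cellsize: float

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.nrows}x{self.ncols}")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.cellsize

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def lon_centers(self) -> np.ndarray:
        """Longitudes of cell centers, west to east (length ncols)."""
        return self.xmin + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitudes of cell centers, north to south (length nrows, row order)."""
        return self.ymax - (np.arange(self.nrows) + 0.5) * self.cellsize

    def lonlat_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell centers, each of shape (nrows, ncols)."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= self.xmin) & (lon < self.xmax) & (lat > self.ymin) & (lat <= self.ymax)

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col). Out-of-extent points get -1/-1."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)
        col = np.floor((lon - self.xmin) / self.cellsize).astype(int)
        row = np.floor((self.ymax - lat) / self.cellsize).astype(int)
        col = np.clip(col, 0, self.ncols - 1)
        row = np.clip(row, 0, self.nrows - 1)
        col = np.where(inside, col, -1)
        row = np.where(inside, row, -1)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.xmin + (col + 0.5) * self.cellsize
        lat = self.ymax - (row + 0.5) * self.cellsize
        return lon, lat


@dataclasses.dataclass
class Raster:
    """A single layer on a :class:`GridSpec`; NaN marks missing cells."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def sample(self, lon, lat) -> np.ndarray:
        """Nearest-cell values at point coordinates; NaN outside the extent."""
        row, col = self.grid.cell_of(lon, lat)
        out = np.full(np.shape(row), np.nan)
        ok = row >= 0
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        write_ascii_grid(path, self.grid, self.values, nodata=nodata)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        grid, values = read_ascii_grid(path)
        return cls(grid, values)


def write_ascii_grid(
    path: str | Path, grid: GridSpec, values: np.ndarray, nodata: float = -9999.0
) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.xmin!r}\n"
        f"yllcorner {grid.ymin!r}\n"
        f"cellsize {grid.cellsize!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xmin=header["xllcorner"],
        ymin=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    nodata = header["nodata_value"]
    values = np.where(values == nodata, np.nan, values)
    return grid, values


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (R = 6371 km)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Full symmetric distance matrix (km) between points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
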