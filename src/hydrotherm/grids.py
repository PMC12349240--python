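"""Regular lon/lat grids and plain-text raster I/O.

All coordinates in the package are geographic WGS84 decimal degrees.
Grids are cell-center registered, stored row-major from the north-west
corner (row 0 = northernmost band). Rasters are exchanged as single-band
ESRI ASCII grids with nodata = -9999; nodata cells are NaN in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid (cell-center registration)."""

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    resolution_arcmin: float = 2.5

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("bbox must satisfy lon_min < lon_max and lat_min < lat_max")
        if self.resolution_arcmin <= 0:
            raise ValueError("resolution must be positive")
        if self.lon_min < -180 or self.lon_max > 180 or self.lat_min < -90 or self.lat_max > 90:
            raise ValueError("bbox outside geographic bounds")

    @property
    def cellsize(self) -> float:
        """Cell size in decimal degrees."""
        return self.resolution_arcmin / 60.0

    @property
    def ncols(self) -> int:
        return max(1, round((self.lon_max - self.lon_min) / self.cellsize))

    @property
    def nrows(self) -> int:
        return max(1, round((self.lat_max - self.lat_min) / self.cellsize))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row center, row 0 northernmost."""
        return self.lat_min + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def cell_of(self, lon, lat):
        """Containing cell (row, col) of points, floor convention.

        A point exactly on an interior cell edge belongs to the cell with the
        larger coordinate index (floor of the offset/cellsize ratio), i.e. the
        edge is the lower boundary of the north/east cell. Points on the very
        outer east/north bbox edge are clamped into the grid.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cellsize).astype(int)
        irow = np.floor((lat - self.lat_min) / self.cellsize).astype(int)
        col = np.clip(col, None, self.ncols - 1)
        irow = np.clip(irow, None, self.nrows - 1)
        row = self.nrows - 1 - irow
        return row, col

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min) & (lon <= self.lon_max)
            & (lat >= self.lat_min) & (lat <= self.lat_max)
        )


@dataclass
class Raster:
    """A single-band grid; nodata cells are NaN."""

    spec: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.spec.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds a value."""
        return np.isfinite(self.values)

    def sample(self, lon, lat) -> np.ndarray:
        """Value of the cell containing each point (NaN outside the bbox)."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.full(lon.shape, np.nan)
        inside = self.spec.contains(lon, lat)
        row, col = self.spec.cell_of(lon[inside], lat[inside])
        out[inside] = self.values[row, col]
        return out

    def copy(self, values: np.ndarray | None = None, name: str | None = None) -> "Raster":
        return Raster(
            self.spec,
            self.values.copy() if values is None else values,
            self.name if name is None else name,
        )

    def aligned_with(self, other: "Raster") -> bool:
        return self.spec == other.spec


def write_ascii_grid(path: str | Path, raster: Raster) -> None:
    """Write an ESRI ASCII grid (cell-center registered via xllcorner)."""
    spec = raster.spec
    vals = np.where(np.isfinite(raster.values), raster.values, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {spec.lon_min!r}\n")
        fh.write(f"yllcorner {spec.lat_min!r}\n")
        fh.write(f"cellsize {spec.cellsize!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in vals:
            # 17 significant digits: exact binary64 round-trip
            fh.write(" ".join(f"{v:.17g}" for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path, name: str = "") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    nodata = header.get("nodata_value", NODATA)
    # snap derived extents to 10 decimals: cellsize is stored in decimal
    # degrees, so arc-minute resolutions like 2.5' are not exactly binary
    spec = GridSpec(
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        lon_max=round(header["xllcorner"] + ncols * cellsize, 10),
        lat_max=round(header["yllcorner"] + nrows * cellsize, 10),
        resolution_arcmin=round(cellsize * 60.0, 10),
    )
    values = np.array(
        [[float(v) for v in line.split()] for line in lines[6 : 6 + nrows]], dtype=float
    )
    values[values == nodata] = np.nan
    if not name:
        name = Path(path).stem
    return Raster(spec, values, name=name)


def great_circle_km(lon1: float, lat1: float, lon2: float, lat2: float,
                    radius_km: float = 6371.0088) -> float:
    """Haversine great-circle distance in km (IUGG mean Earth radius)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(a)))
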