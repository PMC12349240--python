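"""Habitat dynamics: suitability classes, latitude-corrected areas,
gain/loss change maps and centroid migration.

Cell areas use the exact spherical-zone formula A = R²·Δλ·(sin φ_top −
sin φ_bottom) with the IUGG mean Earth radius, so area totals and centroids
are latitude-corrected. Suitability is cut at breaks 0.2/0.4/0.6 into
non/minimally/moderately/highly suitable classes; everything above 0.2
counts as potential distribution area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Raster, great_circle_km

EARTH_RADIUS_KM = 6371.0088
DEFAULT_BREAKS = (0.2, 0.4, 0.6)
CLASS_LABELS = ("non-suitable", "minimally", "moderately", "highly")
CHANGE_CODES = {"never": 0, "loss": 1, "gain": 2, "stable": 3}
CARDINALS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def cell_area(lat_bottom: float, lat_top: float, lon_width: float) -> float:
    """Spherical-zone area (km²) of a lon/lat cell."""
    if lat_top <= lat_bottom:
        raise ValueError("lat_top must exceed lat_bottom")
    dl = math.radians(lon_width)
    return EARTH_RADIUS_KM**2 * dl * (
        math.sin(math.radians(lat_top)) - math.sin(math.radians(lat_bottom))
    )


def cell_area_grid(raster: Raster) -> np.ndarray:
    """Per-cell area (km²), constant along rows."""
    spec = raster.spec
    cs = spec.cellsize
    lat_c = spec.lat_centers()
    areas = np.array([cell_area(lc - cs / 2, lc + cs / 2, cs) for lc in lat_c])
    return np.repeat(areas[:, None], spec.ncols, axis=1)


@dataclass
class SuitabilityClasses:
    breaks: tuple
    classified: np.ndarray       # int codes 0..3, -1 for nodata
    areas_1e4_km2: dict          # label -> area in 10^4 km²
    raster: Raster

    @property
    def total_potential_1e4_km2(self) -> float:
        return sum(self.areas_1e4_km2[k] for k in CLASS_LABELS[1:])


def classify_suitability(suitability: Raster,
                         breaks: tuple = DEFAULT_BREAKS) -> SuitabilityClasses:
    """Cut a [0,1] suitability grid into four classes (lower-inclusive bins)."""
    if not all(0 < a < b < 1 for a, b in zip(breaks, breaks[1:])) or not (
        0 < breaks[0] < 1
    ):
        raise ValueError("breaks must be strictly increasing within (0,1)")
    v = suitability.values
    finite = np.isfinite(v)
    if finite.any() and ((v[finite] < 0).any() or (v[finite] > 1).any()):
        raise ValueError("suitability values must lie in [0,1]")
    codes = np.full(v.shape, -1, dtype=int)
    codes[finite] = np.digitize(v[finite], breaks, right=False)
    areas = cell_area_grid(suitability)
    per_class = {
        label: float(areas[codes == i].sum()) / 1e4
        for i, label in enumerate(CLASS_LABELS)
    }
    return SuitabilityClasses(breaks=tuple(breaks), classified=codes,
                              areas_1e4_km2=per_class, raster=suitability)


def class_areas(classes: SuitabilityClasses) -> pd.DataFrame:
    """Per-class area table (10⁴ km²) plus the potential-distribution total."""
    rows = [{"class": k, "area_1e4_km2": v}
            for k, v in classes.areas_1e4_km2.items()]
    rows.append({"class": "total_potential",
                 "area_1e4_km2": classes.total_potential_1e4_km2})
    return pd.DataFrame(rows)


def binary_presence(suitability: Raster, threshold: float = 0.2) -> np.ndarray:
    """Presence mask: suitability strictly greater than the threshold."""
    v = suitability.values
    return np.isfinite(v) & (v > threshold)


@dataclass
class ChangeMap:
    codes: np.ndarray            # CHANGE_CODES; -1 outside both masks' data
    areas_1e4_km2: dict


def change_map(current: Raster, future: Raster,
               threshold: float = 0.2) -> ChangeMap:
    """Categorical range change between two suitability grids.

    never = absent in both; loss = present now only; gain = present in the
    future only; stable = present in both.
    """
    if current.spec != future.spec:
        raise ValueError("suitability grids are not aligned")
    c = binary_presence(current, threshold)
    f = binary_presence(future, threshold)
    codes = np.full(c.shape, CHANGE_CODES["never"], dtype=int)
    codes[c & ~f] = CHANGE_CODES["loss"]
    codes[~c & f] = CHANGE_CODES["gain"]
    codes[c & f] = CHANGE_CODES["stable"]
    nodata = ~(current.mask | future.mask)
    codes[nodata] = -1
    areas = cell_area_grid(current)
    per_cat = {
        name: float(areas[codes == code].sum()) / 1e4
        for name, code in CHANGE_CODES.items()
    }
    return ChangeMap(codes=codes, areas_1e4_km2=per_cat)


def centroid(suitability: Raster, threshold: float = 0.2,
             suitability_weighted: bool = False) -> tuple[float, float]:
    """Area-weighted mean center of the presence cells (lon, lat).

    Planar averaging of lon/lat is used; extents spanning the antimeridian
    are rejected. ``suitability_weighted`` additionally weights each cell by
    its suitability score.
    """
    spec = suitability.spec
    if spec.lon_min > spec.lon_max:
        raise ValueError("grids spanning the antimeridian are not supported")
    mask = binary_presence(suitability, threshold)
    if not mask.any():
        raise ValueError("no presence cells above the threshold")
    lon, lat = spec.center_mesh()
    w = cell_area_grid(suitability)[mask]
    if suitability_weighted:
        w = w * suitability.values[mask]
    return (
        float((w * lon[mask]).sum() / w.sum()),
        float((w * lat[mask]).sum() / w.sum()),
    )


@dataclass
class MigrationVector:
    from_lonlat: tuple
    to_lonlat: tuple
    distance_km: float
    bearing_deg: float
    cardinal: str


def migration_vector(from_lonlat: tuple, to_lonlat: tuple) -> MigrationVector:
    """Great-circle displacement with initial bearing (° clockwise from N)."""
    lon1, lat1 = from_lonlat
    lon2, lat2 = to_lonlat
    dist = great_circle_km(lon1, lat1, lon2, lat2)
    if dist == 0.0:
        bearing = 0.0
    else:
        p1, p2 = math.radians(lat1), math.radians(lat2)
        dl = math.radians(lon2 - lon1)
        y = math.sin(dl) * math.cos(p2)
        x = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
        bearing = math.degrees(math.atan2(y, x)) % 360.0
        if bearing >= 360.0:  # -0.0 % 360 rounds up to 360.0
            bearing = 0.0
    cardinal = CARDINALS[int(((bearing + 22.5) % 360.0) // 45.0)]
    return MigrationVector(
        from_lonlat=tuple(from_lonlat), to_lonlat=tuple(to_lonlat),
        distance_km=dist, bearing_deg=bearing, cardinal=cardinal,
    )
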