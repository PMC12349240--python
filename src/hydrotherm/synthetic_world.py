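"""Synthetic study region with known hydrothermal ground truth.

The generator emulates the statistical structure of a mid-latitude
arid-region climate-station network and a virtual-species occurrence set:
monthly temperatures fall with latitude and with elevation at a fixed lapse
rate, annual precipitation rises along longitude, and species occurrences
are drawn from a Gaussian suitability kernel in (WI, HI) niche space with
known optima, so every downstream estimator can be checked against the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indexes
from .grids import GridSpec, Raster
from .indexes import MonthlyClimateRecord

# Baseline monthly cycle (°C) at the reference latitude/elevation: a
# continental mid-latitude profile with a warm summer and sub-zero winter.
DEFAULT_MONTHLY_PROFILE = (
    -8.0, -4.0, 2.0, 10.0, 17.0, 22.0, 25.0, 23.0, 17.0, 9.0, 1.0, -5.0,
)


@dataclass
class WorldConfig:
    """Parameters of the synthetic climate world."""

    lon_min: float = 95.0
    lon_max: float = 115.0
    lat_min: float = 35.0
    lat_max: float = 45.0
    resolution_arcmin: float = 2.5
    n_stations: int = 300
    seed: int = 0
    lapse_per_100m: float = 0.6            # °C cooling per 100 m elevation
    lat_gradient: float = 0.8              # °C cooling per degree northward
    monthly_profile: tuple = DEFAULT_MONTHLY_PROFILE
    precip_base: float = 150.0             # mm at the western edge
    precip_lon_gradient: float = 20.0      # mm per degree eastward
    noise_sd_temp: float = 0.3             # °C, i.i.d. per station-month
    noise_sd_precip: float = 15.0          # mm, i.i.d. per station
    alt_lon_slope: float = -80.0           # m per degree lon (high west, low east)
    alt_lat_slope: float = 40.0            # m per degree lat
    alt_base: float = 1200.0               # m at the south-west corner

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("invalid bbox")
        if self.resolution_arcmin <= 0:
            raise ValueError("resolution must be positive")
        if self.noise_sd_temp < 0 or self.noise_sd_precip < 0:
            raise ValueError("noise SDs must be non-negative")
        if len(self.monthly_profile) != 12:
            raise ValueError("monthly_profile must hold 12 values")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.lon_min, self.lat_min, self.lon_max, self.lat_max,
                        self.resolution_arcmin)

    def elevation(self, lon, lat):
        """Deterministic planar DEM (m); clipped at sea level."""
        alt = (
            self.alt_base
            + self.alt_lon_slope * (np.asarray(lon, float) - self.lon_min)
            + self.alt_lat_slope * (np.asarray(lat, float) - self.lat_min)
        )
        return np.maximum(alt, 0.0)

    def monthly_temperature(self, lon, lat, alt, rng=None):
        """Monthly temperature field; adds Normal noise when an RNG is given."""
        lat = np.asarray(lat, dtype=float)
        base = np.asarray(self.monthly_profile, dtype=float)
        t = (
            base[..., :]
            - self.lat_gradient * (lat[..., None] - self.lat_min)
            - self.lapse_per_100m * np.asarray(alt, float)[..., None] / 100.0
        )
        if rng is not None and self.noise_sd_temp > 0:
            t = t + rng.normal(0.0, self.noise_sd_temp, size=t.shape)
        return t

    def annual_precip(self, lon, rng=None):
        lon = np.asarray(lon, dtype=float)
        p = self.precip_base + self.precip_lon_gradient * (lon - self.lon_min)
        if rng is not None and self.noise_sd_precip > 0:
            p = p + rng.normal(0.0, self.noise_sd_precip, size=p.shape)
        return np.maximum(p, 0.0)  # physical non-negativity


@dataclass
class SpeciesSpec:
    """A virtual species: Gaussian niche in (WI, HI) space."""

    name: str
    wi_optimum: float
    wi_tolerance: float
    hi_optimum: float
    hi_tolerance: float
    n_occurrences: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wi_tolerance <= 0 or self.hi_tolerance <= 0:
            raise ValueError("niche tolerances must be positive")
        if self.n_occurrences < 5:
            raise ValueError("a species needs at least 5 occurrence records")


def generate_station_network(cfg: WorldConfig) -> list[MonthlyClimateRecord]:
    """Random station network inside the bbox; deterministic under cfg.seed."""
    if cfg.n_stations < 1:
        raise ValueError("n_stations must be at least 1")
    rng = np.random.default_rng(cfg.seed)
    lon = rng.uniform(cfg.lon_min, cfg.lon_max, cfg.n_stations)
    lat = rng.uniform(cfg.lat_min, cfg.lat_max, cfg.n_stations)
    alt = cfg.elevation(lon, lat)
    temps = cfg.monthly_temperature(lon, lat, alt, rng=rng)
    precip = cfg.annual_precip(lon, rng=rng)
    return [
        MonthlyClimateRecord(
            station_id=f"S{i:04d}", lon=float(lon[i]), lat=float(lat[i]),
            alt=float(alt[i]), monthly_mean_temp=temps[i],
            annual_precip=float(precip[i]),
        )
        for i in range(cfg.n_stations)
    ]


def stations_to_frame(records) -> pd.DataFrame:
    """Station table with columns station_id, lon, lat, alt, t01..t12, precip_ann."""
    rows = []
    for r in records:
        row = dict(station_id=r.station_id, lon=r.lon, lat=r.lat, alt=r.alt)
        row.update({f"t{m + 1:02d}": r.monthly_mean_temp[m] for m in range(12)})
        row["precip_ann"] = r.annual_precip
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_stations(df: pd.DataFrame) -> list[MonthlyClimateRecord]:
    tcols = [f"t{m:02d}" for m in range(1, 13)]
    return [
        MonthlyClimateRecord(
            station_id=str(row["station_id"]), lon=row["lon"], lat=row["lat"],
            alt=row["alt"], monthly_mean_temp=row[tcols].to_numpy(float),
            annual_precip=row["precip_ann"],
        )
        for _, row in df.iterrows()
    ]


def generate_dem(cfg: WorldConfig) -> Raster:
    lon, lat = cfg.grid.center_mesh()
    return Raster(cfg.grid, cfg.elevation(lon, lat), name="dem")


def generate_true_index_surfaces(cfg: WorldConfig, dem: Raster):
    """Noise-free analytic WI/CI/HI surfaces on the configured grid.

    Applies the same index formulas used for stations, cell-wise on the DEM,
    with all noise suppressed — the ground truth for interpolation tests.
    """
    if dem.spec != cfg.grid:
        raise ValueError("DEM grid does not match the world configuration")
    lon, lat = cfg.grid.center_mesh()
    temps = cfg.monthly_temperature(lon, lat, dem.values)  # (..., 12), no noise
    excess = temps - indexes.GROWTH_THRESHOLD_C
    wi = np.where(excess > 0, excess, 0.0).sum(axis=-1)
    ci = -np.where(excess < 0, -excess, 0.0).sum(axis=-1)
    precip = cfg.annual_precip(lon)
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = np.where(wi > 0, precip / np.where(wi > 0, wi, 1.0), np.nan)
    return (
        Raster(cfg.grid, wi, name="wi"),
        Raster(cfg.grid, ci, name="ci"),
        Raster(cfg.grid, hi, name="hi"),
    )


def generate_occurrences(spec: SpeciesSpec, wi: Raster, hi: Raster) -> pd.DataFrame:
    """Occurrence points drawn ∝ a Gaussian suitability kernel in (WI, HI).

    Cells are drawn with replacement (real records cluster within cells) and
    each point is jittered uniformly inside its cell. Returns a DataFrame with
    columns species, lon, lat.
    """
    if wi.spec != hi.spec:
        raise ValueError("WI and HI surfaces are not aligned")
    valid = wi.mask & hi.mask
    z = (
        -0.5 * ((wi.values - spec.wi_optimum) / spec.wi_tolerance) ** 2
        - 0.5 * ((hi.values - spec.hi_optimum) / spec.hi_tolerance) ** 2
    )
    weights = np.where(valid, np.exp(z), 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no cell has positive sampling weight for this niche")
    rng = np.random.default_rng(spec.seed)
    flat_p = (weights / total).ravel()
    cells = rng.choice(weights.size, size=spec.n_occurrences, p=flat_p)
    row, col = np.unravel_index(cells, weights.shape)
    g = wi.spec
    lon = g.lon_min + (col + rng.uniform(0, 1, spec.n_occurrences)) * g.cellsize
    lat = g.lat_min + (g.nrows - row - rng.uniform(0, 1, spec.n_occurrences)) * g.cellsize
    return pd.DataFrame({"species": spec.name, "lon": lon, "lat": lat})


def generate_scenario_climate(layers: dict[str, Raster], delta_t: float,
                              delta_p_fraction: float,
                              temperature_keys=("wi", "bio9", "bio1"),
                              precipitation_keys=("precip", "bio12", "bio14")) -> dict[str, Raster]:
    """Perturbed layer set: temperatures shifted, precipitation scaled.

    A layer is temperature-like or precipitation-like if its name equals, or
    failing that prefix-matches, one of the given keys; the longest matching
    key wins (so "bio12" matches a "bio12" precipitation key, not a "bio1"
    temperature key). Other layers pass through unchanged. Nodata masks are
    preserved.
    """
    if delta_p_fraction <= -1:
        raise ValueError("delta_p_fraction must be greater than -1")

    def best_match(name, keys):
        hits = [k for k in keys if name == k or name.startswith(k)]
        return max(hits, key=len) if hits else None

    out = {}
    for name, layer in layers.items():
        t_key = best_match(name, temperature_keys)
        p_key = best_match(name, precipitation_keys)
        if p_key is not None and (t_key is None or len(p_key) > len(t_key)):
            out[name] = layer.copy(values=layer.values * (1.0 + delta_p_fraction))
        elif t_key is not None:
            out[name] = layer.copy(values=layer.values + delta_t)
        else:
            out[name] = layer.copy()
    return out
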