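"""Kira's warmth/coldness indexes, Xu's humidity index, and their geographic gradients.

The warmth index WI accumulates monthly warmth above the 5 °C growth
threshold, WI = Σ (t − 5) over months with t > 5 °C (°C·month); the coldness
index CI = −Σ (5 − t) over months with t < 5 °C is non-positive. The humidity
index HI = P / WI relates annual precipitation (mm) to accumulated warmth and
is undefined (NaN, excluded downstream) where WI ≤ 0. For any record
WI + CI = 12·(mean monthly temperature − 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

GROWTH_THRESHOLD_C = 5.0


@dataclass
class MonthlyClimateRecord:
    """One station's monthly-mean temperatures (°C) and annual precipitation (mm)."""

    station_id: str
    lon: float
    lat: float
    alt: float
    monthly_mean_temp: np.ndarray
    annual_precip: float

    def __post_init__(self) -> None:
        self.monthly_mean_temp = np.asarray(self.monthly_mean_temp, dtype=float)
        if self.monthly_mean_temp.shape != (12,):
            raise ValueError("monthly_mean_temp must hold exactly 12 values")
        if not np.all(np.isfinite(self.monthly_mean_temp)):
            raise ValueError("non-finite monthly temperature")
        if self.annual_precip < 0:
            raise ValueError("annual_precip must be non-negative")
        if not -90 <= self.lat <= 90:
            raise ValueError("latitude out of range")


def warmth_index(monthly_mean_temp) -> float:
    """Kira warmth index: Σ(t − 5) over months warmer than 5 °C (°C·month)."""
    t = np.asarray(monthly_mean_temp, dtype=float)
    if t.shape != (12,):
        raise ValueError("expected exactly 12 monthly temperatures")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite monthly temperature")
    excess = t - GROWTH_THRESHOLD_C
    return float(excess[excess > 0].sum())


def coldness_index(monthly_mean_temp) -> float:
    """Kira coldness index: −Σ(5 − t) over months colder than 5 °C (≤ 0)."""
    t = np.asarray(monthly_mean_temp, dtype=float)
    if t.shape != (12,):
        raise ValueError("expected exactly 12 monthly temperatures")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite monthly temperature")
    deficit = GROWTH_THRESHOLD_C - t
    return float(-deficit[deficit > 0].sum())


def humidity_index(annual_precip: float, wi: float) -> float:
    """Xu humidity index HI = P / WI (mm per °C·month); NaN where WI ≤ 0."""
    if annual_precip < 0:
        raise ValueError("annual precipitation must be non-negative")
    if wi <= 0:
        return float("nan")
    return float(annual_precip) / float(wi)


def station_indexes(records) -> pd.DataFrame:
    """Per-station index table with columns station_id, lon, lat, alt, wi, ci, hi."""
    records = list(records)
    if not records:
        raise ValueError("no climate records supplied")
    ids = [r.station_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate station_id: {dupes}")
    rows = []
    for r in records:
        wi = warmth_index(r.monthly_mean_temp)
        ci = coldness_index(r.monthly_mean_temp)
        rows.append(
            dict(station_id=r.station_id, lon=r.lon, lat=r.lat, alt=r.alt,
                 wi=wi, ci=ci, hi=humidity_index(r.annual_precip, wi))
        )
    return pd.DataFrame(rows)


@dataclass
class GeoRegressionModel:
    """OLS of an index on longitude, latitude and altitude (with intercept)."""

    response: str
    intercept: float
    coef_lon: float
    coef_lat: float
    coef_alt: float
    r_squared: float
    p_values: dict = field(default_factory=dict)

    def predict(self, lon, lat, alt):
        lon = np.asarray(lon, dtype=float)
        return (
            self.intercept
            + self.coef_lon * lon
            + self.coef_lat * np.asarray(lat, dtype=float)
            + self.coef_alt * np.asarray(alt, dtype=float)
        )


def fit_geo_regression(samples: pd.DataFrame, response: str) -> GeoRegressionModel:
    """Fit index ~ LON + LAT + ALT by ordinary least squares.

    ``samples`` needs columns lon, lat, alt and the response column. Rows with
    an undefined response (NaN) are dropped. Classical t-test p-values are
    reported per coefficient.
    """
    df = samples[["lon", "lat", "alt", response]].dropna()
    if len(df) < 5:
        raise ValueError("need at least 5 samples with a defined response")
    X = sm.add_constant(df[["lon", "lat", "alt"]].to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: lon/lat/alt are exactly collinear")
    fit = sm.OLS(df[response].to_numpy(), X).fit()
    names = ["intercept", "lon", "lat", "alt"]
    return GeoRegressionModel(
        response=response,
        intercept=float(fit.params[0]),
        coef_lon=float(fit.params[1]),
        coef_lat=float(fit.params[2]),
        coef_alt=float(fit.params[3]),
        r_squared=float(fit.rsquared),
        p_values={n: float(p) for n, p in zip(names, fit.pvalues)},
    )


def gradient_summary(model: GeoRegressionModel) -> dict:
    """Index change per 1° latitude, per 1° longitude and per 100 m elevation."""
    return {
        "delta_per_deg_lat": model.coef_lat,
        "delta_per_deg_lon": model.coef_lon,
        "delta_per_100m_alt": model.coef_alt * 100.0,
    }
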