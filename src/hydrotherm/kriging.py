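"""Ordinary kriging of station indexes onto a regular lon/lat grid.

Distances are Euclidean in decimal degrees — adequate for the regional,
mid-latitude extents this package targets, and it keeps the kriging system
symmetric with the grid geometry. The variogram is fit to the empirical
(binned) semivariogram by least squares weighted by pair counts; the family
(spherical | exponential | gaussian) is a configuration choice.

The ordinary-kriging predictor is the best linear unbiased predictor whose
weights sum to one; with a zero nugget it interpolates the data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .grids import GridSpec, Raster

VARIOGRAM_MODELS = ("spherical", "exponential", "gaussian")


def variogram_value(model: str, h, nugget: float, sill: float, rng: float):
    """Semivariance γ(h) for the named model; sill is the total sill (nugget + partial)."""
    h = np.asarray(h, dtype=float)
    c = max(sill - nugget, 0.0)
    if model == "spherical":
        hr = np.clip(h / rng, 0.0, 1.0)
        g = nugget + c * (1.5 * hr - 0.5 * hr**3)
    elif model == "exponential":
        g = nugget + c * (1.0 - np.exp(-3.0 * h / rng))
    elif model == "gaussian":
        g = nugget + c * (1.0 - np.exp(-3.0 * (h / rng) ** 2))
    else:
        raise ValueError(f"unknown variogram model {model!r}")
    return np.where(h > 0, g, 0.0)


@dataclass
class KrigingConfig:
    variogram_model: str = "exponential"
    nugget: float | None = None      # None → fit from data
    sill: float | None = None
    range_: float | None = None
    max_neighbors: int | None = None  # None → use all stations

    def __post_init__(self) -> None:
        if self.variogram_model not in VARIOGRAM_MODELS:
            raise ValueError(f"variogram model must be one of {VARIOGRAM_MODELS}")
        if self.nugget is not None and self.nugget < 0:
            raise ValueError("nugget must be non-negative")
        if (
            self.nugget is not None
            and self.sill is not None
            and self.sill < self.nugget
        ):
            raise ValueError("sill must be at least the nugget")


def empirical_variogram(x, y, values, n_bins: int = 12):
    """Binned empirical semivariogram: (bin center, γ̂, pair count)."""
    pts = np.column_stack([x, y])
    d = cdist(pts, pts)
    iu = np.triu_indices(len(values), k=1)
    h = d[iu]
    sq = 0.5 * (np.subtract.outer(values, values)[iu]) ** 2
    hmax = h.max()
    edges = np.linspace(0, hmax * 0.75, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (h > lo) & (h <= hi)
        if sel.sum() == 0:
            continue
        centers.append(h[sel].mean())
        gammas.append(sq[sel].mean())
        counts.append(int(sel.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(x, y, values, cfg: KrigingConfig):
    """Resolve (nugget, sill, range), fitting unset parameters by weighted LS."""
    var = float(np.var(values))
    span = float(
        np.hypot(np.ptp(np.asarray(x, float)), np.ptp(np.asarray(y, float)))
    )
    if var <= 1e-30:  # constant field: any valid variogram gives weights ~ uniform
        return (
            cfg.nugget if cfg.nugget is not None else 0.0,
            cfg.sill if cfg.sill is not None else 1.0,
            cfg.range_ if cfg.range_ is not None else max(span, 1.0),
        )
    if cfg.nugget is not None and cfg.sill is not None and cfg.range_ is not None:
        return cfg.nugget, cfg.sill, cfg.range_

    hc, gc, cnt = empirical_variogram(x, y, values)
    if len(hc) < 3:
        return (cfg.nugget or 0.0, cfg.sill if cfg.sill is not None else var,
                cfg.range_ if cfg.range_ is not None else max(span / 2, 1e-6))

    def residuals(theta):
        nugget = cfg.nugget if cfg.nugget is not None else abs(theta[0])
        sill = cfg.sill if cfg.sill is not None else nugget + abs(theta[1])
        rng = cfg.range_ if cfg.range_ is not None else abs(theta[2])
        g = variogram_value(cfg.variogram_model, hc, nugget, sill, max(rng, 1e-9))
        return np.sqrt(cnt) * (g - gc)

    theta0 = np.array([0.1 * var if cfg.nugget is None else 0.0,
                       var, max(span / 3, 1e-6)])
    sol = least_squares(residuals, theta0, method="lm", max_nfev=2000)
    nugget = cfg.nugget if cfg.nugget is not None else abs(sol.x[0])
    sill = cfg.sill if cfg.sill is not None else nugget + abs(sol.x[1])
    rng = cfg.range_ if cfg.range_ is not None else max(abs(sol.x[2]), 1e-9)
    return float(nugget), float(sill), float(rng)


def _ok_weights(sx, sy, values, tx, ty, model, nugget, sill, rng):
    """Solve the OK system for each target; returns (predictions, weights)."""
    pts = np.column_stack([sx, sy])
    n = len(values)
    d = cdist(pts, pts)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = variogram_value(model, d, nugget, sill, rng)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    targets = np.column_stack([np.atleast_1d(tx), np.atleast_1d(ty)])
    d0 = cdist(pts, targets)
    B = np.empty((n + 1, targets.shape[0]))
    B[:n] = variogram_value(model, d0, nugget, sill, rng)
    B[n] = 1.0
    try:
        W = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular ordinary-kriging system for {n} stations "
            f"(coincident stations or degenerate variogram): {exc}"
        ) from exc
    weights = W[:n]
    preds = weights.T @ np.asarray(values, dtype=float)
    return preds, weights


def krige_points(station_table, tx, ty, cfg: KrigingConfig | None = None,
                 return_weights: bool = False):
    """Ordinary-kriging predictions of column ``value`` at arbitrary points.

    ``station_table`` is a DataFrame with columns lon, lat, value.
    """
    cfg = cfg or KrigingConfig()
    sx = station_table["lon"].to_numpy(float)
    sy = station_table["lat"].to_numpy(float)
    v = station_table["value"].to_numpy(float)
    if len(v) < 3:
        raise ValueError("ordinary kriging needs at least 3 stations")
    nugget, sill, rng = fit_variogram(sx, sy, v, cfg)
    preds, weights = _ok_weights(
        sx, sy, v, tx, ty, cfg.variogram_model, nugget, sill, rng
    )
    if return_weights:
        return preds, weights
    return preds


def krige_index_surface(station_table, spec: GridSpec,
                        cfg: KrigingConfig | None = None,
                        variable: str = "value",
                        mask: np.ndarray | None = None) -> Raster:
    """Interpolate a station index onto the grid's cell centers.

    ``station_table`` needs columns lon, lat and ``variable``; stations with an
    undefined value (NaN) are dropped. ``mask`` (True = predict) carves nodata.
    """
    tab = station_table.dropna(subset=[variable]).rename(columns={variable: "value"})
    lon, lat = spec.center_mesh()
    if mask is None:
        mask = np.ones(spec.shape, dtype=bool)
    preds = krige_points(tab, lon[mask].ravel(), lat[mask].ravel(), cfg)
    vals = np.full(spec.shape, np.nan)
    vals[mask] = preds
    return Raster(spec, vals, name=variable)


def crossvalidate_kriging(station_table, cfg: KrigingConfig | None = None,
                          variable: str = "value") -> float:
    """Leave-one-out RMSE of kriging predictions at the stations."""
    tab = station_table.dropna(subset=[variable]).reset_index(drop=True)
    if len(tab) < 4:
        raise ValueError("leave-one-out cross-validation needs at least 4 stations")
    errs = []
    for i in range(len(tab)):
        train = tab.drop(index=i).rename(columns={variable: "value"})
        pred = krige_points(train, tab.loc[i, "lon"], tab.loc[i, "lat"], cfg)
        errs.append(float(pred[0]) - float(tab.loc[i, variable]))
    return float(np.sqrt(np.mean(np.square(errs))))
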