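"""Harvest-period model: when does rice come off the field?

The harvest day of paddy rice in hilly terrain shifts with latitude and
altitude. This module screens the two predictors by partial correlation,
fits the ordinary-least-squares plane

    y = b_lat * latitude + b_alt * altitude + b0

where y is a continuous day index anchored so y = 1 means "around 1 August",
and turns the fit into a calendar harvest window y ± k * SEE (k = 3 by
default, SEE the regression standard error of the estimate). The window
brackets the pre/post-harvest image dates used for NDVI differencing. The
fitted plane can also be rasterized over a DEM to map the harvest period.

Organised statsmodels-style: :class:`HarvestModel` holds the data,
``fit()`` returns a :class:`HarvestFit` carrying estimates, uncertainties
and a ``summary()`` table.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.linear_model import OLS

from .raster import Grid, crs_is_geographic, require_aligned

#: Calendar anchor: day index 1 corresponds to 1 August.
ANCHOR_DATE = _dt.date(2019, 7, 31)  # y = 0


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-point-five upward."""
    return int(math.floor(x + 0.5))


def day_index_to_date(y: float, anchor: _dt.date = ANCHOR_DATE) -> _dt.date:
    """Map a continuous day index to a calendar date (y = 1 -> 1 August).

    Values <= 0 roll back into July, values > 31 roll into September;
    rounding to whole days is half-up and happens only here.
    """
    return anchor + _dt.timedelta(days=round_half_up(y))


def partial_correlation(x, y, z) -> tuple[float, float]:
    """Correlation of x and y with the linear effect of z removed.

    Returns ``(r, p)`` where r = (r_xy − r_xz r_yz)/sqrt((1−r_xz²)(1−r_yz²))
    and the two-sided p-value comes from t = r sqrt((n−3)/(1−r²)) on n−3
    degrees of freedom. Equivalent to correlating the OLS residuals of x on z
    with those of y on z.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    n = x.size
    if not (x.size == y.size == z.size):
        raise ValueError("series must have equal length")
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.ptp(v) == 0:
            raise ValueError(f"series {name} is constant")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if min(1 - r_xz**2, 1 - r_yz**2) <= 1e-12:
        raise ValueError("control variable is collinear with x or y (|r| = 1)")
    r = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if 1 - r**2 <= 1e-15:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


@dataclass(frozen=True)
class HarvestWindow:
    """Calendar window y ± k·SEE around the predicted harvest day index."""

    y_center: float
    y_low: float
    y_high: float
    date_low: _dt.date
    date_high: _dt.date
    k_sigma: float

    @property
    def margin(self) -> float:
        return (self.y_high - self.y_low) / 2.0


class HarvestModel:
    """OLS model of harvest day index on latitude (degrees) and altitude (m)."""

    def __init__(self, harvest_day, latitude, altitude):
        self.harvest_day = np.asarray(harvest_day, dtype=float)
        self.latitude = np.asarray(latitude, dtype=float)
        self.altitude = np.asarray(altitude, dtype=float)
        n = self.harvest_day.size
        if not (self.latitude.size == self.altitude.size == n):
            raise ValueError("latitude, altitude and harvest_day must have equal length")
        if n < 4:
            raise ValueError(f"need at least 4 samples to fit 2 predictors, got {n}")
        if not np.all(np.isfinite(self.harvest_day) & np.isfinite(self.latitude)
                      & np.isfinite(self.altitude)):
            raise ValueError("samples contain non-finite values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, day_col: str = "harvest_day",
                       lat_col: str = "latitude", alt_col: str = "altitude") -> "HarvestModel":
        return cls(df[day_col].to_numpy(), df[lat_col].to_numpy(), df[alt_col].to_numpy())

    @classmethod
    def from_csv(cls, path, **cols) -> "HarvestModel":
        return cls.from_dataframe(pd.read_csv(path), **cols)

    def fit(self) -> "HarvestFit":
        X = np.column_stack([np.ones_like(self.latitude), self.latitude, self.altitude])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "rank-deficient design: latitude/altitude constant or collinear"
            )
        res = OLS(self.harvest_day, X).fit()
        return HarvestFit(self, res)


class HarvestFit:
    """Fitted harvest-period plane with its uncertainty.

    ``see`` is the standard error of the estimate sqrt(SSE/(n − p − 1)) with
    p = 2 predictors — the residual scale that sets the ±k·SEE window width.
    """

    def __init__(self, model, res=None, *, coef_lat=None, coef_alt=None,
                 intercept=None, see=None, r2=None, n=None, pvalues=None):
        self.model = model
        self._res = res
        if res is not None:
            self.intercept, self.coef_lat, self.coef_alt = (float(b) for b in res.params)
            self.see = float(np.sqrt(res.mse_resid))
            self.r2 = float(res.rsquared)
            self.n = int(res.nobs)
            self.pvalues = {
                "intercept": float(res.pvalues[0]),
                "latitude": float(res.pvalues[1]),
                "altitude": float(res.pvalues[2]),
            }
        else:
            self.coef_lat, self.coef_alt = float(coef_lat), float(coef_alt)
            self.intercept, self.see = float(intercept), float(see)
            self.r2 = None if r2 is None else float(r2)
            self.n = None if n is None else int(n)
            self.pvalues = pvalues or {}

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_params(cls, coef_lat: float, coef_alt: float, intercept: float,
                    see: float, r2: float | None = None, n: int | None = None) -> "HarvestFit":
        """Build a fit object from published coefficients (no refitting)."""
        return cls(None, None, coef_lat=coef_lat, coef_alt=coef_alt,
                   intercept=intercept, see=see, r2=r2, n=n)

    # -- inference -----------------------------------------------------------
    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        if self._res is None:
            raise ValueError("confidence intervals need a fitted model, not bare parameters")
        ci = self._res.conf_int(alpha)
        return {
            "intercept": (float(ci[0][0]), float(ci[0][1])),
            "latitude": (float(ci[1][0]), float(ci[1][1])),
            "altitude": (float(ci[2][0]), float(ci[2][1])),
        }

    def predict(self, latitude, altitude):
        """Center day index at the given location(s)."""
        return (self.coef_lat * np.asarray(latitude, dtype=float)
                + self.coef_alt * np.asarray(altitude, dtype=float) + self.intercept)

    def predict_window(self, latitude: float, altitude: float,
                       k_sigma: float = 3.0) -> HarvestWindow:
        """Harvest window: center ± k·SEE, mapped to calendar dates."""
        if not k_sigma >= 0:
            raise ValueError("k_sigma must be >= 0")
        y = float(self.predict(latitude, altitude))
        margin = k_sigma * self.see
        y_low, y_high = y - margin, y + margin
        return HarvestWindow(
            y_center=y, y_low=y_low, y_high=y_high,
            date_low=day_index_to_date(y_low), date_high=day_index_to_date(y_high),
            k_sigma=k_sigma,
        )

    def map_harvest_period(self, dem: Grid, latitude_grid: Grid | None = None) -> Grid:
        """Rasterize the predicted center day index over a DEM.

        If no latitude grid is supplied and the DEM is in a geographic CRS,
        per-pixel latitudes come from the DEM's own transform (row centers).
        """
        if latitude_grid is None:
            if not crs_is_geographic(dem.crs):
                raise ValueError(
                    "latitude grid required: DEM CRS is projected, latitude is "
                    "not derivable from its transform"
                )
            nrow, ncol = dem.shape
            _, lat_rows = dem.transform.xy(np.arange(nrow), np.zeros(nrow))
            lat = np.repeat(lat_rows[:, None], ncol, axis=1)
        else:
            require_aligned(dem, latitude_grid)
            lat = latitude_grid.values.astype(float)
        y = self.predict(lat, dem.values.astype(float))
        y = np.where(dem.valid_mask(), y, np.nan)
        if latitude_grid is not None:
            y = np.where(latitude_grid.valid_mask(), y, np.nan)
        return dem.like(y, nodata=float("nan"))

    # -- reporting -----------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coef_lat": self.coef_lat,
            "coef_alt": self.coef_alt,
            "intercept": self.intercept,
            "see": self.see,
            "r2": self.r2,
            "n": self.n,
            "pvalues": self.pvalues,
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path) -> "HarvestFit":
        d = json.loads(Path(path).read_text())
        fit = cls.from_params(d["coef_lat"], d["coef_alt"], d["intercept"],
                              d["see"], d.get("r2"), d.get("n"))
        fit.pvalues = d.get("pvalues", {})
        return fit

    def summary(self) -> str:
        lines = [
            "Harvest-period regression (day index ~ latitude + altitude)",
            f"  n = {self.n}, R^2 = {self.r2 if self.r2 is None else f'{self.r2:.4f}'}, "
            f"SEE = {self.see:.4f} days",
            f"  latitude  {self.coef_lat:+10.4f} d/deg   p = {self.pvalues.get('latitude', float('nan')):.3g}",
            f"  altitude  {self.coef_alt:+10.4f} d/m     p = {self.pvalues.get('altitude', float('nan')):.3g}",
            f"  intercept {self.intercept:+10.4f} d       p = {self.pvalues.get('intercept', float('nan')):.3g}",
        ]
        return "\n".join(lines)


def fit_harvest_model(samples: pd.DataFrame) -> HarvestFit:
    """Convenience wrapper: fit the plane from a samples DataFrame."""
    return HarvestModel.from_dataframe(samples).fit()
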