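"""Life-history and environmental predictors from seasonal range geometries.

Works from breeding/nonbreeding range polygons (shapely geometries in
geographic coordinates) and gridded environmental layers.  Six alternative
migration-distance measures are computed from range latitudes and centroids; a
representative measure is selected as the one that best predicts the others.
Day length comes from a closed-form solar-declination model (the CBM model of
Forsythe and co-workers) so the pipeline runs without any raster download;
any gridded day-length or radiation product can be substituted via
:class:`GridRaster`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy as _contains_xy
from shapely.ops import unary_union

__all__ = [
    "SeasonalRange",
    "GridRaster",
    "migration_distance_measures",
    "select_representative_measure",
    "day_length_analytic",
    "mean_day_length",
    "sample_raster_mean",
    "sample_polygon_points",
    "solar_exposure",
    "KM_PER_DEG_LAT",
    "EARTH_RADIUS_KM",
    "BREEDING_MONTHS",
    "NONBREEDING_MONTHS",
]

KM_PER_DEG_LAT = 111.32
EARTH_RADIUS_KM = 6371.0

# Extraction windows applied to every species regardless of migrant class.
BREEDING_MONTHS = (5, 6, 7)
NONBREEDING_MONTHS = (11, 12, 1, 2)


@dataclass
class SeasonalRange:
    """Breeding and nonbreeding distribution polygons for one species."""

    breeding: object      # shapely (Multi)Polygon, lon/lat degrees
    nonbreeding: object

    def __post_init__(self):
        for name in ("breeding", "nonbreeding"):
            geom = getattr(self, name)
            if geom.is_empty:
                raise ValueError(f"{name} polygon is empty")
            if not geom.is_valid:
                setattr(self, name, geom.buffer(0))  # standard self-intersection repair
            lo, la, hi, lb = geom.bounds
            if la < -90 - 1e-9 or lb > 90 + 1e-9:
                raise ValueError(f"{name} latitude outside [-90, 90]")

    @property
    def migrant_class(self) -> str:
        """migrant = no breeding/nonbreeding overlap, nonmigrant = complete
        overlap, partial = anything between."""
        inter = self.breeding.intersection(self.nonbreeding).area
        union = unary_union([self.breeding, self.nonbreeding]).area
        if inter == 0:
            return "migrant"
        if abs(union - inter) <= 1e-9 * max(union, 1.0):
            return "nonmigrant"
        return "partial"


def _lat_bounds(geom):
    _, lat_min, _, lat_max = geom.bounds
    return lat_min, lat_max


def _haversine_km(lon1, lat1, lon2, lat2) -> float:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def migration_distance_measures(rng: SeasonalRange) -> np.ndarray:
    """The six candidate migration-distance measures, in order.

    1. |midlatitude difference| where midlatitude = (min lat + max lat) / 2
    2. |maximum-latitude difference|
    3. |minimum-latitude difference|
    4. |max breeding latitude - min nonbreeding latitude|
    5. |min breeding latitude - max nonbreeding latitude|
    6. great-circle distance (km) between polygon centroids

    Measures 1-5 are in degrees latitude (multiply by ``KM_PER_DEG_LAT`` for
    km).  Strict nonmigrants are forced to zero on all six; partial migrants
    use the same formulas on their overlapping polygons.
    """
    if rng.migrant_class == "nonmigrant":
        return np.zeros(6)
    b_min, b_max = _lat_bounds(rng.breeding)
    n_min, n_max = _lat_bounds(rng.nonbreeding)
    mid_b, mid_n = (b_min + b_max) / 2, (n_min + n_max) / 2
    cb, cn = rng.breeding.centroid, rng.nonbreeding.centroid
    return np.array([
        abs(mid_b - mid_n),
        abs(b_max - n_max),
        abs(b_min - n_min),
        abs(b_max - n_min),
        abs(b_min - n_max),
        _haversine_km(cb.x, cb.y, cn.x, cn.y),
    ])


def select_representative_measure(measures: np.ndarray) -> dict:
    """Pick the migration-distance measure that best predicts the others.

    For each column, the mean R-squared of simple linear regressions
    predicting every other column is computed; the column with the highest
    mean wins (ties broken toward the lowest index).  Constant columns are
    excluded with a warning entry in the returned table.
    """
    M = np.asarray(measures, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a species x measures matrix with >= 2 columns")
    if M.shape[0] < 3:
        raise ValueError("need at least 3 species")
    ncol = M.shape[1]
    sd = M.std(axis=0)
    usable = sd > 0
    corr = np.corrcoef(M[:, usable], rowvar=False)
    r2 = corr ** 2
    mean_r2 = np.full(ncol, np.nan)
    usable_idx = np.flatnonzero(usable)
    for k, i in enumerate(usable_idx):
        others = [m for m in range(len(usable_idx)) if m != k]
        mean_r2[i] = r2[k, others].mean() if others else np.nan
    best = int(np.nanargmax(mean_r2))
    return {
        "selected": best,
        "mean_r2": mean_r2,
        "excluded_constant": np.flatnonzero(~usable).tolist(),
    }


# ---------------------------------------------------------------------------
# Day length (closed-form fallback for the gridded product)
# ---------------------------------------------------------------------------

def day_length_analytic(latitude, day_of_year) -> np.ndarray:
    """Daylight hours from solar-declination geometry (CBM model).

    ``theta = 0.2163108 + 2 atan(0.9671396 tan(0.00860 (J - 186)))``,
    ``phi = asin(0.39795 cos(theta))`` is the solar declination, and day
    length follows from the sunrise hour angle, clamped to [0, 24] to cover
    polar day and night.
    """
    lat = np.radians(np.asarray(latitude, dtype=float))
    J = np.asarray(day_of_year, dtype=float)
    theta = 0.2163108 + 2 * np.arctan(0.9671396 * np.tan(0.00860 * (J - 186)))
    phi = np.arcsin(0.39795 * np.cos(theta))
    cos_ha = -np.tan(lat) * np.tan(phi)
    cos_ha = np.clip(cos_ha, -1.0, 1.0)
    hours = 24.0 - (24.0 / np.pi) * np.arccos(-cos_ha)
    return np.clip(hours, 0.0, 24.0)


def mean_day_length(latitude: float, months=None) -> float:
    """Mean daily daylight hours over the given calendar months (all year if
    None), at a fixed latitude."""
    month_days = {1: (1, 31), 2: (32, 59), 3: (60, 90), 4: (91, 120),
                  5: (121, 151), 6: (152, 181), 7: (182, 212), 8: (213, 243),
                  9: (244, 273), 10: (274, 304), 11: (305, 334), 12: (335, 365)}
    if months is None:
        days = np.arange(1, 366)
    else:
        days = np.concatenate([np.arange(a, b + 1) for a, b in
                               (month_days[m] for m in months)])
    return float(day_length_analytic(latitude, days).mean())


# ---------------------------------------------------------------------------
# Raster sampling
# ---------------------------------------------------------------------------

@dataclass
class GridRaster:
    """Minimal in-memory regular lon/lat grid.

    ``values[i, j]`` covers the cell with x in ``[x0 + j dx, x0 + (j+1) dx)``
    and y in ``[y0 + i dy, y0 + (i+1) dy)``; ``y0`` is the *bottom* edge and
    rows run south to north.
    """

    values: np.ndarray
    x0: float
    y0: float
    dx: float
    dy: float
    nodata: float = np.nan

    @property
    def bounds(self):
        ny, nx = self.values.shape
        return (self.x0, self.y0, self.x0 + nx * self.dx, self.y0 + ny * self.dy)

    def sample(self, xs, ys) -> np.ndarray:
        xs = np.asarray(xs, float)
        ys = np.asarray(ys, float)
        j = np.floor((xs - self.x0) / self.dx).astype(int)
        i = np.floor((ys - self.y0) / self.dy).astype(int)
        ny, nx = self.values.shape
        out = np.full(xs.shape, np.nan)
        ok = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
        out[ok] = self.values[i[ok], j[ok]]
        if not np.isnan(self.nodata):
            out[out == self.nodata] = np.nan
        return out

    @classmethod
    def from_function(cls, f, bounds, shape) -> "GridRaster":
        """Grid whose cell values are ``f(lon, lat)`` at cell centers."""
        x0, y0, x1, y1 = bounds
        ny, nx = shape
        dx, dy = (x1 - x0) / nx, (y1 - y0) / ny
        xs = x0 + dx * (np.arange(nx) + 0.5)
        ys = y0 + dy * (np.arange(ny) + 0.5)
        X, Y = np.meshgrid(xs, ys)
        return cls(np.asarray(f(X, Y), float), x0, y0, dx, dy)


def sample_polygon_points(polygon, n_points: int, seed: int) -> np.ndarray:
    """Uniform random points inside a polygon by rejection from its bounding
    box; reproducible given (seed, n_points)."""
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = polygon.bounds
    pts = np.empty((0, 2))
    while len(pts) < n_points:
        k = max(int((n_points - len(pts)) * 2.5), 64)
        xs = rng.uniform(x0, x1, k)
        ys = rng.uniform(y0, y1, k)
        keep = _contains_xy(polygon, xs, ys)
        pts = np.vstack([pts, np.column_stack([xs[keep], ys[keep]])])
    return pts[:n_points]


def sample_raster_mean(polygon, raster: GridRaster, n_points: int = 10000,
                       seed: int = 0) -> dict:
    """Mean raster value over uniform random in-polygon points.

    No-data cells are skipped (their count is reported); an error names the
    inputs if no valid sample remains.
    """
    rx0, ry0, rx1, ry1 = raster.bounds
    px0, py0, px1, py1 = polygon.bounds
    if px1 < rx0 or px0 > rx1 or py1 < ry0 or py0 > ry1:
        raise ValueError("polygon does not intersect raster extent")
    pts = sample_polygon_points(polygon, n_points, seed)
    vals = raster.sample(pts[:, 0], pts[:, 1])
    ok = ~np.isnan(vals)
    if ok.sum() == 0:
        raise ValueError(
            f"no valid raster samples for polygon bounds {polygon.bounds}")
    return {
        "mean": float(vals[ok].mean()),
        "n_valid": int(ok.sum()),
        "n_nodata": int((~ok).sum()),
        "seed": seed,
    }


def mean_latitude(polygon, n_points: int = 10000, seed: int = 0) -> float:
    """Mean latitude of uniformly sampled in-range points (the per-season
    latitude variable)."""
    pts = sample_polygon_points(polygon, n_points, seed)
    return float(pts[:, 1].mean())


def solar_exposure(radiation, day_length):
    """Composite exposure variable: radiation x day length (elementwise)."""
    r = np.asarray(radiation, float)
    d = np.asarray(day_length, float)
    if np.any(r < 0) or np.any(d < 0):
        raise ValueError("radiation and day length must be non-negative")
    return r * d


def predictor_table(ranges: dict, n_points: int = 2000, seed: int = 0,
                    rasters: dict | None = None) -> pd.DataFrame:
    """Assemble the core range-derived predictors for a set of species.

    ``ranges`` maps species -> SeasonalRange.  Migration distance uses the
    midlatitude measure (degrees latitude); day length is the analytic model
    averaged over the breeding and nonbreeding windows at each range's mean
    latitude; optional ``rasters`` (name -> (GridRaster, season)) are sampled
    with the same point scheme.
    """
    rows = {}
    for i, (sp, rng) in enumerate(sorted(ranges.items())):
        sp_seed = seed + i
        meas = migration_distance_measures(rng)
        lat_b = mean_latitude(rng.breeding, n_points, sp_seed)
        lat_w = mean_latitude(rng.nonbreeding, n_points, sp_seed + 10_000)
        dl_b = mean_day_length(lat_b, BREEDING_MONTHS)
        dl_w = mean_day_length(lat_w, NONBREEDING_MONTHS)
        row = {
            "migrant_class": rng.migrant_class,
            "migration_distance": meas[0],
            "breeding_latitude": lat_b,
            "winter_latitude": lat_w,
            "day_length": (dl_b + dl_w) / 2,
            "day_length_breeding": dl_b,
            "day_length_winter": dl_w,
        }
        if rasters:
            for name, (raster, season) in rasters.items():
                poly = rng.breeding if season == "breeding" else rng.nonbreeding
                row[name] = sample_raster_mean(poly, raster, n_points, sp_seed)["mean"]
        rows[sp] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("species")
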