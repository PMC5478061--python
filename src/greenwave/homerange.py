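"""Fixed-kernel utilization distributions, isopleths and seasonal ranges.

Home ranges are 95% utilization-distribution (UD) isopleths from a
fixed-kernel density estimate with the reference bandwidth
h = sigma_hat n^(-1/6), sigma_hat = sqrt((var_x + var_y)/2).  Seasonal
contrasts use monthly 95% kernels (March for winter with an April
fallback, July for summer with a June fallback) for elevation means,
and 95% minimum-convex-polygon centroids of the same months for the
summer-winter distance.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Polygon
from skimage import measure

from .raster import Raster

logger = logging.getLogger(__name__)

DEFAULT_GRID_RES = 50.0  # m; finer than the 100 m landscape raster
SEASON_DOY = (91, 243)  # 1 April - 31 August, non-leap calendar


@dataclass
class HomeRange:
    """A kernel UD with (optionally) its isopleth polygons and area."""

    id: str
    window: tuple | None
    h: float
    ud: Raster
    level: float | None = None
    polygons: list[Polygon] = field(default_factory=list)
    area_km2: float | None = None
    threshold: float | None = None


def reference_bandwidth(fixes) -> float:
    """Reference (Gaussian-optimal) smoothing factor in meters.

    h = sigma_hat n^(-1/6) with sigma_hat = sqrt((var_x + var_y)/2),
    variances computed with denominator n - 1.
    """
    xy = _as_xy(fixes)
    n = xy.shape[0]
    if n < 30:
        raise ValueError(f"reference bandwidth needs >= 30 fixes, got {n}")
    var_x = float(np.var(xy[:, 0], ddof=1))
    var_y = float(np.var(xy[:, 1], ddof=1))
    sigma = np.sqrt((var_x + var_y) / 2.0)
    if sigma == 0:
        raise ValueError("all fixes identical: zero variance")
    return sigma * n ** (-1.0 / 6.0)


def _as_xy(fixes) -> np.ndarray:
    if isinstance(fixes, pd.DataFrame):
        return fixes[["x", "y"]].to_numpy(dtype=float)
    return np.asarray(fixes, dtype=float).reshape(-1, 2)


def kernel_ud(fixes, h: float, grid_res: float = DEFAULT_GRID_RES,
              animal_id: str = "", window=None) -> HomeRange:
    """Bivariate-normal kernel density of the fixes on a padded grid.

    The grid extends at least 3h beyond the fix bounding box; the density
    is evaluated by binning the fixes and convolving with a Gaussian of
    sd h (exact to grid resolution), then normalized to integrate to 1.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_res > h:
        logger.warning("UD grid resolution %.0f m exceeds bandwidth %.0f m", grid_res, h)
    xy = _as_xy(fixes)
    pad = 3.0 * h + grid_res
    x_min = xy[:, 0].min() - pad
    y_min = xy[:, 1].min() - pad
    ncol = int(np.ceil((xy[:, 0].max() + pad - x_min) / grid_res))
    nrow = int(np.ceil((xy[:, 1].max() + pad - y_min) / grid_res))

    col = np.floor((xy[:, 0] - x_min) / grid_res).astype(int)
    row = np.floor((xy[:, 1] - y_min) / grid_res).astype(int)
    counts = np.zeros((nrow, ncol))
    np.add.at(counts, (row, col), 1.0)
    dens = gaussian_filter(counts, sigma=h / grid_res, mode="constant")
    total = dens.sum() * grid_res ** 2
    dens /= total
    return HomeRange(id=animal_id, window=window, h=float(h),
                     ud=Raster(dens, x_min, y_min, grid_res))


def isopleth(hr: HomeRange, level: float = 0.95) -> HomeRange:
    """Extract the smallest super-level set holding ``level`` of UD mass.

    Fills the home range's polygons (marching-squares contours at the
    mass threshold, holes subtracted) and its area in km^2 (counted from
    the super-level cells).  Returns the same object for chaining.
    """
    ud = hr.ud.values
    res = hr.ud.res
    cell_mass = ud.ravel() * res ** 2
    order = np.argsort(ud.ravel())[::-1]
    csum = np.cumsum(cell_mass[order])
    k = int(np.searchsorted(csum, level))
    k = min(k, order.size - 1)
    threshold = float(ud.ravel()[order[k]])
    if level >= 1.0:
        mask = ud > 0
        threshold = 0.0
    else:
        mask = ud >= threshold
    area_km2 = float(mask.sum()) * res ** 2 / 1e6

    padded = np.pad(ud, 1, mode="constant")
    contours = measure.find_contours(padded, max(threshold, 1e-300))
    polys = []
    for cont in contours:
        if len(cont) < 4:
            continue
        # contour coords are (row, col) in the padded index frame
        xs = hr.ud.x_min + (cont[:, 1] - 1 + 0.5) * res
        ys = hr.ud.y_min + (cont[:, 0] - 1 + 0.5) * res
        poly = Polygon(np.column_stack([xs, ys]))
        if poly.is_valid and poly.area > 0:
            polys.append(poly)
    # nest holes inside their enclosing rings
    polys.sort(key=lambda p: p.area, reverse=True)
    final: list[Polygon] = []
    for poly in polys:
        placed = False
        for i, outer in enumerate(final):
            if outer.contains(poly):
                final[i] = Polygon(
                    outer.exterior.coords,
                    [r.coords for r in outer.interiors] + [poly.exterior.coords],
                )
                placed = True
                break
        if not placed:
            final.append(poly)
    hr.level = level
    hr.polygons = final
    hr.area_km2 = area_km2
    hr.threshold = threshold
    return hr


def mcp(fixes, retain: float = 0.95) -> tuple[Polygon, tuple[float, float]]:
    """Minimum convex polygon of the ``retain`` fraction of fixes
    closest to the fix centroid, plus its hull-vertex-mean centroid."""
    xy = _as_xy(fixes)
    center = xy.mean(axis=0)
    dist = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
    k = max(int(np.ceil(retain * len(xy))), 3)
    kept = xy[np.argsort(dist)[:k]]
    hull = MultiPoint(kept).convex_hull
    if hull.geom_type != "Polygon":  # collinear degenerate case
        hull = hull.buffer(1e-6)
    verts = np.asarray(hull.exterior.coords)[:-1]
    centroid = (float(verts[:, 0].mean()), float(verts[:, 1].mean()))
    return hull, centroid


@dataclass
class SeasonalRangePair:
    """Winter/summer monthly-range contrast for one animal."""

    id: str
    winter_month: int | None
    summer_month: int | None
    winter_elevation_m: float | None
    summer_elevation_m: float | None
    winter_centroid: tuple[float, float] | None
    summer_centroid: tuple[float, float] | None
    distance_km: float | None
    delta_elevation_m: float | None
    missing: bool = False


def _month_fixes(track, month: int) -> pd.DataFrame:
    ts = track.fixes["timestamp"]
    return track.fixes[ts.dt.month == month]


def _monthly_kernel_elevation(track, months, dem: Raster, grid_res: float):
    """95% kernel elevation mean for the first month with enough fixes."""
    from .covariates import zonal_mean  # deferred to avoid import cycle

    for month in months:
        fixes = _month_fixes(track, month)
        if len(fixes) < 30:
            continue
        try:
            h = reference_bandwidth(fixes)
        except ValueError:
            continue
        hr = isopleth(kernel_ud(fixes, h, grid_res, animal_id=track.id), 0.95)
        elev, count = zonal_mean(dem, hr.polygons)
        if count == 0:
            continue
        _, centroid = mcp(fixes, 0.95)
        return month, float(elev), centroid
    return None, None, None


def summer_window(track, classification) -> tuple[float, float]:
    """Day-of-year window defining the summer home range.

    Residents use the full growing season (1 April - 31 August);
    migrants use arrival at the summer range until departure.
    """
    if classification.tactic == "resident":
        return float(SEASON_DOY[0]), float(SEASON_DOY[1])
    if classification.tactic == "migrant":
        return float(classification.arrival_doy), float(classification.departure_doy)
    raise ValueError(f"unresolved tactic for {classification.id}")


def seasonal_ranges(track, classification, dem: Raster,
                    grid_res: float = DEFAULT_GRID_RES
                    ) -> tuple[HomeRange, SeasonalRangePair]:
    """Summer home range plus the winter/summer seasonal contrast.

    Returns the 95% kernel summer home range (covariate extraction zone)
    and a :class:`SeasonalRangePair` with monthly elevation means, MCP
    centroid distance and delta-elevation.  The pair is flagged missing
    when no eligible winter (March, then April) or summer (July, then
    June) month has enough fixes.
    """
    lo, hi = summer_window(track, classification)
    doy = track.doy
    fixes = track.fixes[(doy >= lo) & (doy <= hi)]
    if len(fixes) < 30:
        raise ValueError(f"track {track.id}: too few fixes in summer window [{lo:.0f}, {hi:.0f}]")
    h = reference_bandwidth(fixes)
    summer_hr = isopleth(kernel_ud(fixes, h, grid_res, animal_id=track.id,
                                   window=(lo, hi)), 0.95)

    w_month, w_elev, w_cent = _monthly_kernel_elevation(track, (3, 4), dem, grid_res)
    s_month, s_elev, s_cent = _monthly_kernel_elevation(track, (7, 6), dem, grid_res)
    if w_month is None or s_month is None:
        pair = SeasonalRangePair(track.id, w_month, s_month, w_elev, s_elev,
                                 w_cent, s_cent, None, None, missing=True)
    else:
        dist_km = float(np.hypot(s_cent[0] - w_cent[0], s_cent[1] - w_cent[1]) / 1000.0)
        pair = SeasonalRangePair(track.id, w_month, s_month, w_elev, s_elev,
                                 w_cent, s_cent, dist_km, s_elev - w_elev)
    return summer_hr, pair


def polygons_to_geojson(polygons, path) -> None:
    """Write a polygon list as a GeoJSON FeatureCollection (plain text)."""
    import json

    from shapely.geometry import mapping

    features = [{"type": "Feature", "properties": {}, "geometry": mapping(p)}
                for p in polygons]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
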