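"""Landscape covariate extraction within summer home ranges.

Zonal statistics use the pixel-center-in-polygon rule.  Terrain slope
and aspect come from central finite differences on the DEM; aspect is
reported clockwise from north (0 = north, 180 = south) and converted to
northness by cosine, averaged per pixel (never cosine of the mean
aspect).  Habitat enters as the proportions of four classes (pasture,
forest, mountain, other) inside the home range.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely

from .raster import Raster

logger = logging.getLogger(__name__)

HABITAT_CODES = {"pasture": 0, "forest": 1, "mountain": 2, "other": 3}
HABITAT_NAMES = {v: k for k, v in HABITAT_CODES.items()}


def _inside_mask(raster: Raster, polygons) -> np.ndarray:
    """Boolean grid of pixels whose centers fall inside any polygon."""
    if not polygons:
        return np.zeros(raster.values.shape, dtype=bool)
    union = shapely.union_all(list(polygons))
    x_lo, y_lo, x_hi, y_hi = union.bounds
    c0 = max(int(np.floor((x_lo - raster.x_min) / raster.res)) - 1, 0)
    c1 = min(int(np.ceil((x_hi - raster.x_min) / raster.res)) + 1, raster.ncol)
    r0 = max(int(np.floor((y_lo - raster.y_min) / raster.res)) - 1, 0)
    r1 = min(int(np.ceil((y_hi - raster.y_min) / raster.res)) + 1, raster.nrow)
    mask = np.zeros(raster.values.shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    xs = raster.x_min + (np.arange(c0, c1) + 0.5) * raster.res
    ys = raster.y_min + (np.arange(r0, r1) + 0.5) * raster.res
    X, Y = np.meshgrid(xs, ys)
    mask[r0:r1, c0:c1] = shapely.contains_xy(union, X.ravel(), Y.ravel()).reshape(X.shape)
    return mask


def zonal_values(raster: Raster, polygons) -> np.ndarray:
    """Raster values at pixel centers inside the polygons (NaNs dropped)."""
    vals = raster.values[_inside_mask(raster, polygons)].astype(float)
    return vals[np.isfinite(vals)]


def zonal_mean(raster: Raster, polygons) -> tuple[float, int]:
    """Mean raster value over pixels inside the polygons, plus pixel count.

    Returns (nan, 0) when no pixel center falls inside (a missing-value
    flag, not an exception).
    """
    vals = zonal_values(raster, polygons)
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def slope_aspect(dem: Raster) -> tuple[Raster, Raster]:
    """Slope (degrees) and aspect (degrees clockwise from north) from a DEM.

    Central finite differences on the 3x3 neighborhood; flat cells get
    NaN aspect so they drop out of northness averages.
    """
    dz_dy, dz_dx = np.gradient(dem.values.astype(float), dem.res)
    grad = np.hypot(dz_dx, dz_dy)
    slope = np.degrees(np.arctan(grad))
    # downslope direction, clockwise angle from north
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    aspect = np.where(grad > 0, aspect, np.nan)
    return (Raster(slope, dem.x_min, dem.y_min, dem.res),
            Raster(aspect, dem.x_min, dem.y_min, dem.res))


def northness(aspect_deg):
    """Cosine of aspect: 1 = north-facing, -1 = south-facing."""
    a = np.asarray(aspect_deg, dtype=float)
    if np.any((a[np.isfinite(a)] < 0) | (a[np.isfinite(a)] > 360)):
        raise ValueError("aspect must lie in [0, 360] degrees")
    out = np.cos(np.radians(a))
    return float(out) if np.isscalar(aspect_deg) else out


def habitat_proportions(habitat: Raster, polygons) -> dict[str, float]:
    """Share of each habitat class among pixels inside the polygons."""
    vals = zonal_values(habitat, polygons)
    if vals.size == 0:
        return {name: float("nan") for name in HABITAT_CODES}
    return {name: float(np.mean(vals == code)) for name, code in HABITAT_CODES.items()}


def distance_to_line(polygons, line, grid: Raster) -> float:
    """Zonal mean distance (km) from pixel centers to a polyline."""
    mask = _inside_mask(grid, polygons)
    if not mask.any():
        return float("nan")
    X, Y = grid.pixel_centers()
    pts = shapely.points(X[mask], Y[mask])
    return float(np.mean(shapely.distance(pts, line)) / 1000.0)


def sample_accounting(table: pd.DataFrame) -> dict[str, int]:
    """Screening-log bookkeeping of how many animals survive each filter.

    ``n_classified`` counts animals with a resolved tactic;
    ``n_analysis`` those with complete CIRG, elevation and
    summer-winter distance / delta-elevation; ``n_reduced`` those
    complete once the distance/delta-elevation covariates are excluded
    from the model (the reduced selection run).
    """
    classified = table["tactic"].isin(["migrant", "resident"])
    has_cirg = table["cirg"].notna()
    has_elev = table["elevation_mean"].notna()
    has_dist = table["dist_summer_winter_km"].notna()
    return {
        "n_migrant": int((table["tactic"] == "migrant").sum()),
        "n_resident": int((table["tactic"] == "resident").sum()),
        "n_classified": int(classified.sum()),
        "n_analysis": int((classified & has_cirg & has_elev & has_dist).sum()),
        "n_reduced": int((classified & has_cirg & has_elev).sum()),
    }


def assemble_table(cirg_results, classifications, summer_ranges, pairs,
                   landscape, meta=None) -> pd.DataFrame:
    """One modeling row per animal: CIRG plus all home-range covariates.

    ``cirg_results`` maps id -> CIRGResult (or NaN cirg), ``summer_ranges``
    maps id -> HomeRange with isopleth polygons, ``pairs`` maps id ->
    SeasonalRangePair, ``meta`` (optional) maps id -> dict with sex and
    year.  Missing values stay as NaN (empty fields on CSV export); a
    screening log of exclusion counts is attached to ``DataFrame.attrs``.
    """
    slope, aspect = slope_aspect(landscape.dem)
    north = Raster(northness(aspect.values), aspect.x_min, aspect.y_min, aspect.res)
    elev_var = landscape.dem

    rows = []
    seen = set()
    for cls in classifications:
        if cls.id in seen:
            raise ValueError(f"duplicate animal id {cls.id}")
        seen.add(cls.id)
        row: dict = {"id": cls.id, "tactic": cls.tactic}
        if meta and cls.id in meta:
            row["sex"] = meta[cls.id].get("sex")
            row["year"] = meta[cls.id].get("year")
        cirg = cirg_results.get(cls.id)
        row["cirg"] = getattr(cirg, "cirg", np.nan) if cirg is not None else np.nan
        hr = summer_ranges.get(cls.id)
        if hr is not None and hr.polygons:
            polys = hr.polygons
            row["elevation_mean"], _ = zonal_mean(elev_var, polys)
            vals = zonal_values(elev_var, polys)
            row["elevation_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            row["slope_mean"], _ = zonal_mean(slope, polys)
            row["aspect_mean"], _ = zonal_mean(aspect, polys)
            row["northness"], _ = zonal_mean(north, polys)
            row["dist_coast_km"] = distance_to_line(polys, landscape.coastline, landscape.dem)
            row["dist_fjord_km"] = distance_to_line(polys, landscape.fjordline, landscape.dem)
            props = habitat_proportions(landscape.habitat, polys)
            for name, val in props.items():
                row[f"prop_{name}"] = val
            row["summer_window"] = hr.window
            row["home_range_km2"] = hr.area_km2
        pair = pairs.get(cls.id)
        if pair is not None and not pair.missing:
            row["delta_elevation_m"] = pair.delta_elevation_m
            row["dist_summer_winter_km"] = pair.distance_km
        rows.append(row)

    cols = ["id", "sex", "year", "tactic", "cirg", "elevation_mean", "elevation_sd",
            "slope_mean", "aspect_mean", "northness", "dist_coast_km",
            "dist_fjord_km", "prop_pasture", "prop_forest", "prop_mountain",
            "prop_other", "delta_elevation_m", "dist_summer_winter_km",
            "summer_window", "home_range_km2"]
    table = pd.DataFrame(rows).reindex(columns=cols)
    table.attrs["accounting"] = sample_accounting(table)
    return table
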