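"""Synthetic fjord landscape, NDVI green wave and partially migratory deer.

The generator produces the statistical structure the analysis assumes:
a coastal elevation gradient (elevation rising inland from a coastline),
an elevation-delayed spring green-up sampled as 16-day NDVI composites
at 250 m (the default delay is 50 days per 1,000 m elevation gain), a
4-class habitat raster at 100 m with the mountain class confined above
the treeline, and GPS tracks for two movement tactics: two-range
migrants (Ornstein-Uhlenbeck attraction to a range centroid, with a
rapid 3-day spring transit to a higher-elevation summer range and an
autumn return) and single-range residents.

All randomness flows from one seed; each animal gets a stable substream
so tracks are reproducible independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .movement import GPSTrack
from .phenology import PhenologyRaster, double_logistic
from .raster import Raster

#: Collar-years assigned cyclically to simulated animals (non-leap years,
#: so the 1 April - 31 August season is day-of-year 91-243 everywhere).
DEFAULT_YEARS = (2005, 2006, 2007, 2009, 2010, 2011)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world.  Defaults are the study conditions."""

    extent: float = 30_000.0  # m, square domain
    dem_res: float = 100.0  # m (landscape rasters)
    ndvi_res: float = 250.0  # m (NDVI composites)
    # terrain
    relief_ramp: float = 40.0  # m elevation per km distance-to-coast
    hill_amplitude: float = 60.0  # m, smooth random relief
    # habitat target proportions (pasture, forest, mountain, other)
    habitat_props: dict = field(default_factory=lambda: {
        "pasture": 0.15, "forest": 0.55, "mountain": 0.15, "other": 0.15})
    # phenology
    onset_intercept: float = 120.0  # spring midpoint (doy) at sea level
    onset_lapse: float = 50.0  # days delay per 1,000 m elevation
    green_up_scale: float = 9.0  # days, spring logistic scale
    autumn_offset: float = 130.0  # days from spring to autumn midpoint
    autumn_scale: float = 15.0
    ndvi_low: float = 0.15  # raw NDVI winter floor
    ndvi_high: float = 0.85  # raw NDVI summer plateau
    ndvi_noise_sd: float = 0.02
    # animals
    n_migrant: int = 20
    n_resident: int = 20
    fix_interval: float = 2.0  # hours; collars report every 1 or 2 h
    track_start_doy: int = 60  # 1 March
    track_end_doy: int = 288  # mid-October, so the autumn return is observed
    resident_radius_km: float = 1.2  # 95% range radius
    migrant_separation_km: tuple = (5.0, 15.0)  # uniform draw
    winter_coast_km: tuple = (1.5, 4.0)  # winter centroid distance to coast
    resident_coast_km: tuple = (1.0, 8.0)
    spring_departure_doy: tuple = (120.0, 130.0)  # uniform draw
    transit_days: float = 3.0  # rapid, jump-like migration
    autumn_departure_doy: tuple = (250.0, 260.0)
    ou_tau_hours: float = 6.0  # relaxation time of the range attraction
    years: tuple = DEFAULT_YEARS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent <= 0 or self.dem_res <= 0 or self.ndvi_res <= 0:
            raise ValueError("extent and resolutions must be positive")
        if self.fix_interval not in (1, 2):
            raise ValueError("collar schedule is every hour or every second hour")


@dataclass
class LandscapeBundle:
    """DEM + habitat rasters and coast/fjord polylines on one planar grid."""

    dem: Raster
    habitat: Raster
    coastline: LineString
    fjordline: LineString
    treeline_m: float
    crs_note: str = "planar projected coordinates in meters"


def _animal_rng(seed: int, animal_id: str) -> np.random.Generator:
    """Stable per-animal substream: hash the id into the seed sequence."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(animal_id.encode())])
    )


def generate_landscape(config: SimulationConfig) -> LandscapeBundle:
    """Deterministic (per seed) coastal landscape.

    Elevation rises inland from a straight coastline on the western edge
    at ``relief_ramp`` m/km plus smooth random hills, carved down along a
    fjord arm reaching inland; the habitat raster assigns the mountain
    class above the treeline (set at the 1 - p_mountain elevation
    quantile) and pasture/other at their configured shares below it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    res = config.dem_res
    n = int(round(config.extent / res))
    if n < 2:
        raise ValueError("extent too small for the DEM resolution")

    coastline = LineString([(0.0, 0.0), (0.0, config.extent)])
    fjordline = LineString([(0.0, 0.55 * config.extent),
                            (0.6 * config.extent, 0.55 * config.extent)])

    xs = (np.arange(n) + 0.5) * res
    ys = (np.arange(n) + 0.5) * res
    X, Y = np.meshgrid(xs, ys)
    dist_coast_km = X / 1000.0  # coastline is the x = 0 edge
    elev = config.relief_ramp * dist_coast_km
    if config.hill_amplitude > 0:
        noise = rng.standard_normal((n, n))
        hills = gaussian_filter(noise, sigma=8, mode="reflect")
        hills *= config.hill_amplitude / max(hills.std(), 1e-12)
        elev = elev + hills
    # carve a valley along the fjord arm
    d_fjord = np.abs(Y - 0.55 * config.extent)
    in_arm = X < 0.6 * config.extent
    elev = elev * (1.0 - 0.5 * np.exp(-(d_fjord / 1500.0) ** 2) * in_arm)
    elev = np.maximum(elev, 0.0)
    dem = Raster(elev, 0.0, 0.0, res)

    # habitat: mountain above the treeline; pasture/other below it
    props = config.habitat_props
    total = sum(props.values())
    p = {k: v / total for k, v in props.items()}
    flat = elev.ravel()
    treeline = float(np.quantile(flat, 1.0 - p["mountain"])) if p["mountain"] > 0 else float("inf")
    codes = np.full(flat.size, 1, dtype=float)  # forest default
    above = flat > treeline
    codes[above] = 2
    below_idx = np.nonzero(~above)[0]
    rng.shuffle(below_idx)
    n_pasture = int(round(p["pasture"] * flat.size))
    n_other = int(round(p["other"] * flat.size))
    codes[below_idx[:n_pasture]] = 0
    codes[below_idx[n_pasture:n_pasture + n_other]] = 3
    habitat = Raster(codes.reshape(n, n), 0.0, 0.0, res)
    return LandscapeBundle(dem=dem, habitat=habitat, coastline=coastline,
                           fjordline=fjordline, treeline_m=treeline)


def composite_dates(n: int = 23) -> np.ndarray:
    """MODIS-like 16-day composite days of year: 1, 17, 33, ..."""
    return 1 + 16 * np.arange(n)


def true_spring_midpoint(config: SimulationConfig, elevation_m) -> np.ndarray:
    """Generating spring inflection day: intercept + lapse x elev/1000."""
    return config.onset_intercept + config.onset_lapse * np.asarray(elevation_m) / 1000.0


def generate_ndvi_series(landscape: LandscapeBundle,
                         config: SimulationConfig) -> PhenologyRaster:
    """16-day NDVI composites following an elevation-delayed green wave.

    Each 250 m pixel gets a noiseless double-logistic annual curve whose
    spring inflection is delayed by ``onset_lapse`` days per 1,000 m of
    elevation, sampled at the composite dates with additive Gaussian
    noise.  The generating parameters are stored on the returned raster
    (``truth``) for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    res = config.ndvi_res
    n = int(round(config.extent / res))
    xs = (np.arange(n) + 0.5) * res
    ys = (np.arange(n) + 0.5) * res
    X, Y = np.meshgrid(xs, ys)
    elev = landscape.dem.value_at(X.ravel(), Y.ravel()).reshape(n, n)

    dates = composite_dates()
    s_mid = true_spring_midpoint(config, elev)
    a_mid = s_mid + config.autumn_offset
    curve = double_logistic(dates[:, None, None], s_mid[None], config.green_up_scale,
                            a_mid[None], config.autumn_scale)
    ndvi = config.ndvi_low + (config.ndvi_high - config.ndvi_low) * curve
    if config.ndvi_noise_sd > 0:
        ndvi = ndvi + rng.normal(0.0, config.ndvi_noise_sd, ndvi.shape)
    truth = {
        "elevation": elev,
        "spring_midpoint": s_mid,
        "spring_scale": np.full_like(s_mid, config.green_up_scale),
        "autumn_midpoint": a_mid,
        "autumn_scale": np.full_like(s_mid, config.autumn_scale),
    }
    return PhenologyRaster(ndvi, dates, 0.0, 0.0, res, truth=truth)


def _ou_path(rng, centroids_xy, times_hours, sd_m, tau_hours):
    """Discrete Ornstein-Uhlenbeck attraction to a (time-varying) centroid."""
    n = len(times_hours)
    pos = np.empty((n, 2))
    pos[0] = centroids_xy[0] + rng.normal(0.0, sd_m, 2)
    for i in range(1, n):
        dt = times_hours[i] - times_hours[i - 1]
        phi = np.exp(-dt / tau_hours)
        eps_sd = sd_m * np.sqrt(max(1.0 - phi ** 2, 0.0))
        pos[i] = centroids_xy[i] + phi * (pos[i - 1] - centroids_xy[i - 1]) \
            + rng.normal(0.0, eps_sd, 2)
    return pos


def simulate_deer(landscape: LandscapeBundle,
                  config: SimulationConfig) -> list[GPSTrack]:
    """GPS tracks for the two movement tactics, with truth labels.

    Migrants hold a low-elevation winter range, jump inland to a summer
    range over ``transit_days`` at an individual spring date, and return
    in autumn; residents hold one range all season.  Each track carries a
    ``truth`` dict (tactic, range centroids, migration days, radius).
    """
    if config.n_migrant + config.n_resident < 1:
        raise ValueError("need at least one animal")
    extent = config.extent
    margin = 1_500.0

    ids = [f"M{i + 1:03d}" for i in range(config.n_migrant)] + \
          [f"R{i + 1:03d}" for i in range(config.n_resident)]
    tracks: list[GPSTrack] = []
    for k, animal_id in enumerate(ids):
        rng = _animal_rng(config.seed, animal_id)
        migrant = animal_id.startswith("M")
        year = config.years[k % len(config.years)]
        sex = "F" if rng.random() < 0.6 else "M"
        radius_m = config.resident_radius_km * 1000.0
        sd_m = radius_m / 2.448  # 95% of a 2-D Gaussian within the radius

        y0 = rng.uniform(margin, extent - margin)
        if migrant:
            wx = rng.uniform(*config.winter_coast_km) * 1000.0
            sep = rng.uniform(*config.migrant_separation_km) * 1000.0
            angle = rng.uniform(-np.pi / 6, np.pi / 6)  # mostly inland
            sx = wx + sep * np.cos(angle)
            sy = y0 + sep * np.sin(angle)
            if not (margin <= sx <= extent - margin and margin <= sy <= extent - margin):
                sy = np.clip(sy, margin, extent - margin)
                if not margin <= sx <= extent - margin:
                    raise ValueError(
                        f"summer range for {animal_id} falls off the grid; enlarge extent")
            winter = np.array([wx, y0])
            summer = np.array([sx, sy])
            depart = rng.uniform(*config.spring_departure_doy)
            autumn = rng.uniform(*config.autumn_departure_doy)
        else:
            wx = rng.uniform(*config.resident_coast_km) * 1000.0
            winter = summer = np.array([wx, y0])
            depart = autumn = np.nan

        step_h = config.fix_interval
        times_h = np.arange(config.track_start_doy * 24.0,
                            (config.track_end_doy + 1) * 24.0, step_h)
        doy = times_h / 24.0
        centroids = np.tile(winter, (len(times_h), 1))
        if migrant:
            frac_spring = np.clip((doy - depart) / config.transit_days, 0.0, 1.0)
            frac_autumn = np.clip((doy - autumn) / config.transit_days, 0.0, 1.0)
            frac = frac_spring - frac_autumn  # 0 winter, 1 summer, back to 0
            centroids = winter[None] + frac[:, None] * (summer - winter)[None]

        pos = _ou_path(rng, centroids, times_h, sd_m, config.ou_tau_hours)
        pos[:, 0] = np.clip(pos[:, 0], 1.0, extent - 1.0)
        pos[:, 1] = np.clip(pos[:, 1], 1.0, extent - 1.0)

        start = pd.Timestamp(year=year, month=1, day=1)
        timestamps = start + pd.to_timedelta(times_h - 24.0, unit="h")
        fixes = pd.DataFrame({"timestamp": timestamps,
                              "x": pos[:, 0], "y": pos[:, 1]})
        truth = {
            "tactic": "migrant" if migrant else "resident",
            "winter_centroid": tuple(winter),
            "summer_centroid": tuple(summer),
            "separation_km": float(np.hypot(*(summer - winter)) / 1000.0),
            "spring_departure_doy": float(depart) if migrant else None,
            "autumn_departure_doy": float(autumn) if migrant else None,
            "range_radius_km": config.resident_radius_km,
        }
        tracks.append(GPSTrack(id=animal_id, sex=sex, year=year, fixes=fixes,
                               schedule=step_h, truth=truth))
    return tracks


def truth_table(tracks) -> pd.DataFrame:
    """Generating parameters of simulated animals, one row per track."""
    rows = []
    for t in tracks:
        row = {"id": t.id, "sex": t.sex, "year": t.year}
        row.update(t.truth or {})
        rows.append(row)
    return pd.DataFrame(rows)
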