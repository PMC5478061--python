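"""Per-pixel NDVI phenology, instantaneous rate of green-up, and CIRG.

The growing-season greenness of each 250 m pixel is summarized by a
double-logistic curve fitted to the annual series of NDVI composites
scaled to [0, 1]:

    f(t) = 1/(1 + exp((m_s - t)/s_s)) - 1/(1 + exp((m_a - t)/s_a))

where ``m_s``/``s_s`` are the spring midpoint (day of year) and scale
(days), and ``m_a``/``s_a`` the autumn counterparts.  The instantaneous
rate of green-up (IRG) is the derivative of the *spring* limb, rescaled
per pixel so its maximum (attained at t = m_s) is 1.  An animal's
cumulative IRG (CIRG) sums, over every day of the growing season on
which it has fixes, the daily mean IRG of the pixels it used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Growing season, day-of-year inclusive bounds (1 April - 31 August,
#: non-leap calendar).
DEFAULT_SEASON = (91, 243)

# Multistart grid for the spring limb; autumn starts are offset from spring.
SPRING_MID_STARTS = (90.0, 130.0, 170.0, 210.0)
SPRING_SCALE_STARTS = (5.0, 15.0)


@dataclass
class DoubleLogisticFit:
    """Fitted annual phenology curve for one pixel (on the scaled series)."""

    ndvi_min: float
    ndvi_max: float
    spring_midpoint: float
    spring_scale: float
    autumn_midpoint: float
    autumn_scale: float
    rss: float


def double_logistic(t, spring_mid, spring_scale, autumn_mid, autumn_scale):
    """Evaluate the scaled double-logistic greenness curve at day(s) t."""
    t = np.asarray(t, dtype=float)
    up = 1.0 / (1.0 + np.exp(np.clip((spring_mid - t) / spring_scale, -500, 500)))
    down = 1.0 / (1.0 + np.exp(np.clip((autumn_mid - t) / autumn_scale, -500, 500)))
    return up - down


def scale_ndvi(series):
    """Scale one pixel's annual NDVI series linearly to [0, 1].

    Returns ``(scaled, vmin, vmax)``, or ``None`` when the series is flat
    (max == min) and therefore unfittable.
    """
    series = np.asarray(series, dtype=float)
    finite = np.isfinite(series)
    if finite.sum() < 6:
        raise ValueError("need at least 6 finite NDVI values per pixel")
    vmin = np.nanmin(series[finite])
    vmax = np.nanmax(series[finite])
    if vmax <= vmin:
        return None
    return (series - vmin) / (vmax - vmin), float(vmin), float(vmax)


def _residuals(params, t, y):
    return double_logistic(t, *params) - y


def _jacobian(params, t, y):
    sm, ss, am, asc = params
    u = 1.0 / (1.0 + np.exp(np.clip((sm - t) / ss, -500, 500)))
    v = 1.0 / (1.0 + np.exp(np.clip((am - t) / asc, -500, 500)))
    J = np.empty((t.size, 4))
    J[:, 0] = -u * (1 - u) / ss
    J[:, 1] = -u * (1 - u) * (t - sm) / ss ** 2
    J[:, 2] = v * (1 - v) / asc
    J[:, 3] = v * (1 - v) * (t - am) / asc ** 2
    return J


def fit_double_logistic(series, dates) -> DoubleLogisticFit | None:
    """Least-squares double-logistic fit to one pixel's annual series.

    Initialization uses a data-driven guess (first/last half-maximum
    crossings) followed by a coarse multistart grid; the best-RSS
    converged solution is kept, ties broken toward the earliest spring
    midpoint.  Returns ``None`` (failure flag) for flat series and for
    series where no start converges to an admissible solution, e.g. a
    monotone-decreasing series whose spring midpoint escapes the
    observed date range.
    """
    dates = np.asarray(dates, dtype=float)
    scaled = scale_ndvi(series)
    if scaled is None:
        return None
    y, vmin, vmax = scaled

    t0, t1 = dates[0], dates[-1]
    lo = np.array([t0, 0.5, t0, 0.5])
    hi = np.array([t1, 80.0, t1 + 150.0, 80.0])

    # data-driven start: half-maximum crossings
    above = np.nonzero(y >= 0.5)[0]
    starts = []
    if above.size:
        s_mid0 = float(dates[above[0]])
        a_mid0 = float(min(dates[above[-1]] + 16.0, hi[2] - 1))
        starts.append((s_mid0, 10.0, max(a_mid0, s_mid0 + 30.0), 15.0))
    for sm in SPRING_MID_STARTS:
        for ss in SPRING_SCALE_STARTS:
            starts.append((sm, ss, min(sm + 120.0, hi[2] - 1), 15.0))

    # a data-driven start that converges to a near-interpolating solution is
    # accepted outright; the multistart grid is the fallback
    accept_rms = 0.05

    best: DoubleLogisticFit | None = None
    for p0 in starts:
        p0 = np.clip(p0, lo + 1e-6, hi - 1e-6)
        try:
            res = least_squares(_residuals, p0, args=(dates, y), jac=_jacobian,
                                bounds=(lo, hi))
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        if not res.success:
            continue
        sm, ss, am, asc = res.x
        rss = float(2.0 * res.cost)
        # admissibility: spring limb inside the data, off the bounds,
        # ordered before autumn
        eps = 1e-3
        at_bound = (
            sm <= lo[0] + eps
            or sm >= hi[0] - eps
            or ss <= lo[1] + eps
            or ss >= hi[1] - eps
        )
        if at_bound or not sm < am:
            continue
        if best is None or rss < best.rss - 1e-12 or (
            abs(rss - best.rss) <= 1e-12 and sm < best.spring_midpoint
        ):
            best = DoubleLogisticFit(vmin, vmax, float(sm), float(ss), float(am), float(asc), rss)
        if best is not None and np.sqrt(best.rss / dates.size) < accept_rms:
            break
    return best


def irg(fit: DoubleLogisticFit, t):
    """Instantaneous rate of green-up at day(s) ``t``, peak-scaled to 1.

    irg(t) = 4 s_s g'(t) = sech^2((m_s - t)/(2 s_s)) for the spring
    logistic g; symmetric about the spring midpoint, where it equals 1.
    """
    return _irg(fit.spring_midpoint, fit.spring_scale, t)


def _irg(spring_mid, spring_scale, t):
    z = (np.asarray(spring_mid, dtype=float) - np.asarray(t, dtype=float)) / spring_scale
    e = np.exp(-np.abs(z))
    return 4.0 * e / (1.0 + e) ** 2


class PhenologyRaster:
    """Gridded NDVI time series plus per-pixel phenology fits.

    Parameters
    ----------
    ndvi : ndarray, shape (T, nrow, ncol)
        NDVI composites; time axis first.
    dates : sequence of int
        Composite day-of-year values, strictly increasing with spacing 16.
    x_min, y_min, res : float
        Grid geometry in meters (row 0 at the southern edge).
    truth : dict of ndarray, optional
        Generating parameters for synthetic series (recovery tests).
    """

    def __init__(self, ndvi, dates, x_min, y_min, res, truth=None):
        self.ndvi = np.asarray(ndvi, dtype=float)
        self.dates = np.asarray(dates, dtype=float)
        if self.ndvi.ndim != 3 or self.ndvi.shape[0] != self.dates.size:
            raise ValueError("ndvi must be (T, nrow, ncol) matching dates")
        d = np.diff(self.dates)
        if np.any(d <= 0) or np.any(d != 16):
            raise ValueError("composite dates must increase with 16-day spacing")
        self.x_min = float(x_min)
        self.y_min = float(y_min)
        self.res = float(res)
        self.truth = truth
        self.fits: dict[tuple[int, int], DoubleLogisticFit | None] = {}

    @property
    def nrow(self) -> int:
        return self.ndvi.shape[1]

    @property
    def ncol(self) -> int:
        return self.ndvi.shape[2]

    def index_of(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.res).astype(int)
        row = np.floor((y - self.y_min) / self.res).astype(int)
        bad = (col < 0) | (col >= self.ncol) | (row < 0) | (row >= self.nrow)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(f"point ({x.flat[i]:.1f}, {y.flat[i]:.1f}) outside NDVI extent")
        return row, col

    def fit_pixel(self, row: int, col: int) -> DoubleLogisticFit | None:
        key = (int(row), int(col))
        if key not in self.fits:
            self.fits[key] = fit_double_logistic(self.ndvi[:, row, col], self.dates)
        return self.fits[key]

    def ensure_fitted(self, pixels) -> int:
        """Fit every (row, col) in ``pixels``; return the failure count."""
        failed = 0
        for row, col in pixels:
            if self.fit_pixel(row, col) is None:
                failed += 1
        return failed

    def fit_all(self) -> int:
        return self.ensure_fitted(
            (r, c) for r in range(self.nrow) for c in range(self.ncol)
        )


@dataclass
class CIRGResult:
    """Cumulative IRG for one animal over a growing season."""

    id: str
    cirg: float
    season: tuple[int, int] = DEFAULT_SEASON
    n_days_with_fixes: int = 0
    n_missing_fixes: int = 0


def build_space_time_matrix(tracks, phen: PhenologyRaster) -> pd.DataFrame:
    """Relate each animal's fixes to green-up in space and time.

    Each fix is mapped to its NDVI pixel and the pixel's IRG is evaluated
    at the fix's calendar date (integer day of year, so daily means do
    not depend on the collar schedule).  Fixes in pixels where the
    phenology fit failed get ``NaN`` IRG and are logged.

    Returns a DataFrame with columns id, doy, row, col, irg.
    """
    frames = []
    for track in tracks:
        x = track.fixes["x"].to_numpy(dtype=float)
        y = track.fixes["y"].to_numpy(dtype=float)
        try:
            row, col = phen.index_of(x, y)
        except ValueError as err:
            raise ValueError(f"animal {track.id}: {err}") from err
        doy = track.fixes["timestamp"].dt.dayofyear.to_numpy()
        frames.append(
            pd.DataFrame({"id": track.id, "doy": doy, "row": row, "col": col})
        )
    mat = pd.concat(frames, ignore_index=True)

    pixels = set(zip(mat["row"].tolist(), mat["col"].tolist()))
    n_failed = phen.ensure_fitted(pixels)
    if n_failed:
        logger.info("space-time matrix: %d pixels unfittable", n_failed)

    key = mat["row"].to_numpy() * phen.ncol + mat["col"].to_numpy()
    mid_of = {r * phen.ncol + c: phen.fits[(r, c)].spring_midpoint
              for (r, c) in pixels if phen.fits[(r, c)] is not None}
    scale_of = {r * phen.ncol + c: phen.fits[(r, c)].spring_scale
                for (r, c) in pixels if phen.fits[(r, c)] is not None}
    mids = np.array([mid_of.get(k, np.nan) for k in key])
    scales = np.array([scale_of.get(k, np.nan) for k in key])
    vals = np.full(len(mat), np.nan)
    ok = np.isfinite(mids)
    vals[ok] = _irg(mids[ok], scales[ok], mat["doy"].to_numpy()[ok])
    mat["irg"] = vals
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info("space-time matrix: %d fixes in unfittable pixels dropped", n_missing)
    return mat


def cumulative_irg(matrix: pd.DataFrame, animal_id: str,
                   season: tuple[int, int] = DEFAULT_SEASON) -> CIRGResult:
    """Sum daily mean IRG over the growing season for one animal.

    For each calendar day in ``season`` (inclusive) with at least one fix
    in a fittable pixel, the IRG values of that day's fixes are averaged;
    the daily means are then summed.
    """
    sub = matrix[matrix["id"] == animal_id]
    if sub.empty:
        raise KeyError(f"animal {animal_id} not present in space-time matrix")
    lo, hi = season
    sub = sub[(sub["doy"] >= lo) & (sub["doy"] <= hi)]
    if sub.empty:
        raise ValueError(f"animal {animal_id} has no fixes inside season {season}")
    n_missing = int(sub["irg"].isna().sum())
    valid = sub.dropna(subset=["irg"])
    daily = valid.groupby("doy")["irg"].mean()
    return CIRGResult(
        id=animal_id,
        cirg=float(daily.sum()),
        season=season,
        n_days_with_fixes=int(daily.size),
        n_missing_fixes=n_missing,
    )


def cirg_table(matrix: pd.DataFrame,
               season: tuple[int, int] = DEFAULT_SEASON) -> pd.DataFrame:
    """CIRG for every animal in a space-time matrix, as a DataFrame."""
    rows = []
    for animal_id in matrix["id"].unique():
        try:
            res = cumulative_irg(matrix, animal_id, season)
        except ValueError:
            rows.append({"id": animal_id, "cirg": np.nan, "n_days_with_fixes": 0})
            continue
        rows.append({"id": res.id, "cirg": res.cirg,
                     "n_days_with_fixes": res.n_days_with_fixes})
    return pd.DataFrame(rows)
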