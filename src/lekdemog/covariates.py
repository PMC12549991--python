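"""Covariate engineering: circular moving windows, exponential distance
decay, seasonal/annual lag-window aggregation of climate series, and z-score
standardization.

Scale conventions
-----------------
Candidate circular-window radii are 2.5, 5, and 10 km for population-level
covariates and 75, 167, 260, 370, 439, 1451 m for life-stage covariates
(1439 m is accepted as an alias for the largest radius, for which both
figures circulate).  Proximity covariates use an exponential
decay exp(-d / alpha) with alpha drawn from the life-stage set.  Coarse
(4 km) climate grids are sampled at the focal location with no moving
window.

Lag-window conventions
----------------------
For a population response in year t (the spring lek count), "previous"
windows resolve as: previous calendar year = 14 Mar t-1 .. 14 Mar t; water
year = 1 Oct t-2 .. 30 Sep t-1; growing season / spring / summer / fall =
those seasons of t-1; winter = 1 Dec t-1 .. end Feb t.  The winter window
ends 29 Feb in leap years (no-data-loss convention).  Survival-model
concurrent windows (current month, previous month, spring Mar-May) resolve
from the encounter interval's midpoint date.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "POPULATION_RADII_M",
    "LIFESTAGE_RADII_M",
    "DECAY_ALPHAS_M",
    "normalize_scale",
    "moving_window_mean",
    "distance_decay",
    "LagWindow",
    "LAG_WINDOWS",
    "resolve_window",
    "resolve_concurrent_window",
    "aggregate_lag_window",
    "standardize",
    "CLIMATE_VARIABLES",
]

POPULATION_RADII_M = (2500.0, 5000.0, 10000.0)
LIFESTAGE_RADII_M = (75.0, 167.0, 260.0, 370.0, 439.0, 1451.0)
DECAY_ALPHAS_M = LIFESTAGE_RADII_M
#: Alias for the largest life-stage radius, which circulates both as
#: 1,439 m and 1,451 m.
_SCALE_ALIASES = {1439.0: 1451.0}

CLIMATE_VARIABLES = ("PPT", "SPI", "SPEI", "PWD", "VPD", "TMIN", "TMAX", "SWE")


def normalize_scale(value: float) -> float:
    """Map known aliases onto the canonical candidate scale."""
    return _SCALE_ALIASES.get(float(value), float(value))


def moving_window_mean(grid: np.ndarray, center: tuple[int, int],
                       radius: float, cell_size: float = 1.0) -> float:
    """Mean of grid cells whose centres lie within ``radius`` of the focal
    cell centre (circular moving window).

    Cells outside the grid are excluded from both numerator and denominator;
    a radius smaller than the cell size returns the focal cell value.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if radius < cell_size / 2.0:
        raise ValueError("radius must be at least half the cell size")
    i0, j0 = center
    if not (0 <= i0 < grid.shape[0] and 0 <= j0 < grid.shape[1]):
        raise ValueError(f"center {center} lies outside the grid")
    ii, jj = np.indices(grid.shape)
    dist = cell_size * np.hypot(ii - i0, jj - j0)
    mask = dist <= radius
    if not mask.any():
        raise ValueError("window covers zero cells")
    return float(grid[mask].mean())


def distance_decay(d: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """Exponential proximity weight exp(-d / alpha) in (0, 1]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance must be non-negative")
    out = np.exp(-d_arr / alpha)
    return out if np.ndim(d) else float(out)


@dataclass(frozen=True)
class LagWindow:
    """A named lag window anchored by month-day endpoints.

    ``start_offset`` / ``end_offset`` are year offsets relative to the
    response year t; endpoints are inclusive.  ``end_month_day`` of
    (2, 28) extends to 29 Feb in leap years.
    """

    name: str
    start_month_day: tuple[int, int]
    end_month_day: tuple[int, int]
    start_offset: int
    end_offset: int


LAG_WINDOWS: dict[str, LagWindow] = {
    "previous_calendar_year": LagWindow(
        "previous_calendar_year", (3, 14), (3, 14), -1, 0),
    "water_year": LagWindow("water_year", (10, 1), (9, 30), -2, -1),
    "growing_season": LagWindow("growing_season", (4, 1), (10, 31), -1, -1),
    "spring": LagWindow("spring", (3, 1), (5, 31), -1, -1),
    "summer": LagWindow("summer", (6, 1), (8, 31), -1, -1),
    "fall": LagWindow("fall", (9, 1), (11, 30), -1, -1),
    "winter": LagWindow("winter", (12, 1), (2, 28), -1, 0),
}


def _window_end(year: int, month: int, day: int) -> dt.date:
    # winter nominally ends 28 Feb; extend to 29 Feb in leap years
    if (month, day) == (2, 28):
        try:
            return dt.date(year, 2, 29)
        except ValueError:
            return dt.date(year, 2, 28)
    return dt.date(year, month, day)


def resolve_window(name: str, response_year: int) -> tuple[dt.date, dt.date]:
    """Absolute (start, end) dates of a named lag window for a response in
    ``response_year``; both endpoints inclusive."""
    try:
        w = LAG_WINDOWS[name]
    except KeyError:
        raise ValueError(f"unknown lag window {name!r}") from None
    start = dt.date(response_year + w.start_offset, *w.start_month_day)
    end = _window_end(response_year + w.end_offset, *w.end_month_day)
    if end <= start and name != "previous_calendar_year":
        raise ValueError(f"window {name!r} resolved to an empty span")
    return start, end


def resolve_concurrent_window(name: str, reference_date: dt.date
                              ) -> tuple[dt.date, dt.date]:
    """Survival-model concurrent windows resolved from an interval's
    midpoint date: current month, previous month, or spring (Mar-May) of the
    reference year."""
    y, m = reference_date.year, reference_date.month
    if name == "current_month":
        start = dt.date(y, m, 1)
    elif name == "previous_month":
        y2, m2 = (y - 1, 12) if m == 1 else (y, m - 1)
        start = dt.date(y2, m2, 1)
    elif name == "spring_mar_may":
        return dt.date(y, 3, 1), dt.date(y, 5, 31)
    else:
        raise ValueError(f"unknown concurrent window {name!r}")
    nxt = (dt.date(start.year + 1, 1, 1) if start.month == 12
           else dt.date(start.year, start.month + 1, 1))
    return start, nxt - dt.timedelta(days=1)


def aggregate_lag_window(series: pd.DataFrame, window: str,
                         response_year: int, mode: str = "mean",
                         reference_date: dt.date | None = None) -> float:
    """Aggregate a climate series over a resolved lag window.

    ``series`` needs columns ``date`` (datetime-like) and ``value``.
    ``mode`` is ``"mean"`` (default; comparable across windows of unequal
    length), ``"sum"`` (cumulative-precipitation variant), ``"min"`` or
    ``"max"`` (monthly temperature extrema).  An empty window returns NaN
    with a warning rather than raising.
    """
    if mode not in ("mean", "sum", "min", "max"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if window in ("current_month", "previous_month", "spring_mar_may"):
        if reference_date is None:
            raise ValueError(f"window {window!r} needs a reference_date")
        start, end = resolve_concurrent_window(window, reference_date)
    else:
        start, end = resolve_window(window, response_year)
    dates = pd.to_datetime(series["date"]).dt.date
    mask = (dates >= start) & (dates <= end)
    if not mask.any():
        warnings.warn(
            f"window {window!r} [{start}..{end}] contains no data",
            stacklevel=2)
        return float("nan")
    vals = series.loc[mask.to_numpy(), "value"].to_numpy(dtype=float)
    agg = {"mean": np.mean, "sum": np.sum, "min": np.min, "max": np.max}
    return float(agg[mode](vals))


def standardize(x: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Z-score a covariate vector (sample sd, n-1 denominator).

    Returns the standardized vector and the ``(mean, sd)`` pair, which must
    be reused verbatim when standardizing prediction inputs.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("standardize requires length >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("covariate has zero variance; cannot standardize")
    return (x - mean) / sd, (mean, sd)
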