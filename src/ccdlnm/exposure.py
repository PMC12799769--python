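"""Exposure assignment, lag matrices, extreme-value trimming, pollutants.

Every event-hour (case or control) receives a backward exposure history from
the weather station nearest to the patient's residence, provided that station
is within a maximum distance (default 50 km); patients farther than that from
every station are excluded, not erred on.  The history for event-hour ``t``
is the vector ``(x_t, x_{t-1}, ..., x_{t-L})`` read straight off the
station's hourly series; hours missing from the series are masked, never
imputed here.

Hourly extremes are trimmed in two stages on the pooled case-window values:
stage 1 masks individual values strictly below the pooled 1st percentile or
strictly above the 99th; stage 2 recomputes, on the surviving values, the 1st
percentile (the "extreme low" contrast value) and the 99th percentile (the
reference).  Percentiles use linear interpolation between order statistics
(type 7), which the trim counts depend on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "haversine_km", "match_station", "build_lag_matrix",
    "ExposureMatrix", "TrimResult", "trim_extremes", "pollutant_means",
    "POLLUTANTS",
]

EARTH_RADIUS_KM = 6371.0
POLLUTANTS = ["pm25", "pm10", "so2", "no2", "o3", "co"]


def haversine_km(point_a, point_b) -> float:
    """Great-circle distance in km between (lat, lon) pairs in degrees."""
    lat1, lon1 = point_a
    lat2, lon2 = point_b
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def match_station(record, stations, max_km: float = 50.0):
    """Nearest admissible station for one patient record.

    ``record`` needs ``latitude``/``longitude`` attributes or keys; ties in
    distance break to the lexicographically smallest ``station_id``.

    Returns ``(station, distance_km)``; ``(None, distance_km)`` when the
    nearest station is beyond ``max_km`` (an exclusion outcome, not an error).
    """
    if not stations:
        raise ValueError("at least one station is required")
    get = (lambda k: record[k]) if isinstance(record, dict) else \
        (lambda k: getattr(record, k))
    p = (float(get("latitude")), float(get("longitude")))
    ranked = sorted(
        ((haversine_km(p, (s.latitude, s.longitude)), str(s.station_id), s)
         for s in stations),
        key=lambda t: (t[0], t[1]),
    )
    d, _, best = ranked[0]
    if d > max_km:
        return None, d
    return best, d


@dataclass
class ExposureMatrix:
    """Backward lag histories for a set of event-hours.

    ``Q[i, l]`` is the exposure at ``event_hours[i]`` minus ``l`` hours
    (column 0 is the concurrent hour); ``mask[i, l]`` is True where the value
    is unavailable or trimmed.  Masked cells stay NaN in ``Q``.
    """

    event_hours: pd.DatetimeIndex
    exposure_name: str
    Q: np.ndarray
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.mask is None:
            self.mask = ~np.isfinite(self.Q)

    @property
    def max_lag(self) -> int:
        return self.Q.shape[1] - 1


def build_lag_matrix(series, event_hours, exposure_name: str,
                     L: int = 24) -> ExposureMatrix:
    """Lag matrix for ``event_hours`` from one station's hourly series.

    ``series`` is a StationSeries-like object whose ``frame`` is indexed by a
    contiguous hourly DatetimeIndex and carries ``exposure_name`` as a column.
    Hours absent from the series (outside its range, or NaN) yield masked
    cells; an event-hour entirely outside the range yields a fully masked row.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    hours = pd.DatetimeIndex(event_hours)
    idx = series.frame.index
    values = series.frame[exposure_name].to_numpy(dtype=float)
    start = idx[0]
    pos = ((hours - start) / pd.Timedelta(hours=1)).astype(int).to_numpy()
    lagpos = pos[:, None] - np.arange(L + 1)[None, :]
    valid = (lagpos >= 0) & (lagpos < len(idx))
    Q = np.full(lagpos.shape, np.nan)
    Q[valid] = values[lagpos[valid]]
    return ExposureMatrix(hours, exposure_name, Q)


@dataclass
class TrimResult:
    """Two-stage trimming bounds and the resulting contrast values."""

    exposure_name: str
    lower: float          # stage-1 P1 of the pooled case-window values
    upper: float          # stage-1 P99
    x_ext: float          # stage-2 P1 of the surviving values (extreme low)
    x_ref: float          # stage-2 P99 (reference)
    n_masked: int
    retain_extremes: bool = False

    def contrast_value(self, percentile: float, pool: np.ndarray) -> float:
        """Alternative low-exposure contrast at another percentile of the
        post-trim pool (used by the sensitivity grid)."""
        return float(np.quantile(pool, percentile / 100.0))

    def require_contrast(self) -> None:
        """Raise when the extreme value equals the reference: a degenerate
        distribution supports no exposure contrast downstream."""
        if self.x_ext == self.x_ref:
            raise ValueError(
                f"degenerate {self.exposure_name or 'exposure'} distribution: "
                "extreme value equals the reference; no contrast is estimable")


def trim_extremes(pool: np.ndarray, retain_extremes: bool = False,
                  lower_pct: float = 1.0, upper_pct: float = 99.0):
    """Two-stage percentile trimming of pooled case-window exposure values.

    Stage 1 computes the ``lower_pct``/``upper_pct`` percentiles of ``pool``
    (NaNs ignored) and masks values *strictly* outside them.  Stage 2
    recomputes the same percentiles on the survivors, defining the extreme
    contrast value ``x_ext`` and the reference ``x_ref``.  With
    ``retain_extremes`` stage 1 is skipped (identity mask) and stage 2 runs
    on the raw pool.

    Returns ``(TrimResult, keep_mask)`` where ``keep_mask`` flags the pool
    entries that survive (NaNs do not survive but are not counted as masked).
    """
    pool = np.asarray(pool, dtype=float).ravel()
    finite = np.isfinite(pool)
    vals = pool[finite]
    if vals.size < 100:
        warnings.warn(
            f"only {vals.size} pooled values; percentile trim bounds are "
            "unstable below 100", stacklevel=2)
    if vals.size == 0:
        raise ValueError("empty exposure pool")
    if retain_extremes:
        lower, upper = float(vals.min()), float(vals.max())
        keep = finite.copy()
        survivors = vals
    else:
        lower = float(np.quantile(vals, lower_pct / 100.0))
        upper = float(np.quantile(vals, upper_pct / 100.0))
        keep = finite & (pool >= lower) & (pool <= upper)
        survivors = pool[keep]
    x_ext = float(np.quantile(survivors, lower_pct / 100.0))
    x_ref = float(np.quantile(survivors, upper_pct / 100.0))
    n_masked = int(finite.sum() - keep.sum())
    return TrimResult("", lower, upper, x_ext, x_ref, n_masked,
                      retain_extremes), keep


def apply_trim(matrix: ExposureMatrix, trim: TrimResult) -> ExposureMatrix:
    """Mask cells of a lag matrix outside the stage-1 trim bounds."""
    Q = matrix.Q.copy()
    mask = matrix.mask.copy()
    if not trim.retain_extremes:
        out = np.isfinite(Q) & ((Q < trim.lower) | (Q > trim.upper))
        Q[out] = np.nan
        mask |= out
    return ExposureMatrix(matrix.event_hours, matrix.exposure_name, Q, mask)


def pollutant_means(series, event_hours, L: int = 24,
                    pollutants=None, max_masked_frac: float = 0.25):
    """Backward ``L``-hour mean of each pollutant per event-hour.

    Means are over the unmasked hours of the window; events with more than
    ``max_masked_frac`` of a pollutant's window masked are flagged (their
    mean is still returned when any hour is observed, NaN when none is).

    Returns ``(means, flagged)``: an ``(n, n_pollutants)`` array and a
    boolean flag vector.
    """
    if pollutants is None:
        pollutants = POLLUTANTS
    n = len(pd.DatetimeIndex(event_hours))
    means = np.full((n, len(pollutants)), np.nan)
    flagged = np.zeros(n, dtype=bool)
    for j, name in enumerate(pollutants):
        m = build_lag_matrix(series, event_hours, name, L)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means[:, j] = np.nanmean(np.where(m.mask, np.nan, m.Q), axis=1)
        flagged |= m.mask.mean(axis=1) > max_masked_frac
    return means, flagged
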