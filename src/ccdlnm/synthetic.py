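"""Synthetic hourly weather, pollutants, and onset events with known truth.

The generator emulates a humid subtropical monsoon climate at hourly
resolution: temperature is a mean plus an annual sinusoid (peak mid-July), a
diurnal sinusoid (peak 15:00), and stationary AR(1) noise; relative humidity
is anticorrelated with the temperature anomaly and clamped to [0, 100];
pollutants are lognormal with AR(1) persistence on the log scale.  Defaults
are calibrated to the mid-latitude mountainous study setting (annual mean
16.8 degC, mean relative humidity ~72%).

Onset events are drawn from an inhomogeneous rate

    lambda(t) = lambda0(t) * exp( sum_{l=0..L} f(x_{t-l}, l) )

by thinning (accept-reject against the maximum rate), where ``f`` is a known
exposure-lag-response surface.  Because the truth surface is explicit, every
downstream stage — lag matrices, cross-basis, conditional-logit fit, odds
ratios — has a parameter-recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "WeatherConfig", "StationSeries", "SimulationTruth", "OnsetRecord",
    "simulate_weather", "simulate_onsets", "decaying_linear_surface",
]

# lognormal pollutant calibration: median (units as named) and log-sd
DEFAULT_POLLUTANT_PARAMS = {
    "pm25": (17.8, 0.60),
    "pm10": (33.8, 0.60),
    "so2": (7.5, 0.35),
    "no2": (8.0, 0.45),
    "o3": (79.1, 0.30),
    "co": (0.6, 0.30),
}


@dataclass
class WeatherConfig:
    start_time: str | pd.Timestamp = "2021-01-01 00:00"
    end_time: str | pd.Timestamp = "2023-12-31 23:00"
    mean_temp: float = 16.8            # degC, annual mean
    annual_amplitude: float = 11.0     # degC, summer-winter half-range
    diurnal_amplitude: float = 4.0     # degC, day-night half-range
    annual_peak_doy: float = 196.0     # day of year of the warmest day (mid-July)
    diurnal_peak_hour: float = 15.0    # local hour of the warmest time of day
    ar1_coefficient: float = 0.95      # hourly persistence of the noise
    noise_sd: float = 0.8              # degC, innovation scale
    rh_mean: float = 72.0              # %
    rh_temp_slope: float = -1.5        # % per degC of temperature anomaly
    rh_noise_sd: float = 8.0           # %
    pollutant_params: dict = field(
        default_factory=lambda: dict(DEFAULT_POLLUTANT_PARAMS))
    pollutant_ar1: float = 0.98
    n_stations: int = 3
    lat_range: tuple = (32.0, 33.0)    # degrees, station coordinate box
    lon_range: tuple = (110.0, 111.0)
    seed: int = 0

    def validate(self) -> None:
        start, end = pd.Timestamp(self.start_time), pd.Timestamp(self.end_time)
        if end <= start:
            raise ValueError("end_time must be after start_time")
        for t in (start, end):
            if t.minute or t.second:
                raise ValueError("start/end must lie on the hourly grid")
        if not -1 < self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in (-1, 1)")
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")


@dataclass
class StationSeries:
    """One station's contiguous hourly record."""

    station_id: str
    latitude: float
    longitude: float
    frame: pd.DataFrame  # hourly DatetimeIndex; temperature, relative_humidity, pollutants

    def __post_init__(self):
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError("frame must be indexed by timestamps")
        if idx.has_duplicates:
            raise ValueError("duplicate timestamps in station series")
        if len(idx) > 1:
            step = np.unique(np.diff(idx.asi8))
            if step.size != 1 or step[0] != 3_600_000_000_000:
                raise ValueError("station series must be strictly hourly")
        rh = self.frame.get("relative_humidity")
        if rh is not None and ((rh.dropna() < 0).any() or (rh.dropna() > 100).any()):
            raise ValueError("relative humidity outside [0, 100]")


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd ``sd / sqrt(1 - rho^2)``."""
    e = rng.normal(0.0, sd, n)
    e[0] = e[0] / np.sqrt(1.0 - rho * rho)  # stationary start
    return lfilter([1.0], [1.0, -rho], e)


def simulate_weather(cfg: WeatherConfig) -> list[StationSeries]:
    """Simulate one hourly :class:`StationSeries` per station.

    Identical config (including seed) reproduces the output bit for bit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    idx = pd.date_range(pd.Timestamp(cfg.start_time), pd.Timestamp(cfg.end_time),
                        freq="h")
    n = len(idx)
    doy = idx.dayofyear.to_numpy() + idx.hour.to_numpy() / 24.0
    hod = idx.hour.to_numpy()
    annual = cfg.annual_amplitude * np.cos(
        2 * np.pi * (doy - cfg.annual_peak_doy) / 365.25)
    diurnal = cfg.diurnal_amplitude * np.cos(
        2 * np.pi * (hod - cfg.diurnal_peak_hour) / 24.0)
    stations = []
    for s in range(cfg.n_stations):
        lat = rng.uniform(*cfg.lat_range)
        lon = rng.uniform(*cfg.lon_range)
        temp = (cfg.mean_temp + annual + diurnal
                + _ar1(rng, n, cfg.ar1_coefficient, cfg.noise_sd))
        rh = (cfg.rh_mean + cfg.rh_temp_slope * (temp - cfg.mean_temp)
              + rng.normal(0.0, cfg.rh_noise_sd, n))
        rh = np.clip(rh, 0.0, 100.0)
        data = {"temperature": temp, "relative_humidity": rh}
        for name, (median, log_sd) in cfg.pollutant_params.items():
            z = _ar1(rng, n, cfg.pollutant_ar1,
                     log_sd * np.sqrt(1.0 - cfg.pollutant_ar1 ** 2))
            data[name] = np.exp(np.log(median) + z)
        frame = pd.DataFrame(data, index=idx)
        stations.append(StationSeries(f"S{s:03d}", float(lat), float(lon), frame))
    return stations


def decaying_linear_surface(slope: float, anchor: float,
                            decay_hours: float = 8.0) -> Callable:
    """Truth surface ``f(x, l) = slope * (x - anchor) * exp(-l / decay_hours)``.

    Linear in the exposure (so it lies in the span of a natural cubic spline
    basis) with a geometrically decaying lag profile.  A negative ``slope``
    makes low exposure raise risk.  ``f(anchor, l) = 0`` for all lags, making
    ``anchor`` the centering reference.
    """

    def f(x, lag):
        return slope * (np.asarray(x, dtype=float) - anchor) * np.exp(
            -np.asarray(lag, dtype=float) / decay_hours)

    return f


@dataclass
class SimulationTruth:
    """Known ground truth for the onset-generating process.

    ``surface(x, l)`` returns the log-rate contribution of exposure value
    ``x`` at lag ``l`` and must vanish at its declared reference exposure.
    ``baseline_log_rate(t)`` maps a DatetimeIndex to log lambda0(t).
    """

    surface: Callable = field(default_factory=lambda: (lambda x, lag: 0.0 * np.asarray(x)))
    exposure_name: str = "temperature"
    max_lag: int = 24
    baseline_log_rate: "Callable | None" = None  # None -> constant rate
    covariate_margins: dict = field(default_factory=lambda: {
        "male": 0.603, "smoking": 0.343, "alcohol": 0.443, "deep": 0.732,
        "infratentorial": 0.149,
    })

    def cumulative_log_or(self, x: float, x_ref: float,
                          window: tuple[int, int] | None = None) -> float:
        """True cumulative log odds ratio of ``x`` vs ``x_ref`` over a lag
        window (defaults to the full 0..max_lag window)."""
        l0, l1 = window if window is not None else (0, self.max_lag)
        lags = np.arange(l0, l1 + 1)
        return float(np.sum(self.surface(x, lags) - self.surface(x_ref, lags)))


def simulate_onsets(stations: list[StationSeries], truth: SimulationTruth,
                    n_cases: int, seed: int,
                    patient_radius_km: float = 10.0,
                    far_fraction: float = 0.0) -> pd.DataFrame:
    """Draw ``n_cases`` onset records by thinning from the truth rate.

    Each patient is assigned a station uniformly at random and coordinates
    within ``patient_radius_km`` of it; with ``far_fraction > 0`` that share
    of patients is instead placed ~60 km away to exercise the distance
    exclusion.  Candidate hours are restricted so that the lag window of the
    case hour *and of every calendar referent hour in its month* is covered
    by the series.

    Returns a patient DataFrame (patient_id, onset_time, latitude, longitude,
    age, sex, smoking, alcohol, gcs, ich_location).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    L = truth.max_lag

    per_station = []
    for st in stations:
        idx = st.frame.index
        x = st.frame[truth.exposure_name].to_numpy(dtype=float)
        # log relative rate per hour: sum over lags of f(x_{t-l}, l)
        logrr = np.full(len(idx), -np.inf)
        if len(idx) <= L:
            raise ValueError("station series shorter than the lag window")
        contrib = np.zeros(len(idx) - L)
        for l in range(L + 1):
            contrib += np.asarray(
                truth.surface(x[L - l: len(x) - l], l), dtype=float)
        logrr[L:] = contrib
        if truth.baseline_log_rate is not None:
            logrr = logrr + np.asarray(truth.baseline_log_rate(idx), dtype=float)
        # eligibility: whole calendar month inside the series, with the month's
        # first hour still owning a full lag window
        month_start = idx.to_period("M").to_timestamp()
        month_end = (month_start + pd.offsets.MonthBegin(1)) - pd.Timedelta(hours=1)
        eligible = np.asarray((month_start - pd.Timedelta(hours=L) >= idx[0])
                              & (month_end <= idx[-1]))
        logrr[~eligible] = -np.inf
        if not np.any(np.isfinite(logrr)):
            raise ValueError(
                "series too short: no hour has full lag coverage for itself "
                "and its referents")
        per_station.append(logrr)

    records = []
    for i in range(n_cases):
        s = int(rng.integers(len(stations)))
        st = stations[s]
        logrr = per_station[s]
        lmax = np.max(logrr)
        n_hours = len(logrr)
        # thinning: uniform candidate hour, accept with prob rate/max rate
        while True:
            t = int(rng.integers(n_hours))
            if not np.isfinite(logrr[t]):
                continue
            if np.log(rng.uniform()) < logrr[t] - lmax:
                break
        onset = st.frame.index[t]
        far = rng.uniform() < far_fraction
        radius = 60.0 if far else patient_radius_km * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        lat = st.latitude + (radius / 111.195) * np.cos(theta)
        lon = st.longitude + (radius / (111.195 * np.cos(np.radians(st.latitude)))) * np.sin(theta)
        m = truth.covariate_margins
        u = rng.uniform(size=4)
        loc_draw = rng.uniform()
        if loc_draw < m.get("deep", 0.732):
            loc = "deep"
        elif loc_draw < m.get("deep", 0.732) + m.get("infratentorial", 0.149):
            loc = "infratentorial"
        else:
            loc = "lobar"
        records.append({
            "patient_id": f"P{i:05d}",
            "onset_time": onset,
            "latitude": float(lat),
            "longitude": float(lon),
            "age": int(np.clip(rng.normal(60.1, 11.5), 18, 95)),
            "sex": "male" if u[0] < m.get("male", 0.603) else "female",
            "smoking": "yes" if u[1] < m.get("smoking", 0.343) else "no",
            "alcohol": "yes" if u[2] < m.get("alcohol", 0.443) else "no",
            "gcs": int(rng.integers(3, 16)),
            "ich_location": loc,
        })
    return pd.DataFrame(records)


@dataclass
class OnsetRecord:
    """Typed view of one patient row; validates the record invariants."""

    patient_id: str
    onset_time: pd.Timestamp
    latitude: float
    longitude: float
    age: int
    sex: str
    smoking: str
    alcohol: str
    gcs: int
    ich_location: str

    def __post_init__(self):
        self.onset_time = pd.Timestamp(self.onset_time)
        if self.onset_time.minute or self.onset_time.second:
            raise ValueError("onset_time must be floored to the hour")
        if not 3 <= int(self.gcs) <= 15:
            raise ValueError(f"gcs {self.gcs} outside [3, 15]")
        if self.age < 18:
            raise ValueError("age must be >= 18")
        if self.ich_location not in ("deep", "infratentorial", "lobar"):
            raise ValueError(f"unknown ich_location {self.ich_location!r}")

    def to_dict(self) -> dict:
        return asdict(self)
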