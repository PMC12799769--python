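"""Readers, writers, validation, and descriptive statistics.

CSV dialect throughout: comma-separated, UTF-8, ISO-8601 civil timestamps,
"." decimal mark.  Station files carry one row per station-hour; patient
files one row per case.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import POLLUTANTS
from .synthetic import StationSeries

__all__ = [
    "write_station_csv", "read_station_csv", "write_patient_csv",
    "read_patient_csv", "load_inputs", "validate_patients",
    "validate_stations", "descriptive_summary", "moving_average",
]

STATION_COLUMNS = ["station_id", "lat", "lon", "timestamp", "temp_c", "rh_pct",
                   *POLLUTANTS]
PATIENT_COLUMNS = ["patient_id", "onset_time", "lat", "lon", "age", "sex",
                   "smoking", "alcohol", "gcs", "ich_location"]
_RENAME_IN = {"temp_c": "temperature", "rh_pct": "relative_humidity"}
_RENAME_OUT = {v: k for k, v in _RENAME_IN.items()}


def write_station_csv(stations: list[StationSeries], path) -> None:
    frames = []
    for st in stations:
        f = st.frame.rename(columns=_RENAME_OUT).reset_index(names="timestamp")
        f.insert(0, "station_id", st.station_id)
        f.insert(1, "lat", st.latitude)
        f.insert(2, "lon", st.longitude)
        frames.append(f[STATION_COLUMNS])
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_station_csv(path) -> list[StationSeries]:
    df = pd.read_csv(path)
    missing = set(STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"station file missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = []
    for sid, g in df.groupby("station_id", sort=True):
        frame = (g.set_index("timestamp").sort_index()
                 [["temp_c", "rh_pct", *POLLUTANTS]].rename(columns=_RENAME_IN))
        frame.index.name = None
        out.append(StationSeries(str(sid), float(g["lat"].iloc[0]),
                                 float(g["lon"].iloc[0]), frame))
    return out


def write_patient_csv(records: pd.DataFrame, path) -> None:
    df = records.rename(columns={"latitude": "lat", "longitude": "lon"}).copy()
    df["onset_time"] = pd.to_datetime(df["onset_time"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    df[PATIENT_COLUMNS].to_csv(path, index=False)


def read_patient_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"patient file missing columns: {sorted(missing)}")
    try:
        df["onset_time"] = pd.to_datetime(df["onset_time"])
    except (ValueError, TypeError) as err:
        raise ValueError(f"unparseable onset_time values: {err}") from err
    return df.rename(columns={"lat": "latitude", "lon": "longitude"})


def validate_patients(df: pd.DataFrame) -> pd.DataFrame:
    """Row-level invariant violations -> DataFrame (row, patient_id, problem)."""
    problems = []
    for i, row in df.iterrows():
        pid = row.get("patient_id", "?")
        ts = pd.Timestamp(row["onset_time"])
        if ts.minute or ts.second:
            problems.append((i, pid, "onset_time not at hour precision"))
        if not 3 <= row["gcs"] <= 15:
            problems.append((i, pid, f"gcs {row['gcs']} outside [3, 15]"))
        if row["age"] < 18:
            problems.append((i, pid, f"age {row['age']} below 18"))
        if row["ich_location"] not in ("deep", "infratentorial", "lobar"):
            problems.append((i, pid, f"unknown ich_location {row['ich_location']!r}"))
    return pd.DataFrame(problems, columns=["row", "patient_id", "problem"])


def validate_stations(stations: list[StationSeries]) -> pd.DataFrame:
    problems = []
    for st in stations:
        rh = st.frame["relative_humidity"]
        bad = rh[(rh < 0) | (rh > 100)]
        for ts, v in bad.items():
            problems.append((st.station_id, ts, f"relative humidity {v} outside [0, 100]"))
        for p in POLLUTANTS:
            neg = st.frame[p][st.frame[p] < 0]
            for ts, v in neg.items():
                problems.append((st.station_id, ts, f"negative {p}: {v}"))
    return pd.DataFrame(problems, columns=["station_id", "timestamp", "problem"])


def load_inputs(config) -> tuple[pd.DataFrame, list[StationSeries], dict]:
    """Load and validate the patient and station files named in ``config``.

    StationSeries construction rejects non-hourly or duplicated timestamps;
    value-level violations are collected per row and returned in the report
    rather than raised.
    """
    records = read_patient_csv(config.patient_csv)
    raw = pd.read_csv(config.station_csv)
    missing = set(STATION_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"station file missing columns: {sorted(missing)}")
    raw["timestamp"] = pd.to_datetime(raw["timestamp"])
    # clamp-free load: flag invalid values, then drop them to NaN so the
    # missingness machinery handles them downstream
    stations = []
    station_problems = []
    for sid, g in raw.groupby("station_id", sort=True):
        frame = (g.set_index("timestamp").sort_index()
                 [["temp_c", "rh_pct", *POLLUTANTS]].rename(columns=_RENAME_IN))
        frame.index.name = None
        rh = frame["relative_humidity"]
        bad_rh = (rh < 0) | (rh > 100)
        for ts in frame.index[bad_rh]:
            station_problems.append((str(sid), ts, "relative humidity outside [0, 100]"))
        frame.loc[bad_rh, "relative_humidity"] = np.nan
        for p in POLLUTANTS:
            neg = frame[p] < 0
            for ts in frame.index[neg]:
                station_problems.append((str(sid), ts, f"negative {p}"))
            frame.loc[neg, p] = np.nan
        stations.append(StationSeries(str(sid), float(g["lat"].iloc[0]),
                                      float(g["lon"].iloc[0]), frame))
    report = {
        "patient_problems": validate_patients(records),
        "station_problems": pd.DataFrame(
            station_problems, columns=["station_id", "timestamp", "problem"]),
    }
    return records, stations, report


def moving_average(values, window: int = 10) -> np.ndarray:
    """Centred moving average; even windows use the classical 2xm smoother
    (half weight on both end points) so the filter is exactly centred and
    reproduces linear trends at interior points.  Ends are NaN."""
    x = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 1:
        w = np.ones(window) / window
    else:
        w = np.concatenate([[0.5], np.ones(window - 1), [0.5]]) / window
    half = (len(w) - 1) // 2
    out = np.full(x.size, np.nan)
    if x.size >= len(w):
        out[half: x.size - half] = np.convolve(x, w, mode="valid")
    return out


def descriptive_summary(records: pd.DataFrame, matrices: dict,
                        ma_window: int = 10) -> dict:
    """Descriptive table over pooled case-window values plus smoothed series.

    ``matrices`` maps variable name -> ExposureMatrix of *case* rows.
    Returns ``{"table": DataFrame, "daily": DataFrame}`` where ``daily`` has
    daily case counts and the centred moving average of daily case counts.
    """
    rows = []
    for name, mat in matrices.items():
        vals = mat.Q[~mat.mask]
        qs = np.percentile(vals, [1, 25, 50, 75, 99]) if vals.size else [np.nan] * 5
        rows.append({
            "variable": name,
            "mean": float(np.mean(vals)) if vals.size else np.nan,
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            "p1": qs[0], "p25": qs[1], "p50": qs[2], "p75": qs[3], "p99": qs[4],
        })
    table = pd.DataFrame(rows)
    onset = pd.to_datetime(records["onset_time"])
    daily = onset.dt.floor("D").value_counts().sort_index()
    full_range = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    daily = daily.reindex(full_range, fill_value=0)
    daily_df = pd.DataFrame({
        "date": full_range,
        "cases": daily.to_numpy(),
        "cases_ma": moving_average(daily.to_numpy(), ma_window),
    })
    return {"table": table, "daily": daily_df}


def write_results_csv(estimates, path) -> None:
    """Tidy effects export: one row per EffectEstimate."""
    rows = []
    for item in estimates:
        if isinstance(item, tuple):
            extra, est = item[0], item[1]
        else:
            extra, est = {}, item
        d = est.to_dict()
        d.update(extra)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fit_json(result, path) -> None:
    """Serialize a pipeline result: fit, basis specs, trim bounds, counts."""
    payload = {
        "config": result.config.to_dict(),
        "config_digest": result.config.digest(),
        "fit": result.fit.to_dict(),
        "cross_bases": {
            name: {"exposure_spec": cb.exposure_spec.to_dict(),
                   "lag_spec": cb.lag_spec.to_dict(),
                   "max_lag": cb.max_lag}
            for name, cb in result.cross_bases.items()},
        "trims": {name: {"lower": t.lower, "upper": t.upper,
                         "x_ext": t.x_ext, "x_ref": t.x_ref,
                         "n_masked": t.n_masked}
                  for name, t in result.trims.items()},
        "counts": result.counts,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
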