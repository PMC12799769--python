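"""Station matching, lag matrices, trimming, pollutant windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ccdlnm.exposure import (apply_trim, build_lag_matrix, haversine_km,
                             match_station, pollutant_means, trim_extremes)
from ccdlnm.synthetic import StationSeries


def make_series(values, start="2021-06-01 00:00", name="temperature",
                station_id="S0", lat=32.0, lon=110.0):
    idx = pd.date_range(start, periods=len(values), freq="h")
    frame = pd.DataFrame({name: np.asarray(values, dtype=float)}, index=idx)
    return StationSeries(station_id, lat, lon, frame)


class TestHaversine:
    def test_identity(self):
        assert haversine_km((30.0, 110.0), (30.0, 110.0)) == 0.0

    def test_one_degree_longitude_at_equator(self):
        assert haversine_km((0, 0), (0, 1)) == \
            pytest.approx(np.pi / 180 * 6371.0, abs=1e-3)

    def test_quarter_great_circle(self):
        assert haversine_km((0, 0), (0, 90)) == \
            pytest.approx(6371.0 * np.pi / 2, abs=1e-3)

    @given(st.floats(-90, 90), st.floats(-180, 180),
           st.floats(-90, 90), st.floats(-180, 180))
    def test_symmetric_nonnegative(self, lat1, lon1, lat2, lon2):
        d = haversine_km((lat1, lon1), (lat2, lon2))
        assert d >= 0
        assert d == pytest.approx(haversine_km((lat2, lon2), (lat1, lon1)),
                                  abs=1e-9)

    def test_out_of_range_latitude_rejected(self):
        with pytest.raises(ValueError):
            haversine_km((95.0, 0.0), (0.0, 0.0))


class TestMatchStation:
    def stations(self):
        # ~0.09 deg latitude ~ 10 km; ~0.18 ~ 20 km
        return [make_series([0], station_id="B", lat=32.09, lon=110.0),
                make_series([0], station_id="A", lat=32.18, lon=110.0)]

    def record(self, lat=32.0, lon=110.0):
        return {"latitude": lat, "longitude": lon}

    def test_nearest_chosen(self):
        st_, d = match_station(self.record(), self.stations())
        assert st_.station_id == "B" and 9 < d < 11

    def test_beyond_max_distance_excluded(self):
        st_, d = match_station(self.record(lat=31.4), self.stations(), max_km=50)
        assert st_ is None and d > 50

    def test_tie_breaks_to_smallest_station_id(self):
        stations = [make_series([0], station_id="S2", lat=32.1, lon=110.0),
                    make_series([0], station_id="S1", lat=31.9, lon=110.0)]
        st_, _ = match_station(self.record(), stations)
        assert st_.station_id == "S1"

    def test_returned_distance_is_minimal(self):
        rng = np.random.default_rng(0)
        stations = [make_series([0], station_id=f"S{i}",
                                lat=float(rng.uniform(31.5, 32.5)),
                                lon=float(rng.uniform(109.5, 110.5)))
                    for i in range(8)]
        rec = self.record(32.2, 110.2)
        _, d = match_station(rec, stations, max_km=1e6)
        all_d = [haversine_km((32.2, 110.2), (s.latitude, s.longitude))
                 for s in stations]
        assert d == pytest.approx(min(all_d))


class TestBuildLagMatrix:
    def test_index_valued_series_row(self):
        series = make_series(np.arange(100))
        t = series.frame.index[40]
        m = build_lag_matrix(series, [t], "temperature", L=24)
        assert np.array_equal(m.Q[0], np.arange(40, 15, -1))
        assert not m.mask.any()

    def test_zero_lag_degenerate_window(self):
        series = make_series(np.arange(10))
        m = build_lag_matrix(series, [series.frame.index[3]], "temperature", L=0)
        assert m.Q.shape == (1, 1) and m.Q[0, 0] == 3

    def test_single_missing_hour_masks_one_cell(self):
        vals = np.arange(100.0)
        vals[35] = np.nan
        series = make_series(vals)
        m = build_lag_matrix(series, [series.frame.index[40]], "temperature", L=24)
        assert m.mask.sum() == 1 and m.mask[0, 5]

    def test_event_before_series_start_fully_masked(self):
        series = make_series(np.arange(48))
        t = series.frame.index[0] - pd.Timedelta(hours=30)
        m = build_lag_matrix(series, [t], "temperature", L=24)
        assert m.mask.all()

    def test_double_loop_reconstruction_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=200)
        series = make_series(vals)
        hours = [series.frame.index[i] for i in (30, 57, 121, 199)]
        m = build_lag_matrix(series, hours, "temperature", L=24)
        for i, t in enumerate(hours):
            for l in range(25):
                pos = series.frame.index.get_loc(t) - l
                assert m.Q[i, l] == vals[pos]


class TestTrimExtremes:
    def test_constant_pool_masks_nothing_and_contrast_errors(self):
        trim, keep = trim_extremes(np.full(500, 7.0))
        assert keep.all() and trim.n_masked == 0
        with pytest.raises(ValueError, match="degenerate"):
            trim.require_contrast()

    def test_integers_1_to_1000_enumeration(self):
        pool = np.arange(1, 1001, dtype=float)
        trim, keep = trim_extremes(pool)
        # type-7 percentiles of 1..1000
        assert trim.lower == pytest.approx(10.99)
        assert trim.upper == pytest.approx(990.01)
        # enumeration: strictly below 10.99 -> 1..10; strictly above 990.01
        # -> 991..1000
        expected_masked = int(np.sum((pool < trim.lower) | (pool > trim.upper)))
        assert expected_masked == 20
        assert trim.n_masked == expected_masked
        assert trim.x_ext == pytest.approx(np.quantile(pool[keep], 0.01))

    def test_retain_extremes_is_identity(self):
        rng = np.random.default_rng(2)
        pool = rng.normal(size=1000)
        trim, keep = trim_extremes(pool, retain_extremes=True)
        assert keep.all() and trim.n_masked == 0
        assert trim.x_ext == pytest.approx(np.quantile(pool, 0.01))
        assert trim.x_ref == pytest.approx(np.quantile(pool, 0.99))

    def test_trimming_idempotent_at_same_bounds(self):
        rng = np.random.default_rng(3)
        pool = rng.normal(size=2000)
        trim, keep = trim_extremes(pool)
        survivors = pool[keep]
        again = int(np.sum((survivors < trim.lower) | (survivors > trim.upper)))
        assert again == 0

    def test_small_pool_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            trim_extremes(np.arange(50, dtype=float))

    def test_apply_trim_masks_out_of_bounds_cells(self):
        series = make_series(np.arange(1, 1001, dtype=float))
        hours = [series.frame.index[i] for i in range(30, 990, 40)]
        m = build_lag_matrix(series, hours, "temperature", L=24)
        trim, _ = trim_extremes(np.arange(1, 1001, dtype=float))
        trimmed = apply_trim(m, trim)
        assert trimmed.mask.sum() > 0
        inside = trimmed.Q[~trimmed.mask]
        assert inside.min() >= trim.lower and inside.max() <= trim.upper


class TestPollutantMeans:
    def series_with(self, pm25):
        idx = pd.date_range("2021-06-01", periods=len(pm25), freq="h")
        frame = pd.DataFrame(
            {name: np.full(len(pm25), 1.0) for name in
             ("temperature", "relative_humidity", "pm10", "so2", "no2", "o3", "co")},
            index=idx)
        frame["pm25"] = np.asarray(pm25, dtype=float)
        return StationSeries("S0", 32.0, 110.0, frame)

    def test_constant_pollutant(self):
        series = self.series_with(np.full(60, 17.8))
        means, flagged = pollutant_means(series, [series.frame.index[40]])
        assert means[0, 0] == pytest.approx(17.8)
        assert not flagged[0]

    def test_ramp_mean(self):
        vals = np.zeros(60)
        vals[16:41] = np.arange(24, -1, -1)  # lags 0..24 hold 0..24
        series = self.series_with(vals)
        means, _ = pollutant_means(series, [series.frame.index[40]])
        assert means[0, 0] == pytest.approx(12.0)

    def test_fully_masked_window_flagged_and_undefined(self):
        vals = np.full(60, np.nan)
        series = self.series_with(vals)
        means, flagged = pollutant_means(series, [series.frame.index[40]])
        assert np.isnan(means[0, 0]) and flagged[0]
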