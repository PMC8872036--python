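"""Ambient-series drift correction, aggregation windows, ratios, profiles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from terpflux.ambient import (
    DEFAULT_WINDOWS,
    diurnal_cycle,
    drift_correct,
    enhancement_ratio,
    intercompare,
    profile_filter,
    ratio_mean,
    window_means,
)
from terpflux.synthetic import AmbientParams, gen_ambient_timeseries, gen_profile_flights


def _series(values, start="2019-06-15 00:00-09:00", freq="2h", cfc=None, compound="isoprene"):
    n = len(values)
    cfc = np.ones(n) * 1e6 if cfc is None else np.asarray(cfc, dtype=float)
    return pd.DataFrame({
        "timestamp": pd.date_range(start, periods=n, freq=freq),
        "compound": compound,
        "value_pptv": np.asarray(values, dtype=float),
        "cfc11_area": cfc,
        "cfc113_area": 0.8 * cfc,
    })


class TestDriftCorrect:
    def test_constant_areas_identity(self):
        df = _series(np.linspace(10, 50, 48))
        out = drift_correct(df)
        assert np.allclose(out["value_corrected"], out["value_pptv"], rtol=1e-12)

    def test_halved_sensitivity_doubles_values(self):
        n = 96
        cfc = np.concatenate([np.ones(n // 2), 0.5 * np.ones(n // 2)]) * 1e6
        df = _series(np.ones(n) * 20.0, cfc=cfc)
        out = drift_correct(df, smoothing_window="2h")
        # away from the step the correction is multiplicative: the second
        # half ends up exactly twice the first (reference = campaign median)
        first = out["value_corrected"].iloc[5: n // 2 - 5]
        second = out["value_corrected"].iloc[n // 2 + 5: -5]
        assert second.mean() / first.mean() == pytest.approx(2.0, rel=1e-9)
        assert first.std() == pytest.approx(0.0, abs=1e-9)

    def test_planted_linear_decay_removed(self):
        p = AmbientParams(drift_total=0.2, noise_cv=0.05, seed=10)
        df = gen_ambient_timeseries(days=30, params=p)
        acn = df[df["compound"] == "acetonitrile"]
        out = drift_correct(acn)
        x = np.arange(len(out), dtype=float)
        before = scipy.stats.linregress(x, out["value_pptv"])
        after = scipy.stats.linregress(x, out["value_corrected"])
        # the raw series trends down; the corrected series has no trend
        assert before.slope < 0
        assert before.pvalue < 1e-6
        assert abs(after.slope) <= 1.96 * after.stderr
        # corrected level sits at truth × campaign-median sensitivity
        med_sens = out["sens_factor"].median()
        assert out["value_corrected"].mean() == pytest.approx(
            p.acn_level * med_sens, rel=0.03)

    def test_nonpositive_area_flagged_not_corrected(self):
        df = _series([10.0, 20.0, 30.0])
        df.loc[1, "cfc11_area"] = 0.0
        out = drift_correct(df)
        assert bool(out.loc[1, "drift_uncorrectable"])
        assert out.loc[1, "value_corrected"] == 20.0

    def test_missing_cfc_columns_rejected(self):
        with pytest.raises(ValueError):
            drift_correct(pd.DataFrame({"timestamp": [], "value_pptv": []}))


class TestDiurnalCycle:
    def test_constant_series_flat_cycle(self):
        df = _series(np.full(48, 7.0))
        out = diurnal_cycle(df)
        assert np.allclose(out["mean"], 7.0)

    def test_planted_sinusoid_peaks_at_fourteen(self):
        ts = pd.date_range("2019-06-15 00:00-09:00", periods=240, freq="1h")
        h = ts.hour.to_numpy()
        df = pd.DataFrame({"timestamp": ts,
                           "value_pptv": 10 + 5 * np.sin(2 * np.pi * (h - 8) / 24)})
        out = diurnal_cycle(df)
        assert out.loc[out["mean"].idxmax(), "hour"] == 14

    def test_count_weighted_hourly_means_conserve_overall_mean(self):
        rng = np.random.default_rng(3)
        ts = pd.Timestamp("2019-06-15 00:00-09:00") + pd.to_timedelta(
            np.sort(rng.uniform(0, 96, 500)), unit="h")
        df = pd.DataFrame({"timestamp": ts, "value_pptv": rng.lognormal(2, 1, 500)})
        out = diurnal_cycle(df)
        weighted = (out["mean"] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(df["value_pptv"].mean(), rel=1e-12)


class TestWindowMeans:
    def test_midday_only_data(self):
        df = _series([5.0, 5.0], start="2019-06-15 12:00-09:00", freq="24h")
        df["value"] = df["value_pptv"]
        out = window_means(df, "value", temperature_col=None).set_index("window")
        assert out.loc["daytime", "n"] == 2
        assert out.loc["midday", "n"] == 2
        assert out.loc["nighttime", "n"] == 0
        assert np.isnan(out.loc["nighttime", "mean"])

    def test_nighttime_wraps_midnight(self):
        ts = pd.to_datetime(["2019-06-15 23:30-09:00", "2019-06-16 04:30-09:00",
                             "2019-06-15 22:30-09:00"])
        df = pd.DataFrame({"timestamp": ts, "value": [1.0, 1.0, 99.0]})
        out = window_means(df, "value", temperature_col=None).set_index("window")
        assert out.loc["nighttime", "n"] == 2
        assert out.loc["nighttime", "mean"] == pytest.approx(1.0)

    def test_temperature_driven_ordering_midday_daytime_nighttime(self):
        # emissions follow the diurnal temperature cycle, so midday > daytime > nighttime
        from terpflux.enclosure import emission_rates
        from terpflux.synthetic import (EnclosureScenario, GeneratorParams,
                                        gen_enclosure_timeseries)

        sc = EnclosureScenario(n_enclosures=4, duration_days=6,
                               params=GeneratorParams(noise_cv=0.1, seed=21))
        rates = emission_rates(gen_enclosure_timeseries(sc))
        iso = rates[rates["compound"] == "isoprene"]
        out = window_means(iso, "value").set_index("window")
        assert out.loc["midday", "mean"] > out.loc["daytime", "mean"]
        assert out.loc["daytime", "mean"] > out.loc["nighttime", "mean"]
        assert out.loc["midday", "t_mean"] > out.loc["nighttime", "t_mean"]

    def test_daytime_window_agrees_with_diurnal_cycle(self):
        rng = np.random.default_rng(5)
        ts = pd.date_range("2019-06-15 00:00-09:00", periods=300, freq="1h")
        df = pd.DataFrame({"timestamp": ts, "value": rng.lognormal(0, 1, 300)})
        wm = window_means(df, "value", temperature_col=None).set_index("window")
        df["value_pptv"] = df["value"]
        dc = diurnal_cycle(df).set_index("hour")
        day = dc.loc[(dc.index >= 10) & (dc.index < 20)]
        weighted = (day["mean"] * day["n"]).sum() / day["n"].sum()
        assert wm.loc["daytime", "mean"] == pytest.approx(weighted, rel=1e-12)


class TestIntercompare:
    def test_identical_series(self):
        a = _series(np.linspace(5, 50, 30))
        r = intercompare(a, a)
        assert r.slope == pytest.approx(1.0, rel=1e-12)
        assert r.pearson_r == pytest.approx(1.0, rel=1e-12)

    def test_exact_proportionality(self):
        a = _series(np.linspace(5, 50, 30))
        b = a.copy()
        b["value_pptv"] = 0.85 * a["value_pptv"]
        r = intercompare(a, b)
        assert r.slope == pytest.approx(0.85, rel=1e-12)
        assert r.intercept == pytest.approx(0.0, abs=1e-10)

    def test_noisy_proportionality_within_published_band(self):
        rng = np.random.default_rng(17)
        x = rng.lognormal(3, 0.8, 500)
        a = _series(x, freq="30min")
        b = a.copy()
        b["value_pptv"] = 0.85 * x * rng.lognormal(-0.02, 0.2, 500)
        r = intercompare(a, b)
        assert 0.7 <= r.slope <= 1.0
        assert r.pearson_r > 0.85
        assert r.n_pairs == 500

    def test_offset_series_pair_within_tolerance(self):
        a = _series(np.linspace(5, 50, 30))
        b = a.copy()
        b["timestamp"] = b["timestamp"] + pd.Timedelta("10min")
        assert intercompare(a, b, tolerance="15min").n_pairs == 30
        with pytest.raises(ValueError):
            intercompare(a, b, tolerance="1min")


class TestEnhancementRatio:
    def test_no_event_gives_unity(self):
        df = _series(np.full(48, 10.0))
        r = enhancement_ratio(df, ("2019-06-17 00:00-09:00", "2019-06-18 00:00-09:00"),
                              ("2019-06-15 00:00-09:00", "2019-06-17 00:00-09:00"))
        assert r == pytest.approx(1.0)

    def test_peak_over_background(self):
        vals = np.full(48, 24.0)
        vals[36:] = 505.0  # event in the final day
        df = _series(vals)
        r = enhancement_ratio(df, ("2019-06-18 00:00-09:00", "2019-06-19 00:00-09:00"),
                              ("2019-06-15 00:00-09:00", "2019-06-18 00:00-09:00"))
        assert r == pytest.approx(505.0 / 24.0, rel=1e-12)

    def test_planted_event_recovered_from_generator(self):
        df = gen_ambient_timeseries(days=25, params=AmbientParams(seed=13, noise_cv=0.1),
                                    event=True, event_day=20)
        acn = df[df["compound"] == "acetonitrile"]
        r = enhancement_ratio(acn, df.attrs["event_window"], df.attrs["background_window"])
        assert r == pytest.approx(4.0, rel=0.1)

    def test_overlapping_windows_rejected(self):
        df = _series(np.full(48, 10.0))
        with pytest.raises(ValueError):
            enhancement_ratio(df, ("2019-06-15 00:00-09:00", "2019-06-17 00:00-09:00"),
                              ("2019-06-16 00:00-09:00", "2019-06-18 00:00-09:00"))


class TestRatioMean:
    def _two_compounds(self, x, y):
        a = _series(x, compound="mvk")
        b = _series(y, compound="methacrolein")
        return pd.concat([a, b], ignore_index=True)

    def test_identical_series_unity(self):
        df = self._two_compounds(np.full(20, 8.0), np.full(20, 8.0))
        r, n = ratio_mean(df, "mvk", "methacrolein")
        assert r == pytest.approx(1.0)
        assert n == 20

    def test_exact_proportionality(self):
        y = np.linspace(3, 30, 20)
        df = self._two_compounds(2.7 * y, y)
        r, _ = ratio_mean(df, "mvk", "methacrolein")
        assert r == pytest.approx(2.7, rel=1e-12)

    def test_below_threshold_pairs_excluded(self):
        df = self._two_compounds(np.array([10.0, 1.0, 10.0]), np.array([5.0, 5.0, 1.0]))
        r, n = ratio_mean(df, "mvk", "methacrolein", threshold=2.0)
        assert n == 1
        assert r == pytest.approx(2.0)

    def test_noisy_planted_ratio(self):
        rng = np.random.default_rng(23)
        y = rng.lognormal(2.5, 0.3, 300)
        noise = rng.lognormal(-0.011, 0.15, 300)
        df = self._two_compounds(2.7 * y * noise, y)
        r, n = ratio_mean(df, "mvk", "methacrolein")
        assert n > 250
        # ratio-of-lognormals carries a small positive bias; tolerated
        assert r == pytest.approx(2.7, abs=0.12)

    def test_no_qualifying_pairs(self):
        df = self._two_compounds(np.full(5, 1.0), np.full(5, 1.0))
        with pytest.raises(ValueError):
            ratio_mean(df, "mvk", "methacrolein", threshold=2.0)


class TestProfileFilter:
    def test_below_blank_discarded_equal_retained(self):
        df = pd.DataFrame({
            "flight_id": ["f1"] * 3,
            "altitude_m": [0.0, 100.0, 240.0],
            "value_pptv": [10.0, 15.0, 20.0],
            "blank_pptv": [15.0, 15.0, 15.0],
        })
        out = profile_filter(df)
        assert list(out["value_pptv"]) == [15.0, 20.0]

    def test_surface_maximum_shape_preserved(self):
        df = gen_profile_flights(n_flights=5, surface_pptv=100.0, noise_cv=0.0,
                                 blank_pptv=4.0, seed=31)
        out = profile_filter(df)
        for _, flight in out.groupby("flight_id"):
            vals = flight.sort_values("altitude_m")["value_pptv"].to_numpy()
            assert np.all(np.diff(vals) < 0)
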