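"""Feature construction and random-forest weather normalization."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import airsynth as ax
from airsynth.deweather import MET_FEATURES, TIME_FEATURES


def _met_frame(index):
    rng = np.random.default_rng(0)
    data = {
        "temp": rng.normal(15, 8, len(index)),
        "rh": rng.uniform(20, 95, len(index)),
        "ws": rng.uniform(0.5, 8, len(index)),
        "wd": rng.uniform(0, 360, len(index)),
        "pressure": rng.normal(1013, 6, len(index)),
        "blh": rng.uniform(100, 1500, len(index)),
        "tcc": rng.uniform(0, 1, len(index)),
        "ssr": rng.uniform(0, 2.5e6, len(index)),
        "tp": rng.exponential(0.1, len(index)),
    }
    return pd.DataFrame(data, index=index)


class TestBuildFeatures:
    def test_calendar_identities(self):
        idx = pd.DatetimeIndex(["2015-03-05 12:00", "2021-01-01 00:00", "2021-02-12 05:00"])
        feats = ax.build_features(_met_frame(idx))
        assert feats["lunar_day_of_year"].iloc[0] == 15  # 2015 LNY: 19 Feb
        assert feats["day_of_year"].iloc[1] == 1
        assert feats["hour_of_day"].iloc[1] == 0
        assert feats["lunar_day_of_year"].iloc[2] == 1  # Lunar New Year 2021
        assert feats["day_of_week"].iloc[1] == 5  # 2021-01-01 was a Friday
        assert set(MET_FEATURES + TIME_FEATURES) <= set(feats.columns)

    def test_missing_met_rows_flagged(self):
        idx = pd.date_range("2020-01-01", periods=5, freq="h")
        met = _met_frame(idx)
        met.loc[idx[2], "blh"] = np.nan
        feats = ax.build_features(met)
        assert feats["met_complete"].tolist() == [True, True, False, True, True]

    def test_year_outside_lunar_table_raises(self):
        idx = pd.date_range("2031-06-01", periods=3, freq="h")
        with pytest.raises(ValueError, match="Lunar New Year table"):
            ax.build_features(_met_frame(idx))

    def test_unsorted_timestamps_rejected(self):
        idx = pd.DatetimeIndex(["2020-01-02", "2020-01-01"])
        with pytest.raises(ValueError, match="sorted"):
            ax.build_features(_met_frame(idx))


@pytest.fixture(scope="module")
def features():
    idx = pd.date_range("2019-01-01", periods=20_000, freq="h")
    return ax.build_features(_met_frame(idx))


class TestWeatherNormalizer:

    def test_constant_target_predicts_constant(self, features):
        y = pd.Series(5.0, index=features.index)
        with pytest.warns(UserWarning, match="correlation undefined"):
            model, metrics = ax.train_rf(
                features, y, ax.RfConfig(n_tree=10, n_resample=10, seed=0)
            )
        assert metrics.r == 0.0
        np.testing.assert_allclose(model.predict(features.iloc[:50]), 5.0)

    def test_smooth_function_of_temperature_is_learned(self, features):
        """Held-out r > 0.95 on a noiseless smooth response to one variable."""
        y = 50.0 + 20.0 * np.sin(features["temp"].to_numpy() / 10.0)
        model, metrics = ax.train_rf(
            features, pd.Series(y, index=features.index),
            ax.RfConfig(n_tree=50, n_resample=10, seed=0),
        )
        assert metrics.r > 0.95
        assert metrics.n_train + metrics.n_test == len(features)
        assert metrics.n_train == round(0.7 * len(features))

    def test_met_independent_target_unchanged_by_deweathering(self, features):
        """If the target ignores meteorology, resampling met must not matter."""
        y = 30.0 + 5.0 * np.sin(features["hour_of_day"].to_numpy() / 24 * 2 * np.pi)
        # all features per split: meteorological splits then never beat the
        # (noiseless) time signal, so predictions are truly met-independent
        model, _ = ax.train_rf(
            features, pd.Series(y, index=features.index),
            ax.RfConfig(n_tree=20, n_resample=30, seed=1),
            max_features=1.0,
        )
        subset = features.iloc[:300]
        dew = model.deweather(subset)
        plain = model.predict(subset)
        np.testing.assert_allclose(dew.to_numpy(), plain, rtol=1e-3)

    def test_resampling_noise_shrinks_like_root_n(self, features):
        """Monte-Carlo error at 50 vs 1000 draws scales roughly as 1/sqrt(n)."""
        rng_y = np.random.default_rng(3)
        y = (
            40.0
            - 8.0 * np.log(features["blh"].to_numpy() / 500.0)
            + rng_y.normal(0, 2, len(features))
        )
        model, _ = ax.train_rf(
            features, pd.Series(y, index=features.index),
            ax.RfConfig(n_tree=20, n_resample=50, seed=2),
        )
        sub = features.iloc[:400]
        d50a = model.deweather(sub, n_resample=50, seed=100)
        d50b = model.deweather(sub, n_resample=50, seed=200)
        d1000a = model.deweather(sub, n_resample=1000, seed=300)
        d1000b = model.deweather(sub, n_resample=1000, seed=400)
        mad50 = float((d50a - d50b).abs().mean())
        mad1000 = float((d1000a - d1000b).abs().mean())
        ratio = mad50 / mad1000
        expected = np.sqrt(1000 / 50)
        assert expected / 2 < ratio < expected * 2

    def test_zero_resamples_rejected(self, features):
        y = pd.Series(np.arange(len(features), dtype=float), index=features.index)
        model, _ = ax.train_rf(features, y, ax.RfConfig(n_tree=5, n_resample=5, seed=0))
        with pytest.raises(ValueError):
            model.deweather(features.iloc[:10], n_resample=0)

    def test_row_floor_enforced(self, features):
        small = features.iloc[:500]
        y = pd.Series(1.0 * np.arange(500), index=small.index)
        with pytest.raises(ValueError, match="floor"):
            ax.train_rf(small, y, ax.RfConfig(n_tree=5, n_resample=5, seed=0))

    def test_seed_determinism(self, features):
        y = pd.Series(
            np.random.default_rng(4).normal(50, 10, len(features)),
            index=features.index,
        )
        cfg = ax.RfConfig(n_tree=10, n_resample=20, seed=9)
        m1, k1 = ax.train_rf(features, y, cfg)
        m2, k2 = ax.train_rf(features, y, cfg)
        assert k1 == k2
        pd.testing.assert_series_equal(
            m1.deweather(features.iloc[:100]), m2.deweather(features.iloc[:100])
        )


class TestOnSyntheticCity:
    def test_heldout_performance_contract(self, rf_city):
        """Forests reach r > 0.7 with near-zero bias on a synthetic city."""
        m = rf_city["metrics"]
        assert m.r > 0.7
        assert abs(m.bias) < 1.0

    def test_deweathered_mean_preserves_observed_mean(self, rf_city):
        """Resampling the period's own meteorology preserves the period mean."""
        dew, obs = rf_city["deweathered"], rf_city["target"]
        assert float(dew.mean()) == pytest.approx(float(obs.mean()), rel=0.02)

    def test_deweathered_tracks_nonmet_truth_weekly(self, rf_city):
        """Weekly deweathered values follow trend+seasonal+heating truth."""
        comp = rf_city["truth"].components
        tc = comp[comp["city_id"] == "T00"].set_index("timestamp")
        ideal = tc["trend"] + tc["seasonal"] + tc["heating"]
        anchor = rf_city["calendar"].start("T00", 2015)
        wk_dew = ax.aggregate_weekly(ax.aggregate_daily(rf_city["deweathered"]), anchor)
        wk_ide = ax.aggregate_weekly(ax.aggregate_daily(ideal), anchor)
        err = (wk_dew - wk_ide).dropna()
        # correlation is the robust fidelity measure here; systematic seasonal
        # shrinkage (meteorology/season confounding) is analysed in the docs
        assert np.corrcoef(wk_dew.loc[err.index], wk_ide.loc[err.index])[0, 1] > 0.9

    def test_weather_effect_matches_true_met_component_seasonally(self, rf_city):
        """The estimated weather effect tracks the generator's met component.

        Any heating-vs-nonheating asymmetry in observed-minus-deweathered
        should reflect the true meteorological modulation, with no extra
        systematic enhancement from the normalization itself.
        """
        obs, dew = rf_city["target"], rf_city["deweathered"]
        we = ax.weather_effect(obs, dew)
        heating = rf_city["calendar"].is_heating("T00", pd.DatetimeIndex(obs.index))
        gap = float(we[heating].mean() - we[~heating].mean())
        comp = rf_city["truth"].components
        met = comp[comp["city_id"] == "T00"].set_index("timestamp")["met"]
        true_gap = float(met[heating].mean() - met[~heating].mean())
        # hourly weather effect tracks the true met component closely ...
        assert np.corrcoef(we.to_numpy(), met.to_numpy())[0, 1] > 0.85
        # ... while the seasonal gap may exceed the true one by the share of
        # season-locked emission the forest attributes to meteorology (a
        # documented limitation), but stays the right sign and magnitude
        assert 0.5 * true_gap < gap < 2.5 * true_gap


class TestWeatherEffect:
    def test_identity_gives_zero(self):
        idx = pd.date_range("2020-01-01", periods=5, freq="h")
        s = pd.Series([1.0, 2, 3, 4, 5], index=idx)
        assert (ax.weather_effect(s, s) == 0).all()

    def test_arithmetic(self):
        idx = pd.date_range("2020-01-01", periods=1, freq="h")
        out = ax.weather_effect(pd.Series([60.0], index=idx), pd.Series([50.0], index=idx))
        assert out.iloc[0] == 10.0

    def test_misaligned_rejected(self):
        a = pd.Series([1.0], index=pd.DatetimeIndex(["2020-01-01"]))
        b = pd.Series([1.0], index=pd.DatetimeIndex(["2020-01-02"]))
        with pytest.raises(ValueError, match="misaligned"):
            ax.weather_effect(a, b)
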