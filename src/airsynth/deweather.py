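"""Random-forest weather normalization ("deweathering") of pollutant series.

A regression forest is trained per city and pollutant on nine meteorological
features plus five time features (linear Unix-time trend, Gregorian day of
year, lunar day of year, day of week, hour of day). The deweathered
concentration at an hour is the average of many model predictions in which
the hour's meteorology is replaced by meteorology resampled uniformly from
the whole observation period while the time features keep their actual
values. Averaging over the period's meteorological distribution removes
weather-driven variability and leaves the emission/trend signal expressed
under period-mean meteorology.

Resampling draws whole meteorological rows (a joint block of all nine
variables) so that cross-variable structure — boundary-layer height vs
temperature, wind speed vs direction — is preserved; independent
per-variable draws would create unphysical states.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .lunar import lunar_day_of_year

__all__ = [
    "RfConfig",
    "ModelMetrics",
    "WeatherNormalizer",
    "build_features",
    "train_rf",
    "deweather",
    "weather_effect",
    "MET_FEATURES",
    "TIME_FEATURES",
]

MET_FEATURES = ["temp", "rh", "ws", "wd", "pressure", "blh", "tcc", "ssr", "tp"]
TIME_FEATURES = ["unix_trend", "day_of_year", "lunar_day_of_year", "day_of_week", "hour_of_day"]


@dataclass
class RfConfig:
    """Forest hyperparameters and resampling settings.

    ``n_tree=300`` and ``min_node_size=5`` are the standard deweathering
    choices; 70% of valid hours train the model and the held-out 30% supply
    the performance metrics; ``n_resample`` meteorological draws are averaged
    per hour.
    """

    n_tree: int = 300
    min_node_size: int = 5
    train_frac: float = 0.70
    n_resample: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tree < 1:
            raise ValueError("n_tree must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.n_resample < 1:
            raise ValueError("n_resample must be >= 1")


@dataclass
class ModelMetrics:
    """Held-out performance of one city/pollutant forest."""

    r: float
    bias: float
    rmse: float
    n_train: int
    n_test: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def build_features(
    panel: pd.DataFrame, lunar_table: dict | None = None
) -> pd.DataFrame:
    """Feature table for one city's hourly panel slice.

    Returns a frame indexed by timestamp with the nine meteorological
    columns, the five time features and a boolean ``met_complete`` flag;
    hours with any missing meteorological value are flagged (they are
    excluded from training and from the resampling pool but still receive
    deweathered predictions when possible).
    """
    if "timestamp" in panel.columns:
        ts = pd.DatetimeIndex(pd.to_datetime(panel["timestamp"]))
        met = panel[MET_FEATURES].copy()
        met.index = ts
    else:
        ts = pd.DatetimeIndex(panel.index)
        met = panel[MET_FEATURES].copy()
    if not ts.is_monotonic_increasing:
        raise ValueError("panel timestamps must be sorted")
    out = met.astype(float)
    out["unix_trend"] = ts.asi8 // 10**9
    out["day_of_year"] = ts.dayofyear
    out["lunar_day_of_year"] = lunar_day_of_year(ts, lunar_table)
    out["day_of_week"] = ts.dayofweek + 1  # 1 = Monday .. 7 = Sunday
    out["hour_of_day"] = ts.hour
    out["met_complete"] = ~met.isna().any(axis=1)
    return out


class WeatherNormalizer(RegressorMixin, BaseEstimator):
    """Random-forest deweathering model for one city/pollutant series.

    Parameters mirror :class:`RfConfig`; ``min_rows`` is the floor on valid
    training rows. ``fit`` performs the seeded 70/30 row split internally and
    stores held-out metrics, matching the deweathering workflow this class
    implements rather than the usual external cross-validation.

    Attributes
    ----------
    forest_ : RandomForestRegressor
    metrics_ : ModelMetrics
    feature_names_ : list of str
    resample_pool_ : pd.DataFrame
        Meteorology rows (complete cases) available to ``deweather``.
    """

    def __init__(
        self,
        n_tree: int = 300,
        min_node_size: int = 5,
        train_frac: float = 0.70,
        n_resample: int = 1000,
        seed: int = 0,
        min_rows: int = 1000,
        log_target: bool = False,
        max_features: float | str = 0.3333,
    ):
        self.n_tree = n_tree
        self.min_node_size = min_node_size
        self.train_frac = train_frac
        self.n_resample = n_resample
        self.seed = seed
        self.min_rows = min_rows
        self.log_target = log_target
        self.max_features = max_features

    # ------------------------------------------------------------------ fit
    def fit(self, X: pd.DataFrame, y: pd.Series) -> "WeatherNormalizer":
        cfg = RfConfig(self.n_tree, self.min_node_size, self.train_frac,
                       self.n_resample, self.seed)  # validates ranges
        X = X.copy()
        yv = np.asarray(y, dtype=float)
        if len(yv) != len(X):
            raise ValueError("X and y must align")
        met_ok = X["met_complete"].to_numpy() if "met_complete" in X else ~X[MET_FEATURES].isna().any(axis=1).to_numpy()
        valid = met_ok & ~np.isnan(yv)
        if valid.sum() < self.min_rows:
            raise ValueError(
                f"{int(valid.sum())} valid rows < required floor {self.min_rows}"
            )
        self.feature_names_ = MET_FEATURES + TIME_FEATURES
        Xv = X.loc[valid, self.feature_names_].to_numpy(dtype=np.float32)
        tv = yv[valid]
        if self.log_target:
            tv = np.log(np.maximum(tv, 1e-3))

        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        order = rng.permutation(len(tv))
        n_train = int(round(cfg.train_frac * len(tv)))
        tr, te = order[:n_train], order[n_train:]
        self.forest_ = RandomForestRegressor(
            n_estimators=cfg.n_tree,
            min_samples_leaf=cfg.min_node_size,
            max_features=self.max_features,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        self.forest_.fit(Xv[tr], tv[tr])
        pred = self.forest_.predict(Xv[te])
        obs = tv[te]
        if self.log_target:
            pred, obs = np.exp(pred), np.exp(obs)
        if np.std(obs) == 0 or np.std(pred) == 0:
            warnings.warn("constant target or prediction; correlation undefined, reported as 0")
            r = 0.0
        else:
            r = float(np.corrcoef(pred, obs)[0, 1])
        self.metrics_ = ModelMetrics(
            r=r,
            bias=float(np.mean(pred - obs)),
            rmse=float(np.sqrt(np.mean((pred - obs) ** 2))),
            n_train=len(tr),
            n_test=len(te),
        )
        self.resample_pool_ = X.loc[met_ok, MET_FEATURES].astype(np.float32)
        self._valid_mask_ = valid
        return self

    # -------------------------------------------------------------- predict
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Plain forest prediction with the hours' actual meteorology."""
        check_is_fitted(self, "forest_")
        out = self.forest_.predict(
            X[self.feature_names_].to_numpy(dtype=np.float32)
        )
        return np.exp(out) if self.log_target else out

    # ------------------------------------------------------------ deweather
    def deweather(
        self,
        X: pd.DataFrame,
        n_resample: int | None = None,
        clip: bool = True,
        seed: int | None = None,
    ) -> pd.Series:
        """Weather-normalized series over the feature table's hours.

        For each hour, ``n_resample`` meteorology rows are drawn uniformly
        with replacement from the observation period's complete-case pool
        and substituted as a joint block while the hour's time features stay
        fixed; the deweathered value is the mean prediction. Negative means
        are clipped to zero at reporting (``clip=False`` disables).
        """
        check_is_fitted(self, "forest_")
        R = self.n_resample if n_resample is None else n_resample
        if R < 1:
            raise ValueError("n_resample must be >= 1")
        pool = self.resample_pool_.to_numpy(dtype=np.float32)
        if len(pool) == 0:
            raise ValueError("no complete meteorology rows to resample from")
        Xt = X[self.feature_names_].to_numpy(dtype=np.float32)
        n = len(Xt)
        time_block = Xt[:, len(MET_FEATURES):]
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed if seed is None else seed, 202])
        )
        total = np.zeros(n, dtype=np.float64)
        # batch draws so the prediction matrix stays ~<= 1e6 rows
        batch = max(1, int(1_000_000 // max(n, 1)))
        done = 0
        while done < R:
            b = min(batch, R - done)
            idx = rng.integers(0, len(pool), size=(b, n))
            met_block = pool[idx.reshape(-1)]
            Xrep = np.empty((b * n, Xt.shape[1]), dtype=np.float32)
            Xrep[:, : len(MET_FEATURES)] = met_block
            Xrep[:, len(MET_FEATURES):] = np.tile(time_block, (b, 1))
            pred = self.forest_.predict(Xrep)
            if self.log_target:
                pred = np.exp(pred)
            total += pred.reshape(b, n).sum(axis=0)
            done += b
        values = total / R
        if clip:
            values = np.maximum(values, 0.0)
        index = (
            pd.DatetimeIndex(pd.to_datetime(X["timestamp"]))
            if "timestamp" in X
            else pd.DatetimeIndex(X.index)
        )
        return pd.Series(values, index=index, name="deweathered")


def train_rf(
    features: pd.DataFrame, target: pd.Series, cfg: RfConfig | None = None, **kw
) -> tuple[WeatherNormalizer, ModelMetrics]:
    """Fit a :class:`WeatherNormalizer` from an :class:`RfConfig`."""
    cfg = cfg or RfConfig()
    model = WeatherNormalizer(
        n_tree=cfg.n_tree,
        min_node_size=cfg.min_node_size,
        train_frac=cfg.train_frac,
        n_resample=cfg.n_resample,
        seed=cfg.seed,
        **kw,
    ).fit(features, target)
    return model, model.metrics_


def deweather(
    model: WeatherNormalizer, features: pd.DataFrame, cfg: RfConfig | None = None
) -> pd.Series:
    """Module-level wrapper over :meth:`WeatherNormalizer.deweather`."""
    n = cfg.n_resample if cfg is not None else None
    return model.deweather(features, n_resample=n)


def weather_effect(observed: pd.Series, deweathered: pd.Series) -> pd.Series:
    """Observed minus deweathered concentration (the weather contribution)."""
    if len(observed) != len(deweathered) or not observed.index.equals(
        deweathered.index
    ):
        raise ValueError("observed and deweathered series are misaligned")
    return observed - deweathered
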