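"""Tree-ensemble meta-model of the simulator.

A bagged random-forest regression predicts the annual N2O-N flux
(kg N ha-1 yr-1) from 12 site predictors — soil (clay, sand, SOC stock,
passive:total ratio, pH), nitrogen inputs (organic, mineral, atmospheric
deposition), productivity (NPP) and climate (maximum/minimum annual
temperature, annual precipitation).  Once trained on point simulations
it can be applied to gridded predictor layers, trading process detail
for speed.

Variable importance is reported as %IncMSE: the percent increase in
mean squared prediction error when one predictor's column is randomly
permuted (averaged over permutations), computed on the held-out set by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .synthgen import PREDICTORS, SoilPoint, WeatherSeries

__all__ = [
    "MetaRecord", "EmulatorReport", "RFHyper", "Emulator",
    "build_table", "split", "fit", "evaluate", "importance",
]

TARGET = "n2o"

#: MetaRecord is represented as one row of a DataFrame with these columns
MetaRecord = tuple(PREDICTORS) + (TARGET,)


@dataclass(frozen=True)
class RFHyper:
    """Random-forest hyperparameters (defaults: 500 trees, ⌊p/3⌋ features
    per split, unlimited depth)."""

    n_trees: int = 500
    max_features: float = 1.0 / 3.0
    max_depth: int | None = None
    min_samples_leaf: int = 1
    #: bagging on bootstrap resamples; disable to let fully grown trees
    #: interpolate the training set (degenerate-consistency checks)
    bootstrap: bool = True
    seed: int = 0


@dataclass
class Emulator:
    """A fitted forest plus its feature contract."""

    model: RandomForestRegressor
    features: tuple[str, ...]
    hyper: RFHyper

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in data.columns]
        if missing:
            raise ValueError(f"missing predictor column(s): {missing}")
        return self.model.predict(data[list(self.features)].to_numpy())

    def save(self, path: str) -> None:
        """Serialize the fitted forest with its feature/seed metadata."""
        import joblib

        from . import __version__
        joblib.dump({"model": self.model, "features": self.features,
                     "hyper": self.hyper, "version": __version__}, path)

    @classmethod
    def load(cls, path: str) -> "Emulator":
        import joblib

        blob = joblib.load(path)
        return cls(model=blob["model"], features=tuple(blob["features"]),
                   hyper=blob["hyper"])


@dataclass
class EmulatorReport:
    variance_explained: float                 # percent, held-out
    rmse_train: float                         # kg N ha-1 yr-1
    rmse_test: float
    importance: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.rmse_train < 0 or self.rmse_test < 0:
            raise ValueError("negative RMSE")
        missing = set(PREDICTORS) - set(self.importance)
        if self.importance and missing:
            raise ValueError(f"importance missing predictors: {sorted(missing)}")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


# ---------------------------------------------------------------------------
# Training table
# ---------------------------------------------------------------------------

def _annual_weather_stats(weather: WeatherSeries, years: np.ndarray
                          ) -> tuple[float, float, float]:
    """(MxAT, MnAT, rain): per-year max tmax / min tmin / precip total,
    averaged over the given calendar years."""
    wy = weather.dates.year.to_numpy()
    mx, mn, rain = [], [], []
    for y in years:
        sel = wy == y
        if not sel.any():
            raise ValueError(f"weather for {weather.point_id} lacks year {y}")
        mx.append(weather.tmax[sel].max())
        mn.append(weather.tmin[sel].min())
        rain.append(weather.precip[sel].sum())
    return float(np.mean(mx)), float(np.mean(mn)), float(np.mean(rain))


def build_table(points: list[SoilPoint], derived: dict, results: dict,
                weathers: dict, targets: dict | None = None) -> pd.DataFrame:
    """Assemble the 12-predictor + target training table.

    ``derived``/``results``/``weathers`` map point_id to the point's
    :class:`~soiln2o.derive.DerivedInputs`, its simulation result, and
    its weather.  ``targets`` optionally overrides the per-point target
    (canonically the Monte-Carlo ensemble mean); otherwise the
    deterministic run's mean post-spin-up annual flux is used.

    The frame also carries ``point_id``, ``lon``, ``lat``, ``region_id``
    and ``land_use`` for downstream gridding and aggregation.
    """
    rows = []
    for p in points:
        pid = p.point_id
        for name, src in (("derived", derived), ("result", results),
                          ("weather", weathers)):
            if pid not in src:
                raise ValueError(f"point {pid}: missing {name} inputs")
        d, r, w = derived[pid], results[pid], weathers[pid]
        years = r.reported_years
        mxat, mnat, rain = _annual_weather_stats(w, years)
        if targets is not None and pid in targets:
            tgt = float(targets[pid])
        else:
            tgt = float(r.reported_annual_n2o.mean())
        sched = d.schedule
        rows.append(dict(
            point_id=pid, lon=p.lon, lat=p.lat, region_id=p.region_id,
            land_use=p.land_use,
            clay=p.clay, sand=p.sand, soc_stock=d.soc_stock, ptr=d.ptr,
            ph=p.ph, n_org=sched.manure_n,
            n_min=float(np.mean(sched.mineral_n_by_year)),
            ndep=d.ndep,
            npp=float(r.annual_npp[r.spinup_years:].mean()),
            mxat=mxat, mnat=mnat, rain=rain,
            n2o=tgt,
        ))
    df = pd.DataFrame(rows)
    bad = df[list(PREDICTORS) + [TARGET]].isna()
    if bad.any().any():
        pid = df.loc[bad.any(axis=1), "point_id"].iloc[0]
        col = bad.columns[bad.any(axis=0)][0]
        raise ValueError(f"point {pid}: predictor {col!r} is missing/NaN")
    if (df[TARGET] < 0).any():
        raise ValueError("negative target flux in training table")
    return df


# ---------------------------------------------------------------------------
# Fit / evaluate
# ---------------------------------------------------------------------------

def split(records: pd.DataFrame, train_fraction: float = 0.75,
          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, disjoint, exhaustive train/test split (|train| = round(f*n))."""
    n = len(records)
    if n < 4:
        raise ValueError("need at least 4 records to split")
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return (records.iloc[perm[:n_train]].reset_index(drop=True),
            records.iloc[perm[n_train:]].reset_index(drop=True))


def fit(train: pd.DataFrame, hyper: RFHyper | None = None,
        features: tuple[str, ...] | None = None) -> Emulator:
    """Fit the bagged regression-tree ensemble on a training table.

    ``features`` defaults to the 12 canonical predictors; extra columns
    (e.g. a deliberate noise probe) can be included by naming them.
    """
    hyper = hyper or RFHyper()
    features = tuple(features) if features is not None else tuple(PREDICTORS)
    if len(train) < 2:
        raise ValueError("need at least 2 training records")
    y = train[TARGET].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("constant target: nothing to learn")
    X = train[list(features)].to_numpy()
    rf = RandomForestRegressor(
        n_estimators=hyper.n_trees, max_features=hyper.max_features,
        max_depth=hyper.max_depth, min_samples_leaf=hyper.min_samples_leaf,
        random_state=hyper.seed, n_jobs=1, bootstrap=hyper.bootstrap)
    rf.fit(X, y)
    return Emulator(model=rf, features=features, hyper=hyper)


def evaluate(model: Emulator, data: pd.DataFrame) -> tuple[float, float]:
    """(RMSE, variance explained %) of the emulator on a table.

    Variance explained = 100 * (1 - MSE / Var(target)), with the
    population (ddof=0) variance of the target.
    """
    if len(data) == 0:
        raise ValueError("empty evaluation data")
    y = data[TARGET].to_numpy()
    pred = model.predict(data)
    mse = float(np.mean((pred - y) ** 2))
    var = float(np.var(y))
    ve = 100.0 * (1.0 - mse / var) if var > 0 else float("nan")
    return float(np.sqrt(mse)), ve


def importance(model: Emulator, data: pd.DataFrame,
               n_permutations: int = 5, seed: int = 0,
               permuter=None) -> dict[str, float]:
    """%IncMSE permutation importance of every predictor.

    Each predictor column is shuffled ``n_permutations`` times (results
    averaged) and the percent increase of the mean squared prediction
    error over the unpermuted baseline is reported.  ``permuter``
    overrides the shuffling (maps (rng, n) -> index array) — mainly a
    hook for verifying that the identity permutation yields exactly 0.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 records for importance")
    rng = np.random.default_rng(seed)
    X = data[list(model.features)].to_numpy()
    y = data[TARGET].to_numpy()
    base_mse = float(np.mean((model.model.predict(X) - y) ** 2))
    if base_mse == 0.0:
        raise ValueError("baseline MSE is zero; importance undefined")
    permuter = permuter or (lambda r, n: r.permutation(n))
    out = {}
    for j, name in enumerate(model.features):
        mses = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[permuter(rng, len(y)), j]
            mses.append(np.mean((model.model.predict(Xp) - y) ** 2))
        out[name] = float(100.0 * (np.mean(mses) - base_mse) / base_mse)
    return out
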