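"""Regional upscaling, comparison statistics and CO2-equivalent accounting.

Two routes from points to regional totals:

* **direct** — the mean simulated flux of the survey points in a region
  times its agricultural area;
* **meta-model (MT1/MT2)** — the trained emulator applied per grid
  cell, averaged per region ("zonal mean"), times the same area.

The two are compared region by region with the relative deviation

    Var_n = (MT_n - LCS_n) / LCS_n * 100   [%]

where MT_n is the regional mean of emulator pixels and LCS_n the
regional mean of simulated point fluxes.  Regions are classified by
|Var| against a +/-20% inner and +/-50% outer band.

Unit chain: kg N2O-N ha-1 yr-1 x ha -> kg yr-1 -> Tg yr-1 (1e9 kg);
CO2-equivalents via N2O mass (x44/28) times a 100-year GWP of 265.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emulate import Emulator
from .synthgen import PREDICTORS, GridSet

__all__ = [
    "RegionalEstimate", "RegionalComparison", "YieldValidation",
    "predict_grid", "zonal_mean", "direct_total", "var_statistic",
    "classify_var", "to_co2eq", "yield_compare",
    "N2O_N_TO_N2O", "DEFAULT_GWP",
]

N2O_N_TO_N2O = 44.0 / 28.0
DEFAULT_GWP = 265.0
KG_PER_TG = 1e9


@dataclass(frozen=True)
class RegionalEstimate:
    region_id: str
    mean_rate: float          # kg N2O-N ha-1 yr-1
    agri_area: float          # ha
    total_n2o_n: float        # Tg N yr-1
    total_co2eq: float        # Tg CO2eq yr-1
    method: str               # 'direct' | 'MT1' | 'MT2'

    def validate(self) -> None:
        expect = self.mean_rate * self.agri_area / KG_PER_TG
        if abs(self.total_n2o_n - expect) > 1e-9 * max(abs(expect), 1e-30):
            raise ValueError("total inconsistent with rate x area")
        if self.total_n2o_n < 0:
            raise ValueError("negative total")


@dataclass(frozen=True)
class RegionalComparison:
    region_id: str
    mt_mean: float            # regional emulator mean, kg N ha-1 yr-1
    lcs_mean: float           # regional simulated-point mean
    var_pct: float


@dataclass
class YieldValidation:
    rmse: float               # Mg C ha-1, overall
    mae: float
    per_crop: pd.DataFrame = field(repr=False, default=None)

    def validate(self) -> None:
        if not 0 <= self.mae <= self.rmse:
            raise ValueError("need 0 <= MAE <= RMSE")


# ---------------------------------------------------------------------------
# Grid application
# ---------------------------------------------------------------------------

def predict_grid(model: Emulator, grids: GridSet) -> np.ndarray:
    """Per-cell emulator prediction (kg N ha-1 yr-1); NaN outside the mask."""
    missing = [p for p in model.features if p not in grids]
    if missing:
        raise ValueError(f"grid set lacks predictor layer(s): {missing}")
    shape = grids.shape
    for name in model.features:
        if grids[name].values.shape != shape:
            raise ValueError(
                f"misaligned grids: {name} has shape "
                f"{grids[name].values.shape}, expected {shape}")
    stack = np.stack([grids[p].values.ravel() for p in model.features], axis=1)
    codes = grids.region_codes.ravel()
    valid = (codes >= 0) & np.isfinite(stack).all(axis=1)
    out = np.full(shape[0] * shape[1], np.nan)
    if valid.any():
        out[valid] = model.model.predict(stack[valid])
    return out.reshape(shape)


def zonal_mean(flux: np.ndarray, region_codes: np.ndarray,
               region_index: tuple[str, ...]) -> dict[str, float]:
    """Arithmetic mean of non-masked cells per region.

    Regions with zero valid cells are absent from the result (missing,
    not zero).
    """
    if flux.shape != region_codes.shape:
        raise ValueError(
            f"shape mismatch: flux {flux.shape} vs regions {region_codes.shape}")
    out: dict[str, float] = {}
    valid = np.isfinite(flux) & (region_codes >= 0)
    codes = region_codes[valid]
    vals = flux[valid]
    sums = np.bincount(codes, weights=vals, minlength=len(region_index))
    cnts = np.bincount(codes, minlength=len(region_index))
    for i, rid in enumerate(region_index):
        if cnts[i] > 0:
            out[rid] = float(sums[i] / cnts[i])
    return out


# ---------------------------------------------------------------------------
# Direct (area-based) upscaling
# ---------------------------------------------------------------------------

def direct_total(point_fluxes: pd.DataFrame, region_areas: dict[str, float],
                 method: str = "direct",
                 ) -> tuple[dict[str, RegionalEstimate], float, list[str]]:
    """Regional mean point flux times agricultural area.

    ``point_fluxes`` needs columns ``region_id`` and ``n2o``.  Returns
    (per-region estimates, overall total in Tg N2O-N yr-1, list of
    regions excluded for having no points).
    """
    for rid, area in region_areas.items():
        if area < 0:
            raise ValueError(f"negative area for region {rid}")
    means = point_fluxes.groupby("region_id")["n2o"].mean()
    estimates: dict[str, RegionalEstimate] = {}
    excluded = []
    for rid, area in region_areas.items():
        if rid not in means.index:
            excluded.append(rid)
            continue
        rate = float(means.loc[rid])
        total = rate * area / KG_PER_TG
        est = RegionalEstimate(region_id=rid, mean_rate=rate, agri_area=area,
                               total_n2o_n=total,
                               total_co2eq=to_co2eq(total),
                               method=method)
        est.validate()
        estimates[rid] = est
    eu_total = float(sum(e.total_n2o_n for e in estimates.values()))
    return estimates, eu_total, excluded


def regional_totals_from_rates(rates: dict[str, float],
                               region_areas: dict[str, float],
                               method: str,
                               ) -> tuple[dict[str, RegionalEstimate], float]:
    """Totals for emulator-derived regional mean rates (MT1/MT2 route)."""
    estimates = {}
    for rid, rate in rates.items():
        if rid not in region_areas:
            continue
        area = region_areas[rid]
        total = rate * area / KG_PER_TG
        est = RegionalEstimate(region_id=rid, mean_rate=float(rate),
                               agri_area=area, total_n2o_n=total,
                               total_co2eq=to_co2eq(total), method=method)
        est.validate()
        estimates[rid] = est
    return estimates, float(sum(e.total_n2o_n for e in estimates.values()))


# ---------------------------------------------------------------------------
# Comparison statistics
# ---------------------------------------------------------------------------

def var_statistic(mt_mean: float, lcs_mean: float) -> float:
    """Percent deviation of the emulator regional mean from the
    simulated-point regional mean: (MT - LCS) / LCS * 100."""
    if lcs_mean <= 0:
        raise ValueError("lcs_mean must be positive")
    return (mt_mean - lcs_mean) / lcs_mean * 100.0


def compare_regions(mt_means: dict[str, float], lcs_means: dict[str, float]
                    ) -> list[RegionalComparison]:
    """Var statistic for every region present in both inputs with a
    positive point mean; others are dropped (never imputed)."""
    out = []
    for rid in sorted(set(mt_means) & set(lcs_means)):
        if lcs_means[rid] <= 0:
            continue
        out.append(RegionalComparison(
            region_id=rid, mt_mean=float(mt_means[rid]),
            lcs_mean=float(lcs_means[rid]),
            var_pct=var_statistic(mt_means[rid], lcs_means[rid])))
    return out


def classify_var(comparisons: list[RegionalComparison],
                 inner_band: float = 20.0, outer_band: float = 50.0) -> dict:
    """Partition regions by |Var|: within the inner band, outside it,
    and (subset) beyond the outer band; flags the outer offenders."""
    var = np.array([c.var_pct for c in comparisons])
    if var.size and not np.isfinite(var).all():
        raise ValueError("non-finite Var values")
    outside = np.abs(var) > inner_band
    beyond = np.abs(var) > outer_band
    return {
        "total": len(comparisons),
        "within": int((~outside).sum()),
        "outside_inner": int(outside.sum()),
        "beyond_outer": int(beyond.sum()),
        "flagged": [c.region_id for c, b in zip(comparisons, beyond) if b],
    }


# ---------------------------------------------------------------------------
# CO2-equivalent accounting
# ---------------------------------------------------------------------------

def to_co2eq(n2o_n_mass: float, gwp: float = DEFAULT_GWP) -> float:
    """CO2-equivalent mass of an N2O-N mass (units preserved).

    N2O-N -> N2O by the molar-mass ratio 44/28, then times the global
    warming potential (default 265, 100-year horizon).
    """
    if gwp <= 0:
        raise ValueError("gwp must be positive")
    if np.any(np.asarray(n2o_n_mass) < 0):
        raise ValueError("mass must be >= 0")
    return n2o_n_mass * N2O_N_TO_N2O * gwp


# ---------------------------------------------------------------------------
# Yield validation
# ---------------------------------------------------------------------------

def yield_compare(simulated: pd.DataFrame, reported: pd.DataFrame,
                  moisture: dict[str, float],
                  carbon_fraction: float = 0.45) -> YieldValidation:
    """RMSE/MAE of simulated vs reported regional yields, in Mg C ha-1.

    ``simulated`` carries (region_id, crop, yield_c) in carbon units;
    ``reported`` carries (region_id, crop, fresh_yield) in fresh mass.
    Reported yields are converted to dry matter via crop moisture and
    then to carbon (x ``carbon_fraction``) before comparison.
    """
    rep = reported.copy()
    rep["yield_ref"] = [
        row.fresh_yield * (1.0 - moisture[row.crop]) * carbon_fraction
        for row in rep.itertuples()]
    m = simulated.merge(rep[["region_id", "crop", "yield_ref"]],
                        on=["region_id", "crop"], how="inner")
    if len(m) == 0:
        raise ValueError("no matched (region, crop) pairs")
    resid = m["yield_c"].to_numpy() - m["yield_ref"].to_numpy()
    per_crop = (m.assign(abs_err=np.abs(resid), sq_err=resid ** 2)
                 .groupby("crop")
                 .agg(n_regions=("region_id", "nunique"),
                      mae=("abs_err", "mean"),
                      mse=("sq_err", "mean"))
                 .assign(rmse=lambda d: np.sqrt(d.pop("mse"))))
    val = YieldValidation(rmse=float(np.sqrt(np.mean(resid ** 2))),
                          mae=float(np.mean(np.abs(resid))),
                          per_crop=per_crop.reset_index())
    val.validate()
    return val
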