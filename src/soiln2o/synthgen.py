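"""Synthetic soil-survey world: points, weather, regional statistics, predictor grids.

This module stands in for the real data sources a continental N2O
assessment would use — a topsoil point survey, official agricultural
statistics, gridded daily weather and deposition fields, and two
alternative gridded soil-property products.  Every generator is seeded
and byte-reproducible, and each emulates the statistical structure the
downstream stages rely on: right-skewed SOC with a configurable
organic-soil tail, texture triplets summing to 100, regionally
structured fertilizer and climate, and a paired grid variant (MT2) that
differs from the base variant (MT1) only in the SOC-stock and clay
layers by a configurable multiplicative bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.stats import norm

from .params import ARABLE_CROPS, ConfigError, GeneratorConfig, RegionDef

__all__ = [
    "SoilPoint", "WeatherSeries", "RegionStats", "PredictorGrid", "GridSet",
    "gen_points", "gen_weather", "gen_region_stats", "gen_predictor_grids",
    "points_to_frame", "frame_to_points",
]

LAND_USES = ("arable", "grassland")

#: canonical emulator predictor names (also the grid layer names)
PREDICTORS = ("clay", "sand", "soc_stock", "ptr", "ph", "n_org", "n_min",
              "ndep", "npp", "mxat", "mnat", "rain")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoilPoint:
    """One surveyed location (topsoil 0-20 cm)."""

    point_id: str
    lon: float
    lat: float
    land_use: str            # 'arable' | 'grassland'
    clay: float              # percent
    silt: float
    sand: float
    rv: float                # coarse fragments, percent by volume
    soc: float               # organic C, g kg-1
    ph: float
    region_id: str
    country_id: str

    def validate(self) -> None:
        if self.land_use not in LAND_USES:
            raise ValueError(f"{self.point_id}: land_use {self.land_use!r}")
        if abs(self.clay + self.silt + self.sand - 100.0) > 1e-9:
            raise ValueError(f"{self.point_id}: texture does not sum to 100")
        if not 0.0 <= self.rv < 100.0:
            raise ValueError(f"{self.point_id}: rv outside [0, 100)")
        if self.soc <= 0:
            raise ValueError(f"{self.point_id}: non-positive SOC")
        if not 3.0 <= self.ph <= 10.0:
            raise ValueError(f"{self.point_id}: pH outside [3, 10]")


@dataclass
class WeatherSeries:
    """Daily forcing for one point: tmax/tmin (deg C) and precipitation (mm)."""

    point_id: str
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    tmin: np.ndarray
    precip: np.ndarray

    def validate(self) -> None:
        n = len(self.dates)
        if not (len(self.tmax) == len(self.tmin) == len(self.precip) == n):
            raise ValueError("weather arrays have inconsistent lengths")
        full = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        if len(full) != n or not (self.dates == full).all():
            missing = full.difference(self.dates)
            raise ValueError(f"weather has missing days: {list(missing[:5])}...")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin on some days")
        if np.any(self.precip < 0):
            raise ValueError("negative precipitation")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "tmax": self.tmax,
                             "tmin": self.tmin, "precip": self.precip})


@dataclass(frozen=True)
class RegionStats:
    """Regional agricultural statistics (crop shares, livestock, areas, N)."""

    region_id: str
    country_id: str
    crop_shares: dict[str, float]
    livestock_density: float      # LSU ha-1
    irrigated_share: float        # fraction
    agri_area: float              # ha
    national_mineral_n: float     # kg N yr-1, whole parent country
    ndep_wet: float               # kg N ha-1 yr-1
    ndep_dry: float

    def validate(self) -> None:
        s = sum(self.crop_shares.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"{self.region_id}: crop shares sum to {s}")
        for name in ("livestock_density", "irrigated_share", "agri_area",
                     "national_mineral_n", "ndep_wet", "ndep_dry"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.region_id}: negative {name}")


@dataclass
class PredictorGrid:
    """One gridded predictor layer plus the shared region-ID raster.

    North-up, row-major; the cell value applies to the whole cell.
    ``region_codes`` holds an integer index into ``region_index`` per
    cell, with -1 marking cells outside the agricultural mask.
    """

    name: str
    values: np.ndarray            # 2-D float
    cellsize: float               # degrees
    origin: tuple[float, float]   # (lon, lat) of the lower-left corner
    region_codes: np.ndarray      # 2-D int, -1 = masked
    region_index: tuple[str, ...]
    variant: str                  # 'MT1' | 'MT2'

    def __post_init__(self) -> None:
        if self.values.shape != self.region_codes.shape:
            raise ValueError("values and region raster shapes differ")


@dataclass
class GridSet:
    """A complete, aligned set of predictor layers for one variant."""

    layers: dict[str, PredictorGrid] = field(default_factory=dict)
    variant: str = "MT1"

    def __getitem__(self, name: str) -> PredictorGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).values.shape

    @property
    def region_codes(self) -> np.ndarray:
        return next(iter(self.layers.values())).region_codes

    @property
    def region_index(self) -> tuple[str, ...]:
        return next(iter(self.layers.values())).region_index


# ---------------------------------------------------------------------------
# Point generator
# ---------------------------------------------------------------------------

def _soc_median_scale(cfg: GeneratorConfig) -> float:
    """Common multiplier on both land-use SOC medians so that the cohort
    exceedance P(SOC > threshold) equals cfg.soc_exceed_frac exactly."""
    w_g = cfg.grassland_share
    thr = cfg.soc_exclude_threshold

    def exceed(m: float) -> float:
        p_a = norm.sf(np.log(thr / (m * cfg.soc_median_arable))
                      / cfg.soc_sigma_arable)
        p_g = norm.sf(np.log(thr / (m * cfg.soc_median_grassland))
                      / cfg.soc_sigma_grassland)
        return (1.0 - w_g) * p_a + w_g * p_g

    target = cfg.soc_exceed_frac
    if target <= 0.0:
        return 1.0
    return brentq(lambda m: exceed(m) - target, 1e-6, 1e6, xtol=1e-12)


def gen_points(n: int, seed: int, cfg: GeneratorConfig | None = None) -> list[SoilPoint]:
    """Draw ``n`` synthetic survey points.

    Regions are sampled uniformly; within a region, coordinates are
    uniform over its box.  SOC is log-normal per land use with the
    medians rescaled to hit the configured exceedance of the 200 g kg-1
    organic-soil threshold; texture triplets come from a Dirichlet
    centred on the regional mean and sum to 100 exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    regions = cfg.regions
    ridx = rng.integers(0, len(regions), size=n)
    is_grass = rng.random(n) < cfg.grassland_share
    m = _soc_median_scale(cfg)

    lon = np.empty(n)
    lat = np.empty(n)
    tex = np.empty((n, 3))
    for i, r in enumerate(regions):
        sel = ridx == i
        k = int(sel.sum())
        if k == 0:
            continue
        lon[sel] = rng.uniform(r.lon_min, r.lon_max, k)
        lat[sel] = rng.uniform(r.lat_min, r.lat_max, k)
        alpha = np.asarray(r.texture_mean) / 100.0 * cfg.texture_concentration
        tex[sel] = rng.dirichlet(alpha, size=k) * 100.0
    # close the triplet exactly (Dirichlet*100 is already ~exact; force it)
    tex[:, 1] = 100.0 - tex[:, 0] - tex[:, 2]

    sigma = np.where(is_grass, cfg.soc_sigma_grassland, cfg.soc_sigma_arable)
    median = m * np.where(is_grass, cfg.soc_median_grassland,
                          cfg.soc_median_arable)
    soc = median * np.exp(sigma * rng.standard_normal(n))
    ph = np.clip(rng.normal(cfg.ph_mean, cfg.ph_sd, n), 3.0, 10.0)
    rv = rng.beta(cfg.rv_beta_a, cfg.rv_beta_b, n) * cfg.rv_max

    pts = []
    for i in range(n):
        r = regions[ridx[i]]
        pts.append(SoilPoint(
            point_id=f"P{i:06d}",
            lon=float(lon[i]), lat=float(lat[i]),
            land_use="grassland" if is_grass[i] else "arable",
            clay=float(tex[i, 0]), silt=float(tex[i, 1]), sand=float(tex[i, 2]),
            rv=float(rv[i]), soc=float(soc[i]), ph=float(ph[i]),
            region_id=r.region_id, country_id=r.country_id,
        ))
    return pts


def points_to_frame(points: list[SoilPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])


def frame_to_points(df: pd.DataFrame) -> list[SoilPoint]:
    cols = [f for f in SoilPoint.__dataclass_fields__]
    return [SoilPoint(**row) for row in df[cols].to_dict("records")]


# ---------------------------------------------------------------------------
# Weather generator
# ---------------------------------------------------------------------------

def _region_of(cfg: GeneratorConfig, region_id: str) -> RegionDef:
    for r in cfg.regions:
        if r.region_id == region_id:
            return r
    raise KeyError(f"unknown region {region_id!r}")


def gen_weather(point: SoilPoint, start_year: int, n_years: int, seed: int,
                cfg: GeneratorConfig | None = None) -> WeatherSeries:
    """Daily weather for one point.

    Temperature: latitude-dependent annual mean plus a sinusoidal
    seasonal cycle (warmest mid-July) plus white noise on the daily
    midpoint; tmax/tmin straddle the midpoint by the configured diurnal
    range, so tmax >= tmin holds by construction.  Precipitation is a
    Bernoulli wet-day process with exponential intensities whose mean is
    set by the regional annual-precipitation target.
    """
    if n_years < 2:
        raise ValueError(
            "n_years must be >= 2: one spin-up year plus at least one "
            "reporting year")
    cfg = cfg or GeneratorConfig()
    region = _region_of(cfg, point.region_id)
    rng = np.random.default_rng(seed)

    dates = pd.date_range(f"{start_year}-01-01",
                          f"{start_year + n_years - 1}-12-31", freq="D")
    doy = dates.day_of_year.to_numpy(dtype=float)
    t_annual = cfg.temp_at_lat0 - cfg.temp_lapse * point.lat
    tmid = (t_annual
            + cfg.seasonal_amplitude * np.cos(2 * np.pi * (doy - 196) / 365.25)
            + cfg.temp_noise_sd * rng.standard_normal(len(dates)))
    half = cfg.diurnal_range / 2.0
    tmax = tmid + half
    tmin = tmid - half

    p_wet = cfg.wet_day_frac
    mean_intensity = region.annual_precip / (365.25 * p_wet)
    wet = rng.random(len(dates)) < p_wet
    precip = np.where(wet, rng.exponential(mean_intensity, len(dates)), 0.0)

    ws = WeatherSeries(point.point_id, dates, tmax, tmin, precip)
    ws.validate()
    return ws


# ---------------------------------------------------------------------------
# Regional statistics generator
# ---------------------------------------------------------------------------

def gen_region_stats(region_ids: list[str], seed: int,
                     cfg: GeneratorConfig | None = None) -> dict[str, RegionStats]:
    """Synthetic agricultural statistics per region.

    National mineral-N totals are computed from the summed agricultural
    area of each country at the configured per-hectare intensity, so the
    same national figure is shared by (and consistent across) all
    regions of one country.
    """
    if not region_ids:
        raise ConfigError("region_ids: at least one region required")
    cfg = cfg or GeneratorConfig()
    if not cfg.crops:
        raise ConfigError("crops: empty crop list")
    rng = np.random.default_rng(seed)
    known = {r.region_id: r for r in cfg.regions}

    rows: dict[str, dict] = {}
    for rid in region_ids:
        country = known[rid].country_id if rid in known else rid
        shares = rng.dirichlet(np.full(len(cfg.crops),
                                       cfg.crop_share_concentration))
        # exact normalization to 1 within 1e-9 (Dirichlet is exact up to fp)
        shares = shares / shares.sum()
        rows[rid] = dict(
            country_id=country,
            crop_shares=dict(zip(cfg.crops, shares.tolist())),
            livestock_density=float(rng.uniform(0.0, cfg.livestock_max)),
            irrigated_share=float(rng.beta(cfg.irrigated_beta_a,
                                           cfg.irrigated_beta_b)),
            agri_area=float(rng.uniform(cfg.agri_area_min, cfg.agri_area_max)),
            ndep_wet=float(rng.uniform(*cfg.ndep_wet_range)),
            ndep_dry=float(rng.uniform(*cfg.ndep_dry_range)),
        )

    national_area: dict[str, float] = {}
    for rid, row in rows.items():
        national_area.setdefault(row["country_id"], 0.0)
        national_area[row["country_id"]] += row["agri_area"]

    out = {}
    for rid, row in rows.items():
        country = row["country_id"]
        nat_n = cfg.mineral_n_per_ha * national_area[country]
        st = RegionStats(region_id=rid, national_mineral_n=nat_n, **row)
        st.validate()
        out[rid] = st
    return out


# ---------------------------------------------------------------------------
# Predictor-grid generator
# ---------------------------------------------------------------------------

def gen_predictor_grids(table: pd.DataFrame, variant: str,
                        shape: tuple[int, int], seed: int,
                        bias_cfg: dict[str, float] | None = None,
                        noise_sd: float = 0.0,
                        cfg: GeneratorConfig | None = None,
                        n_neighbors: int = 8) -> GridSet:
    """Interpolate per-point predictor values onto a regional raster.

    ``table`` must carry ``lon``, ``lat``, ``region_id`` and the 12
    predictor columns.  Fields are inverse-distance-weighted from the
    ``n_neighbors`` nearest points, plus optional white noise scaled by
    ``noise_sd`` times the field's point-level standard deviation.

    The MT2 variant reuses the MT1 field (identical seed stream) and
    rescales the layers named in ``bias_cfg`` (canonically ``soc_stock``
    and ``clay``) by their multiplicative bias — emulating substitution
    of an alternative gridded soil product.
    """
    if variant not in ("MT1", "MT2"):
        raise ValueError(f"variant must be 'MT1' or 'MT2', got {variant!r}")
    missing = [c for c in PREDICTORS if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks predictor column(s): {missing}")
    cfg = cfg or GeneratorConfig()
    bias_cfg = dict(bias_cfg or {})
    bad = set(bias_cfg) - set(PREDICTORS)
    if bad:
        raise ValueError(f"bias_cfg names unknown layer(s): {sorted(bad)}")

    nrows, ncols = shape
    lon_min = min(r.lon_min for r in cfg.regions)
    lon_max = max(r.lon_max for r in cfg.regions)
    lat_min = min(r.lat_min for r in cfg.regions)
    lat_max = max(r.lat_max for r in cfg.regions)
    cellsize = max((lon_max - lon_min) / ncols, (lat_max - lat_min) / nrows)
    xs = lon_min + (np.arange(ncols) + 0.5) * cellsize
    ys = lat_max - (np.arange(nrows) + 0.5) * cellsize   # north-up
    gx, gy = np.meshgrid(xs, ys)

    region_index = tuple(r.region_id for r in cfg.regions)
    codes = np.full(shape, -1, dtype=np.int64)
    for i, r in enumerate(cfg.regions):
        inside = ((gx >= r.lon_min) & (gx < r.lon_max)
                  & (gy >= r.lat_min) & (gy < r.lat_max))
        codes[inside] = i

    pts_xy = table[["lon", "lat"]].to_numpy()
    k = min(n_neighbors, len(table))
    tree = cKDTree(pts_xy)
    dist, idx = tree.query(np.column_stack([gx.ravel(), gy.ravel()]), k=k)
    dist = np.atleast_2d(dist.reshape(-1, k))
    idx = idx.reshape(-1, k)
    w = 1.0 / (dist ** 2 + 1e-12)
    w /= w.sum(axis=1, keepdims=True)

    rng = np.random.default_rng(seed)    # same stream for MT1 and MT2
    gs = GridSet(variant=variant)
    for name in PREDICTORS:
        v = table[name].to_numpy(dtype=float)
        fld = (w * v[idx]).sum(axis=1).reshape(shape)
        if noise_sd > 0:
            fld = fld + rng.normal(0.0, noise_sd * v.std(), size=shape)
            if name in ("soc_stock", "clay", "rain", "n_org", "n_min",
                        "ndep", "npp", "ptr"):
                fld = np.maximum(fld, 0.0)
        if variant == "MT2" and name in bias_cfg:
            fld = fld * bias_cfg[name]
        fld = np.where(codes >= 0, fld, np.nan)
        gs.layers[name] = PredictorGrid(
            name=name, values=fld, cellsize=cellsize,
            origin=(lon_min, lat_max - nrows * cellsize),
            region_codes=codes, region_index=region_index, variant=variant)
    return gs


# ---------------------------------------------------------------------------
# Plain-text grid I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: PredictorGrid, path: str) -> None:
    nrows, ncols = grid.values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]}\nyllcorner {grid.origin[1]}\n")
        fh.write(f"cellsize {grid.cellsize}\nNODATA_value -9999\n")
        vals = np.where(np.isnan(grid.values), -9999.0, grid.values)
        np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path: str) -> tuple[np.ndarray, float, tuple[float, float]]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            k, v = fh.readline().split()
            header[k.lower()] = float(v)
        vals = np.loadtxt(fh)
    vals = np.where(vals == header["nodata_value"], np.nan, vals)
    return vals, header["cellsize"], (header["xllcorner"], header["yllcorner"])
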