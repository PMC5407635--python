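"""From survey points to simulator-ready inputs.

Covers the preprocessing chain of the point-scale assessment: exclusion
of organic soils (SOC > 20% by mass), hydraulic pedotransfer with stone
correction, bulk density and SOC-stock computation, regional crop
rotations and manure from agricultural statistics, and mass-conserving
partitioning of national mineral-N consumption onto points.

Pedotransfer forms: a Saxton-Rawls-type texture+organic-matter
regression for water retention and saturated conductivity, and an
Adams-type organic/mineral mixing rule for bulk density.  Coefficients
are configuration (``SimParams``), not constants of the science.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .params import (ARABLE_CROPS, GRASS, ConfigError, CropParams, SimParams,
                     default_crop_table)
from .synthgen import RegionStats, SoilPoint

__all__ = [
    "HydraulicProperties", "ManagementSchedule", "DerivedInputs",
    "filter_by_soc", "hydraulic_ptf", "stone_correct", "bulk_density_ptf",
    "soc_stock", "build_schedule", "partition_fertilizer", "derive_point",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydraulicProperties:
    """Volumetric water-retention points, conductivity and bulk density."""

    field_capacity: float      # volumetric fraction
    wilting_point: float       # volumetric fraction
    ksat: float                # cm day-1
    bulk_density: float        # g cm-3
    particle_density: float = 2.65

    @property
    def porosity(self) -> float:
        return 1.0 - self.bulk_density / self.particle_density

    def validate(self) -> None:
        if not 0.0 < self.wilting_point < self.field_capacity:
            raise ValueError("need 0 < wilting_point < field_capacity")
        if not self.field_capacity < self.porosity <= 1.0:
            raise ValueError("need field_capacity < porosity <= 1")
        if self.ksat <= 0:
            raise ValueError("ksat must be positive")
        if not 0.5 <= self.bulk_density <= 2.2:
            raise ValueError("bulk density outside [0.5, 2.2]")


@dataclass(frozen=True)
class ManagementSchedule:
    """Per-point management: rotation, N inputs, tillage and irrigation.

    ``rotation`` holds one crop per simulation year (permanent grass for
    grassland points).  ``mineral_n_by_year`` carries the annual mineral
    N allocation (kg N ha-1) for the matching rotation year; at run time
    each year's allocation is split over exactly two events (planting
    and mid-vegetative stage).  Arable years receive a primary
    (mouldboard) tillage before planting and a secondary one at
    planting.
    """

    point_id: str
    rotation: tuple[str, ...]
    mineral_n_by_year: tuple[float, ...]
    manure_n: float              # kg N ha-1 yr-1
    irrigated: bool

    def validate(self, calendar: dict[str, CropParams] | None = None) -> None:
        if len(self.rotation) != len(self.mineral_n_by_year):
            raise ValueError("rotation and mineral N allocations differ in length")
        if any(v < 0 for v in self.mineral_n_by_year):
            raise ValueError("negative mineral N allocation")
        if self.manure_n < 0:
            raise ValueError("negative manure N")
        cal = calendar or default_crop_table()
        for crop in self.rotation:
            if crop not in cal:
                raise ConfigError(f"crop {crop!r} missing from the crop calendar")


@dataclass(frozen=True)
class DerivedInputs:
    """Everything the simulator needs for one point."""

    point_id: str
    hydraulics: HydraulicProperties     # stone-corrected retention
    soc_stock: float                    # Mg C ha-1
    ptr: float                          # passive:total SOC ratio
    ndep: float                         # kg N ha-1 yr-1 (wet + dry)
    schedule: ManagementSchedule
    rv: float = 0.0

    def validate(self) -> None:
        if not 0.0 < self.ptr < 1.0:
            raise ValueError("ptr must lie in (0, 1)")
        if self.soc_stock <= 0:
            raise ValueError("soc_stock must be positive")
        self.hydraulics.validate()
        self.schedule.validate()


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_by_soc(points: list[SoilPoint], threshold: float = 200.0
                  ) -> tuple[list[SoilPoint], list[SoilPoint]]:
    """Split a cohort into (kept, removed) at an organic-C threshold.

    Process models parameterised for mineral soils behave poorly on
    organic soils, so points above ``threshold`` g C kg-1 (default 200,
    i.e. 20% SOC by mass) are excluded from simulation.  Order is
    preserved in both outputs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kept = [p for p in points if p.soc <= threshold]
    removed = [p for p in points if p.soc > threshold]
    return kept, removed


# ---------------------------------------------------------------------------
# Pedotransfer
# ---------------------------------------------------------------------------

def _om_percent(soc: float, params: SimParams) -> float:
    return soc / 10.0 * params.om_factor


def hydraulic_ptf(clay: float, sand: float, soc: float,
                  params: SimParams | None = None) -> HydraulicProperties:
    """Water retention and conductivity from texture and organic carbon.

    Saxton-Rawls-type regressions on clay/sand fractions and organic
    matter (OM clamped to the regression's calibration range for the
    retention terms).  Returns *uncorrected* (stone-free) properties;
    apply :func:`stone_correct` for stony soils.
    """
    params = params or SimParams()
    silt = 100.0 - clay - sand
    if not (0 <= clay <= 100 and 0 <= sand <= 100 and -1e-9 <= silt <= 100):
        raise ValueError("texture triplet does not sum to 100")
    if soc <= 0:
        raise ValueError("soc must be positive")
    C, S = clay / 100.0, sand / 100.0
    om = float(np.clip(_om_percent(soc, params), 0.1, 8.0))

    t1500 = (-0.024 * S + 0.487 * C + 0.006 * om + 0.005 * S * om
             - 0.013 * C * om + 0.068 * C * S + 0.031)
    wp = t1500 + (0.14 * t1500 - 0.02)

    t33 = (-0.251 * S + 0.195 * C + 0.011 * om + 0.006 * S * om
           - 0.027 * C * om + 0.452 * C * S + 0.299)
    fc = t33 + (1.283 * t33 ** 2 - 0.374 * t33 - 0.015)

    ts33 = (0.278 * S + 0.034 * C + 0.022 * om - 0.018 * S * om
            - 0.027 * C * om - 0.584 * C * S + 0.078)
    th_s33 = ts33 + (0.636 * ts33 - 0.107)
    theta_s = fc + th_s33 - 0.097 * S + 0.043

    bd = bulk_density_ptf(soc, clay, sand, params)
    porosity = 1.0 - bd / params.particle_density

    # keep the retention points physically ordered inside the pore space
    wp = float(np.clip(wp, 0.005, None))
    fc = float(np.clip(fc, wp + 0.005, porosity - 0.02))
    wp = float(np.clip(wp, 0.004, fc - 0.004))

    lam = (np.log(fc) - np.log(wp)) / (np.log(1500.0) - np.log(33.0))
    ksat_mmh = 1930.0 * max(theta_s - fc, 0.01) ** (3.0 - lam)
    ksat = float(ksat_mmh * 2.4)    # mm h-1 -> cm day-1

    hp = HydraulicProperties(field_capacity=fc, wilting_point=wp,
                             ksat=ksat, bulk_density=bd,
                             particle_density=params.particle_density)
    hp.validate()
    return hp


def stone_correct(value, rv):
    """Reduce a volumetric property for coarse-fragment content.

    ``value * (1 - Rv/100)`` with Rv the rock-fragment percent by
    volume.  Works elementwise on arrays.
    """
    rv = np.asarray(rv, dtype=float)
    if np.any((rv < 0) | (rv >= 100)):
        raise ValueError("rv must lie in [0, 100)")
    out = np.asarray(value, dtype=float) * (1.0 - rv / 100.0)
    return float(out) if out.ndim == 0 else out


def bulk_density_ptf(soc: float, clay: float, sand: float,
                     params: SimParams | None = None) -> float:
    """Bulk density (g cm-3) from organic matter and texture.

    Organic/mineral mixing: the soil is treated as OM (packing density
    ``bd_om``) blended with mineral matter whose packing density rises
    with sand.  Strictly decreasing in SOC; clamped to [0.5, 2.2] with a
    log warning outside the physical range.
    """
    params = params or SimParams()
    if soc <= 0:
        raise ValueError("soc must be positive")
    om = _om_percent(soc, params)
    om = min(om, 100.0)
    bd_min = params.bd_mineral_base + params.bd_mineral_sand_coeff * sand
    bd = 100.0 / (om / params.bd_om + (100.0 - om) / bd_min)
    if not 0.5 <= bd <= 2.2:
        log.warning("bulk density %.3f clamped to [0.5, 2.2] (soc=%.1f)", bd, soc)
        bd = float(np.clip(bd, 0.5, 2.2))
    return float(bd)


def soc_stock(soc: float, bd: float, depth: float = 20.0, rv: float = 0.0) -> float:
    """Topsoil organic-carbon stock, Mg C ha-1.

    soc [g kg-1] x bulk density [g cm-3] x depth [cm], stone-corrected;
    the factor 100 converts (g C / cm2-column equivalents) to Mg ha-1.
    """
    if soc < 0 or bd <= 0 or depth <= 0:
        raise ValueError("soc, bd and depth must be positive")
    if not 0 <= rv < 100:
        raise ValueError("rv must lie in [0, 100)")
    return soc / 1000.0 * bd * depth * (1.0 - rv / 100.0) * 100.0


# ---------------------------------------------------------------------------
# Management
# ---------------------------------------------------------------------------

def build_schedule(point: SoilPoint, region_stats: RegionStats,
                   crop_calendar: dict[str, CropParams], seed: int,
                   n_years: int = 6,
                   params: SimParams | None = None) -> ManagementSchedule:
    """Sample a management schedule for one point.

    Arable rotations draw each year's crop from the regional crop
    shares; grassland points get permanent grass.  Manure N scales with
    regional livestock density; the irrigation flag is sampled from the
    regional irrigated share (arable only).  Mineral-N allocations start
    at zero and are filled by :func:`partition_fertilizer`.
    """
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    if point.land_use == "grassland":
        rotation = (GRASS,) * n_years
        irrigated = False
    else:
        crops = list(region_stats.crop_shares)
        for crop in crops:
            if crop not in crop_calendar:
                raise ConfigError(f"crop {crop!r} missing from the crop calendar")
        shares = np.array([region_stats.crop_shares[c] for c in crops])
        rotation = tuple(rng.choice(crops, size=n_years, p=shares / shares.sum()))
        irrigated = bool(rng.random() < region_stats.irrigated_share)
    if GRASS not in crop_calendar:
        raise ConfigError(f"crop {GRASS!r} missing from the crop calendar")
    manure = region_stats.livestock_density * params.manure_n_per_lsu
    sched = ManagementSchedule(
        point_id=point.point_id, rotation=rotation,
        mineral_n_by_year=(0.0,) * n_years, manure_n=float(manure),
        irrigated=irrigated)
    sched.validate(crop_calendar)
    return sched


def _rotation_requirement(sched: ManagementSchedule,
                          requirements: dict[str, float],
                          grassland_req: float) -> float:
    """Mean annual agronomic N requirement of a rotation, kg N ha-1."""
    reqs = []
    for crop in sched.rotation:
        if crop == GRASS:
            reqs.append(grassland_req)
        elif crop in requirements:
            reqs.append(requirements[crop])
        else:
            raise ConfigError(f"crop {crop!r} missing from the requirements table")
    return float(np.mean(reqs))


def partition_fertilizer(national_total: float,
                         points: list[SoilPoint],
                         schedules: dict[str, ManagementSchedule],
                         areas: dict[str, float],
                         requirements: dict[str, float],
                         grassland_req: float = 80.0,
                         ) -> dict[str, ManagementSchedule]:
    """Distribute a national mineral-N total over points, conserving mass.

    Each point represents ``areas[point_id]`` hectares.  Its annual rate
    is proportional to the agronomic requirement of that year's crop,
    with a single national scale factor chosen so that
    sum_p area_p * mean_year(rate_p) == national_total.

    Returns new schedules with ``mineral_n_by_year`` filled in.
    """
    if national_total < 0:
        raise ValueError("national_total must be >= 0")
    if any(v < 0 for v in requirements.values()):
        raise ValueError("requirements must be >= 0")
    demand = 0.0
    for p in points:
        demand += areas[p.point_id] * _rotation_requirement(
            schedules[p.point_id], requirements, grassland_req)
    if demand <= 0:
        if national_total > 0:
            raise ValueError(
                "total agronomic requirement is zero but national mineral N "
                "is positive: nothing to partition onto")
        scale = 0.0
    else:
        scale = national_total / demand

    out = {}
    for p in points:
        sched = schedules[p.point_id]
        rates = tuple(
            scale * areas[p.point_id]
            * (grassland_req if c == GRASS else requirements[c])
            / areas[p.point_id]
            for c in sched.rotation)
        out[p.point_id] = replace(sched, mineral_n_by_year=rates)
    return out


def default_requirements(calendar: dict[str, CropParams] | None = None
                         ) -> dict[str, float]:
    cal = calendar or default_crop_table()
    return {c: cal[c].n_req for c in cal if c != GRASS}


# ---------------------------------------------------------------------------
# Convenience: full derivation for one point
# ---------------------------------------------------------------------------

def derive_point(point: SoilPoint, region_stats: RegionStats,
                 schedule: ManagementSchedule,
                 params: SimParams | None = None,
                 ptr: float | None = None) -> DerivedInputs:
    """Assemble the complete simulator input record for one point."""
    params = params or SimParams()
    hp = hydraulic_ptf(point.clay, point.sand, point.soc, params)
    hp_corr = HydraulicProperties(
        field_capacity=stone_correct(hp.field_capacity, point.rv),
        wilting_point=stone_correct(hp.wilting_point, point.rv),
        ksat=hp.ksat,
        bulk_density=hp.bulk_density,
        particle_density=hp.particle_density)
    stock = soc_stock(point.soc, hp.bulk_density, depth=20.0, rv=point.rv)
    di = DerivedInputs(
        point_id=point.point_id, hydraulics=hp_corr, soc_stock=stock,
        ptr=params.ptr_default if ptr is None else ptr,
        ndep=region_stats.ndep_wet + region_stats.ndep_dry,
        schedule=schedule, rv=point.rv)
    return di
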