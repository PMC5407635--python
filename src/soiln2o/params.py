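"""Configuration objects: cohort generator settings, crop tables, simulator parameters.

Everything a user might legitimately retune lives here — pedotransfer
coefficients, soil-process rate constants and response-curve shapes,
crop calendars and nitrogen requirements, and the statistical targets of
the synthetic cohort generator.  All containers are plain dataclasses
convertible to/from dicts so they round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """A generator or simulator configuration field is invalid."""


# ---------------------------------------------------------------------------
# Crops
# ---------------------------------------------------------------------------

#: The arable crops the simulator supports (plus permanent grassland).
ARABLE_CROPS = (
    "winter_barley", "spring_barley", "winter_wheat", "spring_wheat",
    "forage_maize", "grain_maize", "oilseed_rape", "potato", "sugar_beet",
    "soybean", "sunflower", "pulses", "cotton",
)

GRASS = "grass"

N_FIXING_CROPS = frozenset({"soybean", "pulses"})


@dataclass(frozen=True)
class CropParams:
    """Agronomic parameters of one crop.

    plant_doy / harvest_doy : calendar window (day of year)
    n_req                   : agronomic mineral-N requirement, kg N ha-1
    pot_production          : potential above-ground production, Mg C ha-1 yr-1
    harvest_index           : fraction of standing biomass C removed at harvest
    plant_cn                : C:N mass ratio of new biomass
    fixation                : symbiotic N fixation, kg N ha-1 per growing day
    moisture                : fresh-yield moisture fraction (reporting only)
    base_temp               : growth base temperature, deg C
    gdd_maturity            : growing-degree-days to maturity
    """

    plant_doy: int
    harvest_doy: int
    n_req: float
    pot_production: float
    harvest_index: float
    plant_cn: float
    fixation: float
    moisture: float
    base_temp: float = 5.0
    gdd_maturity: float = 1400.0


def default_crop_table() -> dict[str, CropParams]:
    t = {
        "winter_barley": CropParams(288, 182, 110.0, 9.6, 0.50, 30.0, 0.0, 0.14, 0.0, 1300),
        "spring_barley": CropParams(85, 215, 90.0, 8.6, 0.50, 30.0, 0.0, 0.14, 2.0, 1200),
        "winter_wheat": CropParams(290, 200, 150.0, 10.8, 0.45, 30.0, 0.0, 0.14, 0.0, 1500),
        "spring_wheat": CropParams(90, 230, 120.0, 9.6, 0.45, 30.0, 0.0, 0.14, 2.0, 1350),
        "forage_maize": CropParams(120, 270, 160.0, 15.6, 0.80, 35.0, 0.0, 0.65, 8.0, 1500),
        "grain_maize": CropParams(115, 290, 170.0, 14.4, 0.50, 35.0, 0.0, 0.14, 8.0, 1700),
        "oilseed_rape": CropParams(240, 195, 160.0, 9.1, 0.35, 28.0, 0.0, 0.09, 0.0, 1400),
        "potato": CropParams(105, 260, 140.0, 10.8, 0.75, 25.0, 0.0, 0.78, 4.0, 1300),
        "sugar_beet": CropParams(95, 285, 120.0, 14.4, 0.70, 25.0, 0.0, 0.77, 3.0, 1600),
        "soybean": CropParams(130, 280, 20.0, 8.4, 0.40, 18.0, 1.2, 0.13, 8.0, 1450),
        "sunflower": CropParams(110, 265, 70.0, 7.7, 0.35, 28.0, 0.0, 0.09, 6.0, 1400),
        "pulses": CropParams(80, 220, 10.0, 6.7, 0.45, 16.0, 0.9, 0.14, 3.0, 1250),
        "cotton": CropParams(115, 300, 130.0, 7.2, 0.35, 28.0, 0.0, 0.10, 12.0, 1900),
        # Permanent grassland: "plant"/"harvest" bracket the growth season;
        # biomass is cut twice a year inside the simulator.
        GRASS: CropParams(60, 300, 60.0, 12.0, 0.60, 22.0, 0.0, 0.80, 4.0, 3000),
    }
    return t


# ---------------------------------------------------------------------------
# Synthetic-cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionDef:
    """A rectangular NUTS2-like region of one country."""

    region_id: str
    country_id: str
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    #: mean annual precipitation target, mm yr-1
    annual_precip: float = 700.0
    #: mean clay/silt/sand of the regional texture distribution (percent)
    texture_mean: tuple[float, float, float] = (22.0, 38.0, 40.0)


def _default_regions() -> tuple[RegionDef, ...]:
    regions = []
    lat0 = 37.0
    for ci in range(3):
        for ri in range(4):
            k = ci * 4 + ri
            lat = lat0 + 2.0 * k
            precip = 450.0 + 45.0 * k           # drier south, wetter north
            clay = 30.0 - 1.2 * k
            sand = 30.0 + 1.5 * k
            silt = 100.0 - clay - sand
            regions.append(RegionDef(
                region_id=f"C{ci + 1}R{ri + 1}",
                country_id=f"C{ci + 1}",
                lon_min=4.0 * ci, lon_max=4.0 * ci + 4.0,
                lat_min=lat, lat_max=lat + 2.0,
                annual_precip=precip,
                texture_mean=(clay, silt, sand),
            ))
    return tuple(regions)


@dataclass
class GeneratorConfig:
    """Statistical targets of the synthetic soil-survey world.

    SOC at points is log-normal per land use (grassland richer than
    arable), with both medians rescaled by a common factor so that the
    cohort-level probability of exceeding ``soc_exclude_threshold``
    equals ``soc_exceed_frac`` (the organic-soil tail that the pipeline
    later filters out; default 1.1%).
    """

    regions: tuple[RegionDef, ...] = field(default_factory=_default_regions)
    #: fraction of points under grassland (the rest arable)
    grassland_share: float = 0.30
    #: log-normal SOC: base medians (g kg-1) and log-sd per land use
    soc_median_arable: float = 16.0
    soc_median_grassland: float = 32.0
    soc_sigma_arable: float = 0.60
    soc_sigma_grassland: float = 0.90
    #: target P(SOC > threshold) over the cohort
    soc_exceed_frac: float = 0.011
    soc_exclude_threshold: float = 200.0
    #: Dirichlet concentration for texture triplets (higher = tighter)
    texture_concentration: float = 60.0
    #: pH ~ Normal(mean, sd), clipped to [3, 10]
    ph_mean: float = 6.3
    ph_sd: float = 0.9
    #: coarse fragments Rv ~ Beta(a, b) * rv_max (percent by volume)
    rv_beta_a: float = 1.3
    rv_beta_b: float = 6.0
    rv_max: float = 60.0
    #: allowed crops and the Dirichlet concentration of regional shares
    crops: tuple[str, ...] = ARABLE_CROPS
    crop_share_concentration: float = 2.0
    #: livestock density range, LSU ha-1
    livestock_max: float = 1.8
    #: irrigated-share Beta parameters
    irrigated_beta_a: float = 1.0
    irrigated_beta_b: float = 6.0
    #: regional agricultural area range, ha
    agri_area_min: float = 2e5
    agri_area_max: float = 1.5e6
    #: national mineral-N intensity, kg N per agricultural ha
    mineral_n_per_ha: float = 75.0
    #: N deposition ranges, kg N ha-1 yr-1
    ndep_wet_range: tuple[float, float] = (2.0, 9.0)
    ndep_dry_range: tuple[float, float] = (1.0, 6.0)

    # --- weather ---
    #: coefficients of the latitude lapse: mean annual T = t_at_0 - lapse*lat
    temp_at_lat0: float = 32.0
    temp_lapse: float = 0.45
    seasonal_amplitude: float = 9.0
    diurnal_range: float = 9.0
    temp_noise_sd: float = 2.5
    wet_day_frac: float = 0.33

    def __post_init__(self) -> None:
        if not self.regions:
            raise ConfigError("regions: at least one region required")
        if not 0.0 <= self.grassland_share <= 1.0:
            raise ConfigError("grassland_share: must lie in [0, 1]")
        for name in ("soc_median_arable", "soc_median_grassland",
                     "soc_sigma_arable", "soc_sigma_grassland",
                     "texture_concentration", "ph_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")
        if not 0.0 <= self.soc_exceed_frac < 0.5:
            raise ConfigError("soc_exceed_frac: must lie in [0, 0.5)")
        if not self.crops:
            raise ConfigError("crops: the allowed-crop list is empty")
        unknown = set(self.crops) - set(ARABLE_CROPS)
        if unknown:
            raise ConfigError(f"crops: unknown crop(s) {sorted(unknown)}")

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]


# ---------------------------------------------------------------------------
# Simulator parameters
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Rate constants and response-curve coefficients of the soil core.

    Layers: four topsoil layers over 0-20 cm; water cascades top-down
    (tipping bucket) and drains below the profile, carrying nitrate.
    SOM: three pools (active/slow/passive) with first-order turnover,
    temperature (Q10-style) and moisture modifiers, texture-dependent
    stabilization of the active-pool outflow.
    """

    # --- geometry ---
    layer_thickness_cm: tuple[float, ...] = (5.0, 5.0, 5.0, 5.0)
    particle_density: float = 2.65          # g cm-3

    # --- hydrology ---
    #: fraction of profile water transpirable per day at full demand
    et_coeff: float = 0.22
    pet_temp_coeff: float = 0.16            # mm day-1 per deg C above 0
    pet_base: float = 0.5                   # mm day-1
    irrigation_trigger: float = 0.55        # trigger when water < x*FC
    irrigation_amount: float = 12.0         # mm per event
    leach_eff: float = 0.3                  # NO3 mobility in drainage water

    # --- soil temperature ---
    tsoil_smoothing: float = 0.15           # day-1 relaxation toward air T

    # --- SOM pools: daily base turnover rates ---
    k_active: float = 7.0 / 365.0
    k_slow: float = 0.20 / 365.0
    k_passive: float = 0.0045 / 365.0
    #: respired CO2 fraction of each pool's outflow
    resp_frac_active: float = 0.60
    resp_frac_slow: float = 0.55
    resp_frac_passive: float = 0.55
    #: clay stabilization: fraction of non-respired active outflow diverted
    #: straight to the passive pool, clay_coeff * clay% (capped at 0.4)
    stab_clay_coeff: float = 0.004
    #: slow-pool outflow split to passive
    slow_to_passive: float = 0.08
    #: fixed pool C:N ratios
    cn_active: float = 8.0
    cn_slow: float = 12.0
    cn_passive: float = 10.0
    #: litter/residue split into active vs slow
    litter_to_active: float = 0.45

    # --- temperature / moisture response ---
    q10: float = 2.0
    t_ref: float = 20.0                      # deg C
    t_min_process: float = -2.0              # hard off below this soil T

    # --- nitrification ---
    k_nit: float = 0.10                      # day-1 of NH4 at optimum
    nit_wfps_opt: float = 0.55
    nit_wfps_width: float = 0.28
    nit_n2o_frac: float = 0.010              # N2O-N fraction of nitrified N
    nit_nox_frac: float = 0.01               # NOx-N fraction
    ph_half: float = 6.0                     # nitrification pH response midpoint
    ph_slope: float = 1.2

    # --- denitrification ---
    denit_wfps_threshold: float = 0.60
    denit_wfps_steep: float = 22.0
    k_denit: float = 0.08                    # day-1 of NO3 at full response
    #: labile-C half-saturation, expressed on daily heterotrophic CO2
    #: (kg C ha-1 day-1)
    denit_c_half: float = 18.0
    #: N2O fraction of denitrified N declines with WFPS (more complete
    #: reduction to N2 in wetter soil) and rises with NO3 availability
    denit_n2o_frac_max: float = 0.55
    denit_n2o_wfps_coeff: float = 1.6
    denit_no3_half: float = 18.0             # kg N ha-1

    # --- plants ---
    uptake_frac: float = 0.30                # day-1 of mineral N accessible
    growth_t_opt: float = 22.0
    growth_t_width: float = 14.0
    grass_cut_doys: tuple[int, ...] = (150, 230)
    grass_cut_frac: float = 0.55
    #: fraction of harvested-crop residue returned to litter
    #: (1 - harvest_index of biomass is residue; all residue returned)
    #: manure C:N ratio for organic fertilizer carbon input
    manure_cn: float = 15.0
    #: manure N per livestock unit, kg N LSU-1 yr-1 applied
    manure_n_per_lsu: float = 85.0
    #: grassland mineral-N requirement, kg N ha-1 yr-1
    grassland_n_req: float = 80.0

    # --- tillage ---
    till_slow_to_active: float = 0.02        # fraction of slow pool mixed per event
    till_decomp_boost: float = 1.25          # multiplier for 30 days after event

    # --- pedotransfer coefficients ---
    #: organic-matter conversion: OM% = soc(g/kg)/10 * om_factor
    om_factor: float = 1.724
    #: Adams-style bulk density mixing: BD = 100/(OM%/bd_om + (100-OM%)/bd_min)
    bd_om: float = 0.224
    bd_mineral_base: float = 1.45
    bd_mineral_sand_coeff: float = 0.005

    #: passive:total SOC ratio default
    ptr_default: float = 0.45

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimParams":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown simulator parameter(s): {sorted(bad)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
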