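"""Central configuration for the agrocycle pipeline.

Every effect size, emission factor, price and noise scale used by the
pipeline lives here, so that nothing downstream is hard-coded.  The
defaults describe a temperate western-European arable region (annual mean
temperature 11 °C, 837 mm rainfall) and three 8-year circularity
scenarios: a business-as-usual cash-crop rotation (BAU), a stockless
Vegan rotation, and an integrated crop-livestock system (ICLS) with
2.5 years of mown temporary pasture feeding sheep.

Values that could not be sourced from published tables (per-crop baseline
yields, cereal-unit coefficients, prices, fixed costs, dietary kcal
conversions) are plausible regional defaults, not measured values; they
are marked ``# plausible regional default`` below and discussed in
docs/methods.md.

A configuration is a plain nested dict.  :func:`default_config` builds the
defaults; :func:`load_config` merges a YAML file over them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

# Crop codes used throughout: WW winter wheat, SB sugar beet, PT potato,
# MZ grain maize, PE pea, FB faba bean, RS winter rapeseed, GR temporary
# pasture (grass), plus "cover" for catch crops flagged on a season.
CROPS = ("WW", "SB", "PT", "MZ", "PE", "FB", "RS", "GR")

WINTER_CROPS = frozenset({"WW", "RS"})
SPRING_CROPS = frozenset({"SB", "PT", "MZ", "PE", "FB"})
PASTURE_CROPS = frozenset({"GR"})
LEGUMES = frozenset({"PE", "FB"})

ROTATION_NAMES = ("BAU", "Vegan", "ICLS")

RESIDUE_FATES = ("incorporated", "removed_exchange", "removed_feed")


@dataclass(frozen=True)
class ClimateScenarioSpec:
    """One climate forcing: a warming offset plus a replication stream.

    ``esm_label`` selects an independent noise stream (the analogue of
    running distinct Earth-system models); it does not change the
    climatology.
    """

    name: str
    warming_offset: float  # °C above the historical baseline
    co2_ppm: float
    esm_label: str

    def __post_init__(self) -> None:
        if self.warming_offset not in (0, 2, 3, 4):
            raise ValueError(
                f"warming_offset must be one of 0/2/3/4, got {self.warming_offset}"
            )


@dataclass(frozen=True)
class SiteSpec:
    """A simulation location with its soil state and leaching propensity."""

    uid: int
    soc0_topsoil: float  # Mg C ha-1, 0-30 cm
    soc0_profile: float  # Mg C ha-1, 0-200 cm
    leach_propensity: float  # dimensionless >= 0, mean 1 across sites

    def __post_init__(self) -> None:
        if not (self.soc0_profile >= self.soc0_topsoil > 0):
            raise ValueError("require soc0_profile >= soc0_topsoil > 0")
        if self.leach_propensity < 0:
            raise ValueError("leach_propensity must be >= 0")


#: Default atmospheric CO2 per warming offset (ppm).
CO2_PPM = {0: 410.0, 2: 475.0, 3: 627.0, 4: 1006.0}


def default_scenarios() -> list[ClimateScenarioSpec]:
    """Historical baseline plus three warming levels x three noise streams."""
    out = [ClimateScenarioSpec("historical", 0, CO2_PPM[0], "ERA5")]
    for off in (2, 3, 4):
        for esm in ("MPI", "CMCC", "MIR"):
            out.append(
                ClimateScenarioSpec(f"+{off}C_{esm}", off, CO2_PPM[off], esm)
            )
    return out


def scenario_by_name(name: str, config: dict | None = None) -> ClimateScenarioSpec:
    for sc in default_scenarios():
        if sc.name == name:
            return sc
    raise KeyError(f"unknown climate scenario {name!r}")


def default_config() -> dict[str, Any]:
    """Build the full default configuration tree."""
    cfg: dict[str, Any] = {}

    cfg["weather"] = {
        "latitude_deg": 50.5,
        "mean_temp_c": 11.0,  # annual mean temperature
        "temp_seasonal_amplitude": 7.5,
        "temp_noise_sd": 2.6,
        "temp_ar1": 0.72,
        "diurnal_range_mean": 8.0,
        "diurnal_range_amplitude": 2.0,
        "annual_precip_mm": 837.0,  # annual rainfall target
        "wet_day_prob": 0.5,  # frequent, light rainfall
        "precip_gamma_shape": 0.75,
        # Seasonal precipitation multipliers at +4 °C, interpolated
        # linearly in the warming offset: drier summers, wetter winters
        # and springs, annual totals roughly unchanged.
        "precip_mult_at_4C": {"DJF": 1.15, "MAM": 1.15, "JJA": 0.80, "SON": 1.00},
    }

    cfg["sites"] = {
        "soc0_topsoil_mean": 78.0,  # Mg C ha-1, regional average 0-30 cm
        "soc0_topsoil_sd": 15.0,
        "soc0_topsoil_min": 25.0,
        "profile_ratio_mean": 2.3,  # SOC(0-200) / SOC(0-30)
        "profile_ratio_sd": 0.2,
        "profile_ratio_min": 1.05,
        "leach_propensity_cv": 0.3,
    }

    # plausible regional defaults (fresh mass for roots/tubers, DM for
    # grains and forage); supplementary yield tables are not reprinted here.
    cfg["crops"] = {
        "WW": {"base_yield": 8.5, "cv": 0.15},
        "SB": {"base_yield": 80.0, "cv": 0.15},
        "PT": {"base_yield": 45.0, "cv": 0.15},
        "MZ": {"base_yield": 10.0, "cv": 0.15},
        "PE": {"base_yield": 4.5, "cv": 0.15},
        "FB": {"base_yield": 4.0, "cv": 0.15},
        "RS": {"base_yield": 4.0, "cv": 0.15},
        "GR": {"base_yield": 6.0, "cv": 0.10},  # hay, relatively stable
    }
    cfg["cover_biomass"] = 1.8  # Mg DM ha-1 catch-crop biomass
    cfg["cover_biomass_cv"] = 0.20

    # Mean relative yield change vs historical per warming offset.  The
    # +4 °C column encodes the target changes recovered by the pipeline's
    # yield-evolution estimator (sugar beet +70 %, maize +19 %, potato
    # +21 %, rapeseed +28 %, wheat +3 %, pea -1 %, faba bean -44 %).
    cfg["yield_warming_mult"] = {
        "WW": {2: 0.97, 3: 1.00, 4: 1.03},
        "SB": {2: 1.20, 3: 1.45, 4: 1.70},
        "PT": {2: 0.98, 3: 1.10, 4: 1.21},
        "MZ": {2: 1.05, 3: 1.12, 4: 1.19},
        "PE": {2: 0.95, 3: 0.97, 4: 0.99},
        "FB": {2: 0.80, 3: 0.68, 4: 0.56},
        "RS": {2: 0.95, 3: 1.10, 4: 1.28},
        "GR": {2: 1.00, 3: 1.02, 4: 1.05},
    }

    # Wheat-year coupling to the standardized March-May water balance z:
    # yields are depressed by k_wet * (z - z0) for z > z0 (wet extremes)
    # and mildly boosted by k_dry * (-z - z0) for z < -z0.  ICLS is the
    # least wet-sensitive rotation.
    cfg["wet_coupling"] = {
        "z0": 0.6,
        "k_wet": {"BAU": 0.30, "Vegan": 0.22, "ICLS": 0.14},
        "k_dry": 0.03,
        "floor": 0.10,
    }

    cfg["leaching"] = {
        "base": 4.5,  # kg NO3-N ha-1 yr-1, regional historical mean
        "lognorm_sigma": 0.35,
        # historical rotation multipliers average to 1 so the regional
        # mean stays at the 4.5 kg baseline
        "rotation_mult": {"BAU": 1.30, "Vegan": 1.15, "ICLS": 0.55},
        "warming_mult": {
            "BAU": {2: 1.10, 3: 1.20, 4: 1.30},
            "Vegan": {2: 1.50, 3: 2.10, 4: 2.90},
            "ICLS": {2: 1.10, 3: 1.15, 4: 1.20},
        },
    }

    cfg["n2o"] = {
        "base": 0.6,  # kg N2O-N ha-1 yr-1 background
        "ef_applied": 0.010,  # per kg fertilizer+manure N
        "ef_residue": 0.012,  # per kg residue N incorporated
        "lognorm_sigma": 0.25,
        "warming_factor_per_degC": 1.04,
    }

    # Annual SOC stock change (Mg C ha-1 yr-1).  Topsoil trends are
    # negative everywhere; subsoil gains (mineralization below 30 cm
    # negligible) make the ICLS the only profile-positive rotation.
    cfg["soc"] = {
        "topsoil_trend": {"BAU": -0.23, "Vegan": -0.12, "ICLS": -0.05},
        "subsoil_gain": {"BAU": 0.08, "Vegan": 0.17, "ICLS": 0.35},
        "warming_penalty_per_degC": 0.04,
        "sd_topsoil": 0.12,
        "sd_subsoil": 0.05,
    }

    # kg N ha-1 residue N returned when residues are incorporated
    cfg["residue_n"] = {
        "WW": 25.0, "SB": 80.0, "PT": 30.0, "MZ": 40.0,
        "PE": 30.0, "FB": 35.0, "RS": 25.0, "GR": 0.0,
    }
    cfg["cover_residue_n"] = 20.0

    cfg["livestock"] = {
        # Tier-1-style sheep and solid-storage defaults; non-measured
        "fcr": 6.0,  # kg DM intake per kg live weight gain
        "dressing": 0.48,
        "retail_fraction": 0.75,
        "ch4_yield": 0.0219,  # kg CH4 per kg DM intake
        "feed_n_frac": 0.025,  # kg N per kg DM intake
        "n_retention": 0.10,  # fraction of ingested N retained in LWG
        "vs_per_dmi": 0.30,  # kg volatile solids excreted per kg DMI
        "b0": 0.19,  # m3 CH4 per kg VS
        "ch4_density": 0.67,  # kg CH4 per m3
        "mcf_storage": 0.02,
        "ef_n2o_direct": 0.005,  # kg N2O-N per kg manure N stored
        "frac_volatilized": 0.12,
        "ef_n2o_indirect": 0.01,
        "ef_ch4_spreading": 0.01,  # kg CH4 per kg VS applied to the field
        "utilization": 0.60,  # fraction of harvested forage ingested
        "manure_vs_per_n": 30.0,  # kg VS per kg N in imported farmyard manure
    }

    cfg["ghg"] = {
        "gwp100_ch4": 27.2,
        "gwp100_n2o": 273.0,
        "gwpstar": {"r": 0.75, "s": 0.25, "H": 100.0, "dt": 20},
        "ef_leach_n2o": 0.0075,  # fraction of leached N emitted as N2O-N
        "ef_fert_n2o": 0.0010,  # fraction of applied fertilizer N
        "fuel_l": {"combine": 20.5, "plough": 27.6, "surface_tillage": 5.6},
        "fuel_c_per_l": 0.81,  # kg C per litre
        "c_to_co2_fuel": 3.67,  # printed conversion for fuel C
        "fert_co2": 6.17,  # kg CO2-eq per kg N synthesized
    }

    cfg["spei"] = {
        "window": 3,
        "classification_month": 5,  # SPEI-3 dated May = March-May window
        "quantiles": [0.1, 0.25, 0.75, 0.9],
    }

    # plausible regional defaults: cereal units per Mg product, producer
    # prices (EUR per Mg, 2018-2022 era) and fixed costs (EUR per ha)
    cfg["value_tables"] = {
        "cu": {
            "WW": 1.04, "SB": 0.26, "PT": 0.22, "MZ": 1.03,
            "PE": 1.07, "FB": 1.05, "RS": 1.30, "GR": 0.55, "meat": 4.0,
        },
        "price": {
            "WW": 210.0, "SB": 35.0, "PT": 180.0, "MZ": 200.0,
            "PE": 250.0, "FB": 260.0, "RS": 450.0, "GR": 120.0,
            "meat": 5000.0,
        },
        "fixed_cost": {
            "WW": 800.0, "SB": 1800.0, "PT": 3500.0, "MZ": 900.0,
            "PE": 700.0, "FB": 700.0, "RS": 850.0, "GR": 450.0,
        },
    }

    # kcal per Mg of harvested product, split into food and feed
    # commodities (plausible, non-measured conversion table)
    cfg["diet"] = {
        "kcal_per_mg": {
            "WW": {"cereals": 2.4e6, "feed": 0.5e6},
            "SB": {"sweeteners": 0.62e6, "feed": 0.25e6},
            "PT": {"tubers": 0.72e6},
            "MZ": {"feed": 3.3e6},
            "PE": {"legumes": 3.0e6, "feed": 0.3e6},
            "FB": {"legumes": 3.0e6, "feed": 0.3e6},
            "RS": {"oils": 3.5e6, "feed": 1.1e6},
            "GR": {"feed": 2.0e6},
            "cover": {"feed": 1.8e6},
            "meat": {"meat": 2.34e6},
        },
        # kcal person-1 day-1 intake bounds, EAT-Lancet-style
        "bounds": {
            "cereals": [200.0, 1200.0],
            "legumes": [50.0, 400.0],
            "oils": [250.0, 500.0],
            "sweeteners": [0.0, 120.0],
            "tubers": [0.0, 150.0],
            "dairy": [0.0, 250.0],
            "meat": [0.0, 120.0],
            "eggs": [0.0, 60.0],
        },
        "animal_commodities": ["dairy", "meat", "eggs"],
        # kcal of feed required per kcal of animal product demanded
        "feed_per_animal_kcal": {"meat": 6.0, "dairy": 1.6, "eggs": 2.5},
        "external_kcal": 300.0,  # fruits/vegetables/nuts, produced off-rotation
        "energy_target": 2500.0,  # kcal person-1 day-1
        "people_prior": [0.5, 30.0],  # people fed per ha, uniform prior
        "w_energy": 10.0,
        "w_balance": 1.0,
        "n_iter": 2000,
        "diet_mode": {"BAU": "omnivorous", "Vegan": "vegan", "ICLS": "omnivorous"},
    }

    cfg["stats"] = {
        "subsample_fraction": 0.01,
        "iqr_multiplier": 1.5,
        "p_threshold": 0.05,
    }

    cfg["rotations"] = _default_rotation_tables()

    cfg["run"] = {
        "n_sites": 20,
        "n_years": 24,
        "seed": 0,
        "scenarios": ["historical", "+4C_MPI"],
        "metric": "gwpstar",
        "save_weather": False,
    }

    return cfg


def _default_rotation_tables() -> dict[str, Any]:
    """Season tables for the three circularity scenarios.

    Each season: crop, duration (years), residue fate, mineral fertilizer
    N (kg N ha-1, identical management across scenarios for shared
    crops), imported manure N, field operation counts, and whether a
    cover crop follows the season (sown before the next spring crop).
    The full sequences are reconstructions consistent with the design
    rules (wheat in positions 2 and 4 everywhere; straw-manure exchange
    in BAU; everything incorporated and zero manure in Vegan; 2.5 pasture
    years in ICLS).
    """

    def season(crop, fert, *, duration=1.0, residue="incorporated", manure=0.0,
               combine=1, plough=0, surface=0, cover=False):
        return {
            "crop": crop,
            "duration": duration,
            "residue_fate": residue,
            "fertilizer_n": fert,
            "manure_n": manure,
            "operations": {
                "combine": combine, "plough": plough, "surface_tillage": surface,
            },
            "cover_crop": cover,
        }

    bau = [
        season("SB", 110, manure=75, plough=1),
        season("WW", 170, residue="removed_exchange", surface=1, cover=True),
        season("MZ", 130, manure=75, plough=2),
        season("WW", 170, surface=1, cover=True),
        season("PT", 180, plough=1, cover=True),
        season("MZ", 130, plough=2),
        season("WW", 170, surface=1),
        season("RS", 170, cover=True),
    ]
    vegan = [
        season("PT", 180, plough=1),
        season("WW", 170, surface=1, cover=True),
        season("FB", 0, plough=1),
        season("WW", 170, surface=1, cover=True),
        season("SB", 110, plough=1),
        season("WW", 170, surface=1),
        season("RS", 170, cover=True),
        season("PE", 0, plough=1, cover=True),
    ]
    icls = [
        season("MZ", 130, manure=0, plough=2),  # manure: on-farm, computed
        season("WW", 170, residue="removed_feed", surface=1, cover=True),
        season("FB", 0, plough=1),
        season("WW", 170, surface=1),
        season("GR", 60, combine=0, surface=2),
        season("GR", 60, combine=0, surface=2),
        season("GR", 30, duration=0.5, combine=0, surface=1, plough=1),
        season("PE", 0, plough=1, cover=True),
    ]

    return {
        "BAU": {
            "livestock_linkage": "manure_exchange",
            "seasons": bau,
        },
        "Vegan": {
            "livestock_linkage": "none",
            "seasons": vegan,
        },
        "ICLS": {
            "livestock_linkage": "on_farm_sheep",
            # positions (1-based) receiving the sheep manure produced by
            # the rotation's own forage, split evenly
            "manure_positions": [1],
            "seasons": icls,
        },
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | None = None) -> dict[str, Any]:
    """Default configuration, optionally overlaid with a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, override)
    return cfg


def save_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
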