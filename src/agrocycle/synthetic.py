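"""Seeded synthetic generator emulating soil-crop-model output.

The generator stands in for a process-based soil-crop model run at
thousands of locations: it produces per-site daily weather (with +2/+3/+4
°C variants), per-season crop yields, annual nitrate leaching and direct
N2O fluxes, and annual SOC stock changes at 0-30 cm and 0-200 cm, with
the statistical structure the downstream analysis assumes:

* historical weather targets the configured climatology (837 mm,
  11 °C); warming adds a uniform temperature offset and seasonal
  precipitation multipliers (drier summers, wetter winters/springs),
  with PET responding to temperature through a Hargreaves law;
* yields are ``base x warming multiplier x lognormal noise`` with
  multiplicative mean 1, so configured effect sizes are recoverable;
* wheat-year yields are coupled to the standardized March-May water
  balance, so wet extremes depress yields (rotation-specific strength,
  ICLS least sensitive);
* nitrate leaching is drawn around a 4.5 kg N ha-1 yr-1 baseline scaled
  by site propensity, rotation and warming multipliers;
* SOC changes follow rotation trends (ICLS profile-positive, BAU
  negative) and decline with warming.

All randomness flows from ``numpy`` SeedSequences keyed on
``(seed, uid, esm stream)``; the warming offset is *not* part of the
key, so two scenarios generated with the same seed differ only by the
deterministic climate transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .config import ClimateScenarioSpec, SiteSpec, default_config
from .rotations import RotationPlan

_ESM_CODE = {"ERA5": 0, "MPI": 1, "CMCC": 2, "MIR": 3}

# stream ids to keep sub-generators independent
_STREAM_WEATHER = 1
_STREAM_YIELD = 2
_STREAM_FLUX = 3
_STREAM_SOC = 4

_START_YEAR = 1981  # nominal calendar anchor for all scenarios


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1."""
    if cv <= 0:
        return np.ones(size) if size is not None else np.float64(1.0)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_sites(
    n_sites: int, seed: int, config: dict | None = None
) -> list[SiteSpec]:
    """Draw site soil states; topsoil SOC averages 78 Mg C ha-1."""
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    cfg = (config or default_config())["sites"]
    rng = _rng(seed, 0)
    top = rng.normal(cfg["soc0_topsoil_mean"], cfg["soc0_topsoil_sd"], n_sites)
    top = np.clip(top, cfg["soc0_topsoil_min"], None)
    ratio = rng.normal(cfg["profile_ratio_mean"], cfg["profile_ratio_sd"], n_sites)
    ratio = np.clip(ratio, cfg["profile_ratio_min"], None)
    cv = cfg["leach_propensity_cv"]
    if cv > 0:
        shape = 1.0 / (cv * cv)
        leach = rng.gamma(shape, scale=1.0 / shape, size=n_sites)
    else:
        leach = np.ones(n_sites)
    return [
        SiteSpec(
            uid=i + 1,
            soc0_topsoil=float(top[i]),
            soc0_profile=float(top[i] * ratio[i]),
            leach_propensity=float(leach[i]),
        )
        for i in range(n_sites)
    ]


def _extraterrestrial_radiation(doy: np.ndarray, latitude_deg: float) -> np.ndarray:
    """Daily top-of-atmosphere radiation (MJ m-2 d-1), standard astronomy."""
    phi = np.deg2rad(latitude_deg)
    j = doy.astype(float)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * j / 365.0)
    delta = 0.409 * np.sin(2 * np.pi * j / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24 * 60 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def _hargreaves_pet(
    tmean: np.ndarray, trange: np.ndarray, doy: np.ndarray, latitude_deg: float
) -> np.ndarray:
    ra = _extraterrestrial_radiation(doy, latitude_deg)
    pet = 0.0023 * (ra / 2.45) * (tmean + 17.8) * np.sqrt(np.maximum(trange, 0.0))
    return np.maximum(pet, 0.0)


_SEASON_OF_MONTH = np.array(
    ["DJF", "DJF", "MAM", "MAM", "MAM", "JJA", "JJA", "JJA", "SON", "SON", "SON", "DJF"]
)


def generate_weather(
    site: SiteSpec,
    scenario: ClimateScenarioSpec,
    n_years: int,
    seed: int,
    config: dict | None = None,
) -> pd.DataFrame:
    """Daily weather (tmin, tmax, precip, pet) for one site and scenario.

    The same ``seed`` under different warming offsets yields weather that
    differs only by the additive temperature offset, the seasonal
    precipitation multipliers, and the PET response.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    cfg = (config or default_config())["weather"]
    rng = _rng(seed, site.uid, _ESM_CODE.get(scenario.esm_label, 9), _STREAM_WEATHER)

    dates = pd.date_range(
        f"{_START_YEAR}-01-01", f"{_START_YEAR + n_years - 1}-12-31", freq="D"
    )
    nd = len(dates)
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()

    # temperature: seasonal cycle + AR(1) day-to-day anomaly
    seasonal = cfg["mean_temp_c"] + cfg["temp_seasonal_amplitude"] * np.cos(
        2 * np.pi * (doy - 196) / 365.25
    )
    phi = cfg["temp_ar1"]
    white = rng.normal(0.0, cfg["temp_noise_sd"] * np.sqrt(1 - phi * phi), nd)
    anomaly = signal.lfilter([1.0], [1.0, -phi], white)
    tmean = seasonal + anomaly + scenario.warming_offset

    trange = (
        cfg["diurnal_range_mean"]
        + cfg["diurnal_range_amplitude"] * np.cos(2 * np.pi * (doy - 172) / 365.25)
        + rng.normal(0.0, 1.0, nd)
    )
    trange = np.clip(trange, 0.5, None)
    tmax = tmean + trange / 2.0
    tmin = tmean - trange / 2.0

    # precipitation: wet-day occurrence x gamma amounts, then seasonal
    # multipliers interpolated in the warming offset
    p_wet = cfg["wet_day_prob"]
    wet_mean = cfg["annual_precip_mm"] / (365.25 * p_wet)
    shape = cfg["precip_gamma_shape"]
    wet = rng.random(nd) < p_wet
    amounts = rng.gamma(shape, scale=wet_mean / shape, size=nd)
    precip = np.where(wet, amounts, 0.0)
    if scenario.warming_offset > 0:
        m4 = cfg["precip_mult_at_4C"]
        frac = scenario.warming_offset / 4.0
        mult_by_season = {k: 1.0 + (v - 1.0) * frac for k, v in m4.items()}
        mult = np.array([mult_by_season[s] for s in _SEASON_OF_MONTH])[month - 1]
        precip = precip * mult

    pet = _hargreaves_pet(tmean, trange, doy, cfg["latitude_deg"])

    return pd.DataFrame(
        {
            "date": dates,
            "tmin": tmin,
            "tmax": tmax,
            "precip": precip,
            "pet": pet,
        }
    )


def march_may_balance(weather: pd.DataFrame) -> pd.Series:
    """Per-year March-May water balance P - PET (mm), indexed by year."""
    w = weather
    mask = w["date"].dt.month.isin([3, 4, 5])
    d = (w.loc[mask, "precip"] - w.loc[mask, "pet"]).groupby(
        w.loc[mask, "date"].dt.year
    ).sum()
    d.index.name = "year"
    return d


def generate_season_outcomes(
    site: SiteSpec,
    scenario: ClimateScenarioSpec,
    rotation: RotationPlan,
    weather: pd.DataFrame,
    seed: int,
    config: dict | None = None,
    weather_hist: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Season outcomes and SOC trajectory for one site x scenario x rotation.

    ``weather_hist`` supplies the historical reference for standardizing
    the March-May water balance used by the wheat coupling; it defaults
    to ``weather`` itself (appropriate for the historical scenario).

    Returns ``(seasons, soc)`` DataFrames; one season row per simulated
    year and one SOC row per year with changes at both depths.
    """
    cfg = config or default_config()
    n_years = weather["date"].dt.year.nunique()
    if n_years % rotation.length != 0:
        raise ValueError(
            f"weather covers {n_years} years, not a multiple of the "
            f"{rotation.length}-year rotation"
        )
    n_cycles = n_years // rotation.length
    off = int(scenario.warming_offset)

    d_mam = march_may_balance(weather).to_numpy()
    ref = march_may_balance(weather_hist if weather_hist is not None else weather)
    ref_mean, ref_sd = float(ref.mean()), float(ref.std(ddof=1))
    if ref_sd <= 0:
        z_mam = np.zeros(n_years)
    else:
        z_mam = (d_mam - ref_mean) / ref_sd

    esm = _ESM_CODE.get(scenario.esm_label, 9)
    rot_code = {"BAU": 1, "Vegan": 2, "ICLS": 3}.get(rotation.name, 7)
    rng_y = _rng(seed, site.uid, esm, _STREAM_YIELD, rot_code, off)
    rng_f = _rng(seed, site.uid, esm, _STREAM_FLUX, rot_code, off)
    rng_s = _rng(seed, site.uid, esm, _STREAM_SOC, rot_code, off)

    wc = cfg["wet_coupling"]
    k_wet = wc["k_wet"].get(rotation.name, 0.2)
    lv = cfg["livestock"]

    rows = []
    for year in range(1, n_years + 1):
        pos = (year - 1) % rotation.length
        season = rotation.seasons[pos]
        crop = season.crop
        ccfg = cfg["crops"][crop]
        mult = 1.0 if off == 0 else cfg["yield_warming_mult"][crop][off]
        noise = float(_lognormal_factor(rng_y, ccfg["cv"], None))
        y = ccfg["base_yield"] * mult * noise * season.duration
        z = float(z_mam[year - 1])
        if crop == "WW":
            m = 1.0
            if z > wc["z0"]:
                m -= k_wet * (z - wc["z0"])
            elif z < -wc["z0"]:
                m += wc["k_dry"] * (-z - wc["z0"])
            y *= max(m, wc["floor"])

        cover_biomass = 0.0
        if season.cover_crop:
            cover_biomass = cfg["cover_biomass"] * float(
                _lognormal_factor(rng_y, cfg["cover_biomass_cv"], None)
            )

        rows.append(
            {
                "uid": site.uid,
                "scenario": scenario.name,
                "rotation": rotation.name,
                "year_index": year,
                "position": pos + 1,
                "crop": crop,
                "duration": season.duration,
                "yield_mg_ha": y,
                "n_fertilizer": season.fertilizer_n,
                "manure_n_applied": season.manure_n,
                "residue_fate": season.residue_fate,
                "cover_crop": season.cover_crop,
                "cover_biomass": cover_biomass,
                "n_combine": season.operations.get("combine", 0),
                "n_plough": season.operations.get("plough", 0),
                "n_surface_tillage": season.operations.get("surface_tillage", 0),
                "mam_z": z,
            }
        )

    seasons = pd.DataFrame(rows)

    # on-farm manure for ICLS: the rotation's own forage, through sheep
    if rotation.livestock_linkage == "on_farm_sheep" and rotation.manure_positions:
        for c in range(n_cycles):
            blk = seasons.iloc[c * rotation.length : (c + 1) * rotation.length]
            forage = (
                blk.loc[blk["crop"] == "GR", "yield_mg_ha"].sum()
                + blk["cover_biomass"].sum()
            )
            dmi = forage * 1000.0 * lv["utilization"]  # kg DM per rotation-ha
            manure_n = dmi * lv["feed_n_frac"] * (1.0 - lv["n_retention"])
            share = manure_n / len(rotation.manure_positions)
            for p in rotation.manure_positions:
                idx = seasons.index[c * rotation.length + (p - 1)]
                seasons.loc[idx, "manure_n_applied"] += share

    # annual N fluxes
    ncfg, lcfg = cfg["n2o"], cfg["leaching"]
    res_n = np.array(
        [
            cfg["residue_n"][r.crop] * r.duration
            if r.residue_fate == "incorporated"
            else 0.0
            for r in (rotation.seasons[(y - 1) % rotation.length] for y in range(1, n_years + 1))
        ]
    )
    # covers are incorporated unless the rotation feeds them to sheep
    if rotation.livestock_linkage != "on_farm_sheep":
        res_n = res_n + np.where(
            seasons["cover_crop"].to_numpy(), cfg["cover_residue_n"], 0.0
        )
    n_applied = seasons["n_fertilizer"].to_numpy() + seasons["manure_n_applied"].to_numpy()
    warm_n2o = ncfg["warming_factor_per_degC"] ** off
    n2o_mean = (ncfg["base"] + ncfg["ef_applied"] * n_applied + ncfg["ef_residue"] * res_n) * warm_n2o
    n2o_noise = _lognormal_factor(
        rng_f, np.expm1(ncfg["lognorm_sigma"] ** 2) ** 0.5, n_years
    )
    seasons["n2o_direct"] = n2o_mean * n2o_noise

    warm_leach = 1.0 if off == 0 else lcfg["warming_mult"][rotation.name][off]
    leach_mean = (
        lcfg["base"]
        * site.leach_propensity
        * lcfg["rotation_mult"][rotation.name]
        * warm_leach
    )
    leach_noise = _lognormal_factor(
        rng_f, np.expm1(lcfg["lognorm_sigma"] ** 2) ** 0.5, n_years
    )
    seasons["no3_leached"] = leach_mean * leach_noise

    # SOC trajectory at both depths
    scfg = cfg["soc"]
    pen = scfg["warming_penalty_per_degC"] * off
    d_top = rng_s.normal(
        scfg["topsoil_trend"][rotation.name] - pen, scfg["sd_topsoil"], n_years
    )
    sub = rng_s.normal(
        scfg["subsoil_gain"][rotation.name] - 0.01 * off, scfg["sd_subsoil"], n_years
    )
    sub = np.maximum(sub, 0.0)  # mineralization below 30 cm negligible
    soc = pd.DataFrame(
        {
            "uid": site.uid,
            "scenario": scenario.name,
            "rotation": rotation.name,
            "year_index": np.arange(1, n_years + 1),
            "dsoc_topsoil": d_top,
            "dsoc_profile": d_top + sub,
        }
    )
    return seasons, soc
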