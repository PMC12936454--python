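"""End-to-end orchestration: generate, assess, compare, export.

``run_pipeline`` wires the stages together for a configured set of
sites, climate scenarios and rotations:

  generate sites -> weather -> season outcomes + SOC -> livestock ->
  GHG budgets -> SPEI + event classes -> productivity / stability /
  resistance -> diet balances -> multi-criteria index -> group tests

and returns (optionally writes) all result tables.  Every output table
has a column schema that is validated on write; runs are deterministic
for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as cl
from . import diet as dt
from . import ghg
from . import performance as pf
from . import stats as st
from .config import ClimateScenarioSpec, CO2_PPM, default_config, scenario_by_name
from .livestock import FeedSupply, manure_emissions, sheep_production
from .rotations import RotationPlan, build_rotation, rotation_table, validate_rotation
from .synthetic import (
    _START_YEAR as START_YEAR,
    generate_season_outcomes,
    generate_sites,
    generate_weather,
)

log = logging.getLogger("agrocycle")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


SCHEMAS: dict[str, list[str]] = {
    "seasons": [
        "uid", "scenario", "rotation", "year_index", "position", "crop",
        "duration", "yield_mg_ha", "n_fertilizer", "manure_n_applied",
        "residue_fate", "cover_crop", "cover_biomass", "n_combine",
        "n_plough", "n_surface_tillage", "mam_z", "n2o_direct", "no3_leached",
    ],
    "soc": ["uid", "scenario", "rotation", "year_index", "dsoc_topsoil",
            "dsoc_profile"],
    "livestock": ["uid", "scenario", "rotation", "year_index", "dm_intake",
                  "lwg", "meat_retail", "ch4_enteric", "ch4_storage",
                  "ch4_spreading", "n2o_storage"],
    "budgets": ["uid", "scenario", "rotation", "metric", "co2_soil",
                "co2_fertilizer", "co2_management", "n2o_direct",
                "n2o_indirect", "ch4_total", "manure_n2o", "net"],
    "spei": ["uid", "scenario", "year", "month", "spei3"],
    "season_class": ["uid", "scenario", "year", "label"],
    "performance": ["uid", "scenario", "rotation", "metric_name", "cycle1",
                    "cycle2", "cycle3", "stability"],
    "resistance": ["uid", "scenario", "rotation", "year", "label",
                   "yield_std", "omega"],
    "diet_balance": ["rotation", "diet_mode", "people_per_ha", "objective",
                     "commodity", "supply", "demand", "deficit", "surplus"],
    "multicriteria": ["criterion", "rotation", "value", "index"],
    "group_tests": ["variable", "rotation", "median", "letters", "n",
                    "kruskal_p"],
    "rotations": ["rotation", "position", "crop", "duration", "residue_fate",
                  "fertilizer_n", "manure_n", "n_combine", "n_plough",
                  "n_surface_tillage", "cover_crop"],
}


def validate_schema(name: str, df: pd.DataFrame) -> None:
    expected = SCHEMAS[name]
    if list(df.columns) != expected:
        raise ValueError(
            f"table {name!r} columns {list(df.columns)} != schema {expected}"
        )


def write_table(df: pd.DataFrame, name: str, outdir: Path) -> None:
    validate_schema(name, df)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
    with open(outdir / f"{name}.schema.json", "w") as fh:
        json.dump({"table": name, "columns": list(df.columns)}, fh, indent=1)


def livestock_annual(
    seasons: pd.DataFrame, plan: RotationPlan, config: dict
) -> pd.DataFrame:
    """Per-year livestock flows and manure-chain emissions for one run.

    The crop-livestock rotation feeds its own forage (cycle totals spread
    evenly over the cycle, the farm carrying every rotation phase at
    once); business-as-usual books only the spreading CH4 of imported
    manure; the stockless rotation emits nothing here.
    """
    lv = config["livestock"]
    years = seasons["year_index"].to_numpy()
    n_years = len(years)
    cycle_len = plan.length
    out = pd.DataFrame(
        {
            "year_index": years,
            "dm_intake": 0.0, "lwg": 0.0, "meat_retail": 0.0,
            "ch4_enteric": 0.0, "ch4_storage": 0.0, "ch4_spreading": 0.0,
            "n2o_storage": 0.0,
        }
    )
    if plan.livestock_linkage == "on_farm_sheep":
        for c in range(n_years // cycle_len):
            blk = seasons.iloc[c * cycle_len : (c + 1) * cycle_len]
            forage = (
                blk.loc[blk["crop"] == "GR", "yield_mg_ha"].sum()
                + blk["cover_biomass"].sum()
            )
            dmi_yr = forage * 1000.0 * lv["utilization"] / cycle_len
            prod = sheep_production(FeedSupply(0, 0, dmi_yr), lv)
            man = manure_emissions(prod.manure_n, prod.manure_vs, "icls_full", lv)
            sl = slice(c * cycle_len, (c + 1) * cycle_len)
            out.loc[out.index[sl], "dm_intake"] = dmi_yr
            out.loc[out.index[sl], "lwg"] = prod.lwg
            out.loc[out.index[sl], "meat_retail"] = prod.meat_retail
            out.loc[out.index[sl], "ch4_enteric"] = prod.ch4_enteric
            out.loc[out.index[sl], "ch4_storage"] = man.ch4_storage
            out.loc[out.index[sl], "ch4_spreading"] = man.ch4_spreading
            out.loc[out.index[sl], "n2o_storage"] = man.n2o_total
    elif plan.livestock_linkage == "manure_exchange":
        # the farm carries every rotation phase at once, so the imported
        # manure stream (and its spreading CH4) is steady from year to year
        for c in range(n_years // cycle_len):
            blk = seasons.iloc[c * cycle_len : (c + 1) * cycle_len]
            vs_yr = (
                blk["manure_n_applied"].sum() * lv["manure_vs_per_n"] / cycle_len
            )
            man = manure_emissions(0.0, vs_yr, "bau_spreading_only", lv)
            sl = slice(c * cycle_len, (c + 1) * cycle_len)
            out.loc[out.index[sl], "ch4_spreading"] = man.ch4_spreading
    return out


def _historical_twin(scenario: ClimateScenarioSpec) -> ClimateScenarioSpec:
    """The unwarmed scenario sharing this scenario's noise stream."""
    if scenario.warming_offset == 0:
        return scenario
    return ClimateScenarioSpec(
        "historical", 0, CO2_PPM[0], scenario.esm_label
    )


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Run every stage and return all result tables (optionally written)."""
    cfg = config or default_config()
    run = cfg["run"]
    n_sites, n_years, seed = run["n_sites"], run["n_years"], run["seed"]
    metric = run["metric"]
    if metric not in ghg.METRICS:
        raise ValueError(f"unknown GWP metric {metric!r}")
    scenarios = [scenario_by_name(s) for s in run["scenarios"]]
    plans = {name: build_rotation(name, cfg) for name in cfg["rotations"]}
    for name, plan in plans.items():
        bad = validate_rotation(plan)
        if bad:
            raise ValueError(f"rotation {name} violates design rules: {bad}")
    gwp = ghg.GwpSet.from_config(cfg)
    out_path = Path(outdir) if outdir is not None else None

    t0 = time.time()
    _stage("sites", f"generating {n_sites} sites (seed {seed})")
    sites = generate_sites(n_sites, seed, cfg)

    all_seasons, all_soc, all_livestock, all_budgets = [], [], [], []
    spei_rows, class_rows = [], []

    for scenario in scenarios:
        _stage("simulate", f"scenario {scenario.name}")
        for site in sites:
            weather = generate_weather(site, scenario, n_years, seed, cfg)
            hist_twin = _historical_twin(scenario)
            weather_hist = (
                weather
                if scenario.warming_offset == 0
                else generate_weather(site, hist_twin, n_years, seed, cfg)
            )
            if run.get("save_weather") and out_path is not None:
                out_path.mkdir(parents=True, exist_ok=True)
                weather.to_csv(
                    out_path / f"weather_{site.uid}_{scenario.name}.csv",
                    index=False, float_format="%.4g",
                )

            # SPEI per site x scenario, calibrated on the historical twin
            d_hist = cl.monthly_balance(weather_hist)
            spei_hist = cl.fit_spei(d_hist, window=cfg["spei"]["window"])
            if scenario.warming_offset == 0:
                spei_here = spei_hist
            else:
                spei_here = cl.fit_spei(
                    cl.monthly_balance(weather),
                    window=cfg["spei"]["window"],
                    coefficients=spei_hist.coefficients,
                )
            month = cfg["spei"]["classification_month"]
            seas_hist = cl.seasonal_spei(spei_hist, month)
            thr = cl.event_thresholds(
                seas_hist.to_numpy(), cfg["spei"]["quantiles"]
            )
            seas_here = cl.seasonal_spei(spei_here, month)
            labels = cl.classify_seasons(seas_here.to_numpy(), thr)
            vals = spei_here.values
            spei_rows.append(
                pd.DataFrame(
                    {
                        "uid": site.uid, "scenario": scenario.name,
                        "year": vals.index.year, "month": vals.index.month,
                        "spei3": vals.to_numpy(),
                    }
                )
            )
            class_rows.append(
                pd.DataFrame(
                    {
                        "uid": site.uid, "scenario": scenario.name,
                        "year": seas_here.index.to_numpy(), "label": labels,
                    }
                )
            )

            for plan in plans.values():
                seasons, soc = generate_season_outcomes(
                    site, scenario, plan, weather, seed, cfg,
                    weather_hist=weather_hist,
                )
                lst = livestock_annual(seasons, plan, cfg)
                budget = ghg.assemble_budget(seasons, soc, lst, gwp, metric, cfg)
                all_seasons.append(seasons)
                all_soc.append(soc)
                lst_out = lst.copy()
                lst_out.insert(0, "rotation", plan.name)
                lst_out.insert(0, "scenario", scenario.name)
                lst_out.insert(0, "uid", site.uid)
                all_livestock.append(lst_out)
                all_budgets.append(
                    {
                        "uid": site.uid, "scenario": scenario.name,
                        "rotation": plan.name, "metric": metric,
                        **budget.as_dict(),
                    }
                )

    seasons = pd.concat(all_seasons, ignore_index=True)[SCHEMAS["seasons"]]
    soc = pd.concat(all_soc, ignore_index=True)
    livestock = pd.concat(all_livestock, ignore_index=True)
    budgets = pd.DataFrame(all_budgets)
    spei = pd.concat(spei_rows, ignore_index=True)
    season_class = pd.concat(class_rows, ignore_index=True)
    _stage("simulate", f"{len(seasons)} season records in {time.time()-t0:.1f}s")

    # ---- productivity and stability -------------------------------------
    _stage("performance", "productivity, stability, resistance")
    perf_rows = []
    for (uid, scen, rot), grp in seasons.groupby(["uid", "scenario", "rotation"]):
        lv = livestock[
            (livestock["uid"] == uid)
            & (livestock["scenario"] == scen)
            & (livestock["rotation"] == rot)
        ]
        cycles = pf.productivity(grp, lv, cfg["value_tables"])
        for m in pf.PRODUCTIVITY_METRICS:
            vals = cycles[m].to_numpy()
            perf_rows.append(
                {
                    "uid": uid, "scenario": scen, "rotation": rot,
                    "metric_name": m,
                    "cycle1": vals[0], "cycle2": vals[1], "cycle3": vals[2],
                    "stability": pf.stability(vals),
                }
            )
    performance = pd.DataFrame(perf_rows)

    # ---- resistance ------------------------------------------------------
    wheat = pf.standardize_wheat(seasons)
    lbl = season_class.set_index(["uid", "scenario", "year"])["label"]
    res_rows = []
    for (uid, scen, rot), grp in wheat.groupby(["uid", "scenario", "rotation"]):
        years = grp["year_index"].to_numpy()
        ys = pd.Series(grp["yield_std"].to_numpy(), index=years)
        labels = pd.Series(
            [lbl.get((uid, scen, START_YEAR + y - 1), "normal") for y in years],
            index=years,
        )
        try:
            res = pf.resistance(ys, labels)
        except ValueError:
            continue  # no normal season in this group
        for y in res.omega.index:
            res_rows.append(
                {
                    "uid": uid, "scenario": scen, "rotation": rot, "year": y,
                    "label": labels[y], "yield_std": ys[y],
                    "omega": res.omega[y],
                }
            )
    resistance = pd.DataFrame(
        res_rows, columns=SCHEMAS["resistance"]
    )

    # ---- diet ------------------------------------------------------------
    _stage("diet", "supply-demand optimization per rotation")
    diet_rows = []
    base_scen = scenarios[0].name
    for rot, plan in plans.items():
        sel = seasons[(seasons["scenario"] == base_scen) & (seasons["rotation"] == rot)]
        n_uids = sel["uid"].nunique()
        internal = plan.livestock_linkage == "on_farm_sheep"
        meat = 0.0
        if internal:
            lv_sel = livestock[
                (livestock["scenario"] == base_scen) & (livestock["rotation"] == rot)
            ]
            meat = lv_sel["meat_retail"].mean() / 1000.0  # kg -> Mg per ha yr
        supply = dt.rotation_supply(
            sel, cfg["diet"]["kcal_per_mg"], meat_mg_per_ha_yr=meat,
            internal_forage=internal,
        )
        supply = {c: v / n_uids for c, v in supply.items()}
        mode = cfg["diet"]["diet_mode"].get(rot, "omnivorous")
        bounds = dt.DietBounds.from_config(mode, cfg)
        sol = dt.optimize_diet(supply, bounds, seed=seed, config=cfg)
        for b in sol.balances:
            diet_rows.append(
                {
                    "rotation": rot, "diet_mode": mode,
                    "people_per_ha": sol.people_per_ha,
                    "objective": sol.objective, "commodity": b.commodity,
                    "supply": b.supply, "demand": b.demand,
                    "deficit": b.deficit, "surplus": b.surplus,
                }
            )
    diet_balance = pd.DataFrame(diet_rows)

    # ---- multi-criteria index -------------------------------------------
    _stage("multicriteria", "BAU-referenced scenario index")
    crit_rows = []
    wet = resistance[resistance["label"].isin(["moderate_wet", "extreme_wet"])]
    for rot in plans:
        b = budgets[budgets["rotation"] == rot]
        s = seasons[seasons["rotation"] == rot]
        sc = soc[soc["rotation"] == rot]
        p = performance[
            (performance["rotation"] == rot)
            & (performance["metric_name"] == "energy")
        ]
        crit_rows += [
            {"criterion": "ghg_net", "rotation": rot, "value": b["net"].mean()},
            {"criterion": "leaching", "rotation": rot,
             "value": s["no3_leached"].mean()},
            {"criterion": "soc_profile", "rotation": rot,
             "value": sc["dsoc_profile"].mean()},
            {"criterion": "productivity", "rotation": rot,
             "value": p[["cycle1", "cycle2", "cycle3"]].to_numpy().mean()},
            {"criterion": "stability", "rotation": rot,
             "value": p["stability"].mean(skipna=True)},
            {"criterion": "resistance_wet", "rotation": rot,
             "value": pf.summarize_omega(
                 wet.loc[wet["rotation"] == rot, "omega"],
                 cfg["stats"]["iqr_multiplier"],
             )},
        ]
    multicrit = pd.DataFrame(crit_rows)
    multicrit["index"] = np.nan
    for crit, grp in multicrit.groupby("criterion"):
        vals = pd.Series(grp["value"].to_numpy(), index=grp["rotation"])
        idx = pf.multicriteria_normalize(vals, reference="BAU")
        multicrit.loc[grp.index, "index"] = idx[grp["rotation"]].to_numpy()

    # ---- group comparisons ----------------------------------------------
    _stage("stats", "Kruskal-Wallis + Dunn group tests")
    test_rows = []
    for var, frame, col in (
        ("ghg_net", budgets, "net"),
        ("no3_leached", seasons.groupby(["rotation", "uid", "scenario"])
            ["no3_leached"].mean().reset_index(), "no3_leached"),
    ):
        groups = {
            rot: frame.loc[frame["rotation"] == rot, col].to_numpy()
            for rot in plans
        }
        frac = cfg["stats"]["subsample_fraction"]
        # keep at least a handful of records per group at desk scale
        min_n = min(len(v) for v in groups.values())
        eff_frac = max(frac, min(1.0, 8.0 / min_n))
        cmp = st.compare_groups(
            groups, eff_frac, seed=seed,
            p_threshold=cfg["stats"]["p_threshold"],
        )
        for rot in plans:
            test_rows.append(
                {
                    "variable": var, "rotation": rot,
                    "median": float(np.median(groups[rot])),
                    "letters": cmp.letters[rot],
                    "n": cmp.n_per_group[rot], "kruskal_p": cmp.kruskal_p,
                }
            )
    group_tests = pd.DataFrame(test_rows)

    rotations_tbl = pd.concat(
        [rotation_table(p) for p in plans.values()], ignore_index=True
    )

    tables = {
        "seasons": seasons, "soc": soc, "livestock": livestock,
        "budgets": budgets, "spei": spei, "season_class": season_class,
        "performance": performance, "resistance": resistance,
        "diet_balance": diet_balance, "multicriteria": multicrit,
        "group_tests": group_tests, "rotations": rotations_tbl,
    }
    if out_path is not None:
        for name, df in tables.items():
            write_table(df, name, out_path)
        _stage("write", f"tables written to {out_path}")
    _stage("done", f"pipeline finished in {time.time()-t0:.1f}s")
    return tables
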