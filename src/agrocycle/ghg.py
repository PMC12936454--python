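"""Farm-gate greenhouse-gas budget over a 24-year rotation run.

Seven signed terms, each expressed in Mg CO2-eq ha-1 yr-1 (24-year
mean; emissions positive, sequestration negative):

1. soil CO2 -- the negated total SOC stock change over the whole profile
   (0-200 cm), converted C -> CO2 with 44/12;
2. CO2 embodied in synthetic N fertilizer (6.17 kg CO2-eq per kg N);
3. CO2 from fuel burnt by field operations (combine 20.5 L ha-1, plough
   27.6, surface tillage 5.6; 0.81 kg C per litre; 3.67 kg CO2 per kg C);
4. direct soil N2O (from the crop-model surrogate output);
5. indirect N2O: 0.75 % of leached N plus 0.1 % of fertilizer N;
6. methane (enteric + manure chain), aggregated with GWP100 or GWP*;
7. N2O from manure storage (on-farm livestock only).

GWP* converts a methane emission *rate* into CO2-warming-equivalents,
crediting stable or declining rates: with the default parameters the
annual CO2-we is ``GWP100 x (4 E(t) - 3.75 E(t-20))``; years earlier
than the 20-year look-back assume a stable herd, i.e. the year-1 rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import default_config
from .livestock import N2O_N_TO_N2O

C_TO_CO2 = 44.0 / 12.0  # stoichiometric, used for soil carbon

METRICS = ("gwp100", "gwpstar")


@dataclass(frozen=True)
class GwpSet:
    """Warming-potential parameters for gas aggregation."""

    gwp100_ch4: float = 27.2
    gwp100_n2o: float = 273.0
    r: float = 0.75
    s: float = 0.25
    H: float = 100.0
    dt: int = 20

    def __post_init__(self) -> None:
        if min(self.gwp100_ch4, self.gwp100_n2o, self.r, self.s, self.H, self.dt) <= 0:
            raise ValueError("GWP parameters must be positive")

    @classmethod
    def from_config(cls, config: dict | None = None) -> "GwpSet":
        g = (config or default_config())["ghg"]
        return cls(
            gwp100_ch4=g["gwp100_ch4"],
            gwp100_n2o=g["gwp100_n2o"],
            **{k: g["gwpstar"][k] for k in ("r", "s", "H")},
            dt=g["gwpstar"]["dt"],
        )


TERM_NAMES = (
    "co2_soil",
    "co2_fertilizer",
    "co2_management",
    "n2o_direct",
    "n2o_indirect",
    "ch4_total",
    "manure_n2o",
)


@dataclass(frozen=True)
class GHGBudget:
    """Signed budget terms in Mg CO2-eq ha-1 yr-1 plus their sum."""

    co2_soil: float
    co2_fertilizer: float
    co2_management: float
    n2o_direct: float
    n2o_indirect: float
    ch4_total: float
    manure_n2o: float
    metric: str = "gwp100"

    @property
    def net(self) -> float:
        return float(sum(getattr(self, t) for t in TERM_NAMES))

    def as_dict(self) -> dict[str, float]:
        d = {t: getattr(self, t) for t in TERM_NAMES}
        d["net"] = self.net
        return d


def soil_co2(dsoc_profile, n_years: int = 24) -> float:
    """Mg CO2-eq ha-1 yr-1 from the whole-profile SOC trajectory.

    Positive SOC change (sequestration) yields a negative emission.
    """
    d = np.asarray(dsoc_profile, dtype=float)
    if d.size != n_years:
        raise ValueError(f"expected {n_years} annual SOC changes, got {d.size}")
    return float(-(d.sum() / n_years) * C_TO_CO2)


def indirect_n2o(
    n_leached: float, n_applied: float, config: dict | None = None
) -> float:
    """Indirect N2O-N (kg ha-1): 0.75 % of leached + 0.1 % of fertilizer N."""
    if n_leached < 0 or n_applied < 0:
        raise ValueError("N inputs must be >= 0")
    g = (config or default_config())["ghg"]
    return g["ef_leach_n2o"] * n_leached + g["ef_fert_n2o"] * n_applied


def management_co2(operations: dict[str, float], config: dict | None = None) -> float:
    """kg CO2 ha-1 from fuel burnt by field operations (counts per type)."""
    g = (config or default_config())["ghg"]
    fuel = 0.0
    for op, count in operations.items():
        if count < 0:
            raise ValueError("operation counts must be >= 0")
        fuel += g["fuel_l"][op] * count
    return fuel * g["fuel_c_per_l"] * g["c_to_co2_fuel"]


def fertilizer_co2(n_applied: float, config: dict | None = None) -> float:
    """kg CO2-eq ha-1 embodied in synthetic N fertilizer."""
    if n_applied < 0:
        raise ValueError("n_applied must be >= 0")
    return (config or default_config())["ghg"]["fert_co2"] * n_applied


def gwp_star_series(ch4_annual, gwp: GwpSet | None = None) -> np.ndarray:
    """CO2-warming-equivalent series (kg CO2-we per year) for methane.

    ``E*(t) = GWP100 x [(rH/dt + s) E(t) - (rH/dt) E(t - dt)]``; for
    ``t <= dt`` the look-back rate is taken as the year-1 rate (stable
    herd before the simulation starts).
    """
    if gwp is None:
        gwp = GwpSet()
    e = np.asarray(ch4_annual, dtype=float)
    if e.size < 1:
        raise ValueError("need at least one annual emission")
    a = gwp.r * gwp.H / gwp.dt
    idx = np.arange(e.size) - gwp.dt
    e_past = np.where(idx >= 0, e[np.maximum(idx, 0)], e[0])
    return gwp.gwp100_ch4 * ((a + gwp.s) * e - a * e_past)


def aggregate_ch4(ch4_annual, gwp: GwpSet, metric: str) -> float:
    """Mean annual CO2-eq (kg) of a methane series under either metric."""
    e = np.asarray(ch4_annual, dtype=float)
    if metric == "gwp100":
        return float(e.mean() * gwp.gwp100_ch4)
    if metric == "gwpstar":
        return float(gwp_star_series(e, gwp).mean())
    raise ValueError(f"unknown metric {metric!r}; use one of {METRICS}")


def assemble_budget(
    seasons: pd.DataFrame,
    soc: pd.DataFrame,
    livestock: pd.DataFrame | None = None,
    gwp: GwpSet | None = None,
    metric: str = "gwp100",
    config: dict | None = None,
) -> GHGBudget:
    """Assemble the seven-term budget for one site x scenario x rotation.

    ``seasons`` and ``soc`` are the per-year tables from the generator;
    ``livestock`` is an optional per-year frame with columns
    ``ch4_enteric, ch4_storage, ch4_spreading, n2o_storage`` (kg of each
    gas per ha and year).  All series must cover the same years.
    """
    cfg = config or default_config()
    if gwp is None:
        gwp = GwpSet.from_config(cfg)
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; use one of {METRICS}")
    n_years = len(seasons)
    if n_years == 0 or len(soc) != n_years:
        raise ValueError("seasons and soc must cover the same (non-zero) years")
    if livestock is not None and len(livestock) != n_years:
        raise ValueError("livestock series does not cover the season years")

    term_soil = soil_co2(soc["dsoc_profile"].to_numpy(), n_years=n_years)

    fert = seasons["n_fertilizer"].to_numpy(dtype=float)
    term_fert = float(np.mean([fertilizer_co2(f, cfg) for f in fert])) / 1000.0

    ops_cols = {"combine": "n_combine", "plough": "n_plough",
                "surface_tillage": "n_surface_tillage"}
    term_mgmt = float(
        np.mean(
            [
                management_co2({op: row[col] for op, col in ops_cols.items()}, cfg)
                for _, row in seasons.iterrows()
            ]
        )
    ) / 1000.0

    n2o_n_direct = seasons["n2o_direct"].to_numpy(dtype=float)
    term_n2o = float(n2o_n_direct.mean()) * N2O_N_TO_N2O * gwp.gwp100_n2o / 1000.0

    leached = seasons["no3_leached"].to_numpy(dtype=float)
    ind = np.array([indirect_n2o(l, f, cfg) for l, f in zip(leached, fert)])
    term_ind = float(ind.mean()) * N2O_N_TO_N2O * gwp.gwp100_n2o / 1000.0

    if livestock is not None:
        ch4 = (
            livestock["ch4_enteric"].to_numpy(dtype=float)
            + livestock["ch4_storage"].to_numpy(dtype=float)
            + livestock["ch4_spreading"].to_numpy(dtype=float)
        )
        term_ch4 = aggregate_ch4(ch4, gwp, metric) / 1000.0
        term_man_n2o = (
            float(livestock["n2o_storage"].to_numpy(dtype=float).mean())
            * gwp.gwp100_n2o
            / 1000.0
        )
    else:
        term_ch4 = 0.0
        term_man_n2o = 0.0

    return GHGBudget(
        co2_soil=term_soil,
        co2_fertilizer=term_fert,
        co2_management=term_mgmt,
        n2o_direct=term_n2o,
        n2o_indirect=term_ind,
        ch4_total=term_ch4,
        manure_n2o=term_man_n2o,
        metric=metric,
    )
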