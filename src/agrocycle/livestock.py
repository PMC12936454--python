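"""Sheep production and manure-management emissions (Tier-1 structure).

Within the integrated crop-livestock system, mown pasture and cover-crop
biomass feed sheep; live weight gain follows from dry-matter intake
through a feed conversion ratio, retail meat through a dressing
percentage and retail fraction, enteric methane through a CH4 yield per
kg intake, and manure N / volatile solids from intake minus retention.
All relations are linear in intake, so outputs scale with the feed
supply.

Manure storage and spreading emissions use Tier-1-style factors.  For
the business-as-usual system, where ruminants are off-farm and manure is
imported against wheat straw, only the CH4 from field spreading is
booked; storage emissions stay with the livestock farm.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import default_config

N2O_N_TO_N2O = 44.0 / 28.0  # stoichiometric N2O-N -> N2O mass conversion

MANURE_CONTEXTS = ("icls_full", "bau_spreading_only")


@dataclass(frozen=True)
class FeedSupply:
    """Forage allocated to sheep for one rotation-hectare and year."""

    uid: int
    year: int
    dm_intake: float  # kg DM ha-1 actually ingested

    def __post_init__(self) -> None:
        if self.dm_intake < 0:
            raise ValueError("dm_intake must be >= 0")


@dataclass(frozen=True)
class LivestockOutput:
    lwg: float  # kg live weight ha-1
    meat_retail: float  # kg ha-1
    ch4_enteric: float  # kg CH4 ha-1
    manure_n: float  # kg N ha-1
    manure_vs: float  # kg volatile solids ha-1


@dataclass(frozen=True)
class ManureEmissions:
    """Per-gas manure-chain emissions, kg of each gas per ha."""

    ch4_storage: float
    ch4_spreading: float
    n2o_storage_direct: float
    n2o_storage_indirect: float

    @property
    def ch4_total(self) -> float:
        return self.ch4_storage + self.ch4_spreading

    @property
    def n2o_total(self) -> float:
        return self.n2o_storage_direct + self.n2o_storage_indirect


def sheep_production(
    feed: FeedSupply, params: dict | None = None
) -> LivestockOutput:
    """Convert ingested forage into live weight, meat, CH4 and manure."""
    p = params if params is not None else default_config()["livestock"]
    for key in ("fcr", "dressing", "retail_fraction", "ch4_yield"):
        if p[key] <= 0:
            raise ValueError(f"livestock parameter {key} must be positive")
    dmi = feed.dm_intake
    lwg = dmi / p["fcr"]
    return LivestockOutput(
        lwg=lwg,
        meat_retail=lwg * p["dressing"] * p["retail_fraction"],
        ch4_enteric=dmi * p["ch4_yield"],
        manure_n=dmi * p["feed_n_frac"] * (1.0 - p["n_retention"]),
        manure_vs=dmi * p["vs_per_dmi"],
    )


def manure_emissions(
    manure_n: float,
    manure_vs: float,
    context: str = "icls_full",
    params: dict | None = None,
) -> ManureEmissions:
    """Tier-1 manure storage/spreading emissions for one ha and year.

    ``icls_full`` books storage CH4 and N2O plus spreading CH4 (sheep on
    the farm); ``bau_spreading_only`` books only the spreading CH4 of the
    imported manure.
    """
    if context not in MANURE_CONTEXTS:
        raise ValueError(f"unknown manure context {context!r}")
    if manure_n < 0 or manure_vs < 0:
        raise ValueError("manure inputs must be >= 0")
    p = params if params is not None else default_config()["livestock"]

    ch4_spreading = manure_vs * p["ef_ch4_spreading"]
    if context == "bau_spreading_only":
        return ManureEmissions(0.0, ch4_spreading, 0.0, 0.0)

    ch4_storage = manure_vs * p["b0"] * p["ch4_density"] * p["mcf_storage"]
    n2o_direct = manure_n * p["ef_n2o_direct"] * N2O_N_TO_N2O
    n2o_indirect = (
        manure_n * p["frac_volatilized"] * p["ef_n2o_indirect"] * N2O_N_TO_N2O
    )
    return ManureEmissions(ch4_storage, ch4_spreading, n2o_direct, n2o_indirect)
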