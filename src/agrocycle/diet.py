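"""Diet supply-demand optimization by seeded random search.

Each rotation's food and feed output (kcal ha-1 yr-1 per commodity) is
matched against an EAT-Lancet-style demand: per-commodity intake bounds
(kcal person-1 day-1) act as priors, the number of people fed per
hectare is itself a prior parameter, and the sampler repeatedly draws
candidate intake vectors, scoring each by a weighted sum of (i) the gap
between supplied dietary energy and the target intake (higher weight)
and (ii) the total of commodity deficits (covered by imports) and
surpluses (exports).  The returned optimum is the running argmin, so the
objective is non-increasing in the iteration budget for a fixed seed.

Fruits, vegetables and tree nuts are produced outside the rotations and
contribute a fixed energy term on the demand side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import default_config

DIET_MODES = ("omnivorous", "ovo-lacto", "vegan")

_DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class DietBounds:
    """Per-commodity intake bounds (kcal person-1 day-1) and energy target."""

    bounds: dict[str, tuple[float, float]]
    energy_target: float
    mode: str = "omnivorous"
    animal_commodities: tuple[str, ...] = ("dairy", "meat", "eggs")

    def __post_init__(self) -> None:
        if self.mode not in DIET_MODES:
            raise ValueError(f"unknown diet mode {self.mode!r}")
        for c, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"infeasible bounds for {c!r}: {lo} > {hi}")

    def effective_bounds(self) -> dict[str, tuple[float, float]]:
        """Bounds with animal commodities zeroed out as the mode demands."""
        out = dict(self.bounds)
        banned: tuple[str, ...] = ()
        if self.mode == "vegan":
            banned = self.animal_commodities
        elif self.mode == "ovo-lacto":
            banned = ("meat",)
        for c in banned:
            if c in out:
                out[c] = (0.0, 0.0)
        return out

    @classmethod
    def from_config(cls, mode: str, config: dict | None = None) -> "DietBounds":
        d = (config or default_config())["diet"]
        return cls(
            bounds={c: tuple(b) for c, b in d["bounds"].items()},
            energy_target=d["energy_target"],
            mode=mode,
            animal_commodities=tuple(d["animal_commodities"]),
        )


@dataclass(frozen=True)
class CommodityBalance:
    commodity: str
    supply: float  # kcal ha-1 yr-1
    demand: float
    deficit: float
    surplus: float


@dataclass(frozen=True)
class DietSolution:
    intake: dict[str, float]  # kcal person-1 day-1
    people_per_ha: float
    balances: list[CommodityBalance]
    objective: float

    def balance_frame(self) -> pd.DataFrame:
        return pd.DataFrame([b.__dict__ for b in self.balances])


def rotation_supply(
    seasons: pd.DataFrame,
    conversion_tables: dict | None = None,
    meat_mg_per_ha_yr: float = 0.0,
    internal_forage: bool = False,
) -> dict[str, float]:
    """Per-commodity kcal ha-1 yr-1 supplied by a rotation's seasons.

    ``internal_forage=True`` (crop-livestock rotation) routes pasture and
    cover biomass to the sheep instead of the feed market; the resulting
    meat enters through ``meat_mg_per_ha_yr``.
    """
    tables = (
        conversion_tables
        if conversion_tables is not None
        else default_config()["diet"]["kcal_per_mg"]
    )
    supply: dict[str, float] = {}
    n_years = seasons["year_index"].nunique() if len(seasons) else 1

    for _, row in seasons.iterrows():
        crop = row["crop"]
        if crop not in tables:
            raise KeyError(f"crop {crop!r} missing from kcal conversion table")
        if internal_forage and crop == "GR":
            continue
        for commodity, kcal in tables[crop].items():
            supply[commodity] = supply.get(commodity, 0.0) + row["yield_mg_ha"] * kcal
        if row.get("cover_biomass", 0.0) > 0 and not internal_forage:
            for commodity, kcal in tables["cover"].items():
                supply[commodity] = (
                    supply.get(commodity, 0.0) + row["cover_biomass"] * kcal
                )

    supply = {c: v / n_years for c, v in supply.items()}
    if meat_mg_per_ha_yr > 0:
        for commodity, kcal in tables["meat"].items():
            supply[commodity] = supply.get(commodity, 0.0) + meat_mg_per_ha_yr * kcal
    return supply


def _score(
    intake: dict[str, float],
    people: float,
    supply: dict[str, float],
    diet_cfg: dict,
) -> tuple[float, list[CommodityBalance]]:
    feed_conv = diet_cfg["feed_per_animal_kcal"]
    demand: dict[str, float] = {}
    for c, kcal_day in intake.items():
        demand[c] = kcal_day * _DAYS_PER_YEAR * people
    feed = sum(
        intake.get(a, 0.0) * conv for a, conv in feed_conv.items()
    ) * _DAYS_PER_YEAR * people
    demand["feed"] = feed

    commodities = sorted(set(demand) | set(supply))
    balances = []
    imbalance = 0.0
    for c in commodities:
        s, d = supply.get(c, 0.0), demand.get(c, 0.0)
        deficit = max(0.0, d - s)
        surplus = max(0.0, s - d)
        imbalance += deficit + surplus
        balances.append(CommodityBalance(c, s, d, deficit, surplus))

    energy = sum(intake.values()) + diet_cfg["external_kcal"]
    gap = abs(energy - diet_cfg["energy_target"])
    objective = (
        diet_cfg["w_energy"] * gap
        + diet_cfg["w_balance"] * imbalance / (_DAYS_PER_YEAR * people)
    )
    return objective, balances


def optimize_diet(
    supply: dict[str, float],
    bounds: DietBounds,
    n_iter: int | None = None,
    seed: int = 0,
    config: dict | None = None,
) -> DietSolution:
    """Random search over intake vectors and people-per-ha.

    Samples uniformly within the (mode-adjusted) intake bounds and the
    people-per-ha prior, keeps the argmin of the objective, and is
    deterministic for a fixed seed.
    """
    diet_cfg = (config or default_config())["diet"]
    if n_iter is None:
        n_iter = diet_cfg["n_iter"]
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    eff = bounds.effective_bounds()
    commodities = sorted(eff)
    lo = np.array([eff[c][0] for c in commodities])
    hi = np.array([eff[c][1] for c in commodities])
    p_lo, p_hi = diet_cfg["people_prior"]

    rng = np.random.default_rng(seed)
    best: DietSolution | None = None
    for _ in range(n_iter):
        draw = lo + rng.random(len(commodities)) * (hi - lo)
        people = p_lo + rng.random() * (p_hi - p_lo)
        intake = dict(zip(commodities, draw))
        obj, balances = _score(intake, people, supply, diet_cfg)
        if best is None or obj < best.objective:
            best = DietSolution(
                intake=intake, people_per_ha=people,
                balances=balances, objective=obj,
            )
    assert best is not None
    return best
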