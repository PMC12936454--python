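"""Crop-rotation plans for the three circularity scenarios and the
agronomic design rules they must satisfy.

A rotation is an 8-year cyclic crop sequence.  All three scenarios place
winter wheat in positions 2 and 4 so that wheat seasons can be compared
across scenarios in the same calendar years.  Design rules (minimum
return times, legume spacing, winter/spring alternation, cover crops
before spring planting) are checked on the *cyclic* sequence, i.e. the
rotation is assumed to repeat indefinitely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd

from .config import (
    LEGUMES,
    PASTURE_CROPS,
    RESIDUE_FATES,
    ROTATION_NAMES,
    SPRING_CROPS,
    WINTER_CROPS,
    default_config,
)


@dataclass(frozen=True)
class Season:
    """One year (or part-year, for pasture tails) of a rotation."""

    crop: str
    duration: float = 1.0
    residue_fate: str = "incorporated"
    fertilizer_n: float = 0.0
    manure_n: float = 0.0
    operations: dict[str, int] = field(default_factory=dict)
    cover_crop: bool = False

    def __post_init__(self) -> None:
        if self.residue_fate not in RESIDUE_FATES:
            raise ValueError(f"unknown residue fate {self.residue_fate!r}")
        if self.fertilizer_n < 0 or self.manure_n < 0:
            raise ValueError("N inputs must be >= 0")


@dataclass(frozen=True)
class RotationPlan:
    name: str
    seasons: tuple[Season, ...]
    livestock_linkage: str = "none"
    manure_positions: tuple[int, ...] = ()  # 1-based, on-farm manure returns

    @property
    def length(self) -> int:
        return len(self.seasons)

    @property
    def crops(self) -> tuple[str, ...]:
        return tuple(s.crop for s in self.seasons)

    def pasture_years(self) -> float:
        return sum(s.duration for s in self.seasons if s.crop in PASTURE_CROPS)

    def total_manure_n(self) -> float:
        return sum(s.manure_n for s in self.seasons)


@dataclass(frozen=True)
class DesignRule:
    """A single agronomic constraint on the cyclic crop sequence.

    kinds:
      min_return_same_crop  -- params: crop, gap
      min_return_pair       -- params: crops (pair), gap
      family_alternation    -- params: crops (family members), gap; applies
                               when consecutive family occurrences change species
      winter_spring_alternation -- params: max_run (pasture exempt)
      cover_before_spring   -- no params; pasture as preceding crop counts
                               as cover
    """

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gap = self.params.get("gap", 0)
        if gap < 0:
            raise ValueError("rule gaps must be >= 0")


def default_rules() -> list[DesignRule]:
    rules = [
        DesignRule("min_return_same_crop", {"crop": "WW", "gap": 2}),
        DesignRule("min_return_same_crop", {"crop": "MZ", "gap": 3}),
        DesignRule("min_return_same_crop", {"crop": "SB", "gap": 4}),
        DesignRule("min_return_same_crop", {"crop": "PT", "gap": 4}),
        DesignRule("min_return_same_crop", {"crop": "RS", "gap": 3}),
        DesignRule("min_return_pair", {"crops": ["SB", "PT"], "gap": 4}),
        DesignRule("family_alternation", {"crops": sorted(LEGUMES), "gap": 3}),
        DesignRule("winter_spring_alternation", {"max_run": 2}),
        DesignRule("cover_before_spring", {}),
    ]
    return rules


def build_rotation(name: str, config: dict | None = None) -> RotationPlan:
    """Instantiate one of the configured default plans (BAU/Vegan/ICLS)."""
    cfg = config if config is not None else default_config()
    tables = cfg["rotations"]
    if name not in tables:
        raise KeyError(
            f"unknown rotation {name!r}; known: {sorted(tables)}"
        )
    entry = tables[name]
    seasons = tuple(
        Season(
            crop=s["crop"],
            duration=float(s.get("duration", 1.0)),
            residue_fate=s.get("residue_fate", "incorporated"),
            fertilizer_n=float(s.get("fertilizer_n", 0.0)),
            manure_n=float(s.get("manure_n", 0.0)),
            operations=dict(s.get("operations", {})),
            cover_crop=bool(s.get("cover_crop", False)),
        )
        for s in entry["seasons"]
    )
    plan = RotationPlan(
        name=name,
        seasons=seasons,
        livestock_linkage=entry.get("livestock_linkage", "none"),
        manure_positions=tuple(entry.get("manure_positions", ())),
    )
    _check_plan_invariants(plan)
    return plan


def _check_plan_invariants(plan: RotationPlan) -> None:
    if plan.name in ROTATION_NAMES:
        if plan.length != 8:
            raise ValueError(f"{plan.name}: rotation length must be 8 years")
        if plan.crops[1] != "WW" or plan.crops[3] != "WW":
            raise ValueError(
                f"{plan.name}: winter wheat must occupy positions 2 and 4"
            )
    if plan.name == "Vegan":
        if plan.total_manure_n() != 0:
            raise ValueError("Vegan: no manure is applied")
        if any(s.residue_fate != "incorporated" for s in plan.seasons):
            raise ValueError("Vegan: all residues are incorporated")
    if plan.name == "ICLS" and abs(plan.pasture_years() - 2.5) > 1e-9:
        raise ValueError("ICLS: temporary pasture must total 2.5 years")


def _cyclic_gap(i: int, j: int, n: int) -> int:
    """Smallest forward distance from position i to j on a cycle of n."""
    return (j - i) % n


def _occurrences(crops: Iterable[str], targets: set[str]) -> list[int]:
    return [i for i, c in enumerate(crops) if c in targets]


def validate_rotation(
    plan: RotationPlan, rules: list[DesignRule] | None = None
) -> list[str]:
    """Return human-readable violations; empty list means the plan is valid.

    The sequence is treated as cyclic, so a rule can be violated across
    the rotation boundary.  Violations are data, not errors.
    """
    if plan.length == 0:
        raise ValueError("empty rotation plan")
    if rules is None:
        rules = default_rules()
    crops = list(plan.crops)
    n = plan.length
    violations: list[str] = []

    for rule in rules:
        if rule.kind == "min_return_same_crop":
            crop, gap = rule.params["crop"], rule.params["gap"]
            pos = _occurrences(crops, {crop})
            for a, b in _consecutive_pairs(pos, n):
                d = _cyclic_gap(a, b, n)
                if 0 < d < gap:
                    violations.append(
                        f"{crop} returns after {d} yr at positions "
                        f"{a + 1}->{b + 1} (minimum {gap})"
                    )
        elif rule.kind == "min_return_pair":
            pair, gap = set(rule.params["crops"]), rule.params["gap"]
            pos = _occurrences(crops, pair)
            for a, b in _consecutive_pairs(pos, n):
                d = _cyclic_gap(a, b, n)
                if 0 < d < gap:
                    violations.append(
                        f"{crops[a]}/{crops[b]} spaced {d} yr at positions "
                        f"{a + 1}->{b + 1} (minimum {gap})"
                    )
        elif rule.kind == "family_alternation":
            family, gap = set(rule.params["crops"]), rule.params["gap"]
            pos = _occurrences(crops, family)
            for a, b in _consecutive_pairs(pos, n):
                if crops[a] == crops[b]:
                    continue  # species change only
                d = _cyclic_gap(a, b, n)
                if 0 < d < gap:
                    violations.append(
                        f"legume species change {crops[a]}->{crops[b]} after "
                        f"{d} yr at positions {a + 1}->{b + 1} (minimum {gap})"
                    )
        elif rule.kind == "winter_spring_alternation":
            max_run = rule.params.get("max_run", 2)
            types = [
                "winter" if c in WINTER_CROPS
                else "spring" if c in SPRING_CROPS
                else "pasture"
                for c in crops
            ]
            arable = [(i, t) for i, t in enumerate(types) if t != "pasture"]
            run_len, run_pos = _max_cyclic_run([t for _, t in arable])
            if run_len > max_run:
                pos0 = arable[run_pos][0] if arable else 0
                violations.append(
                    f"{arable[run_pos][1]} crops run {run_len} yr in a row "
                    f"starting near position {pos0 + 1} (maximum {max_run})"
                )
        elif rule.kind == "cover_before_spring":
            for i, c in enumerate(crops):
                if c not in SPRING_CROPS:
                    continue
                prev = (i - 1) % n
                prev_season = plan.seasons[prev]
                if prev_season.crop in PASTURE_CROPS:
                    continue  # pasture keeps the soil covered
                if not prev_season.cover_crop:
                    violations.append(
                        f"spring crop {c} at position {i + 1} not preceded "
                        f"by a cover crop"
                    )
        else:
            raise ValueError(f"unknown rule kind {rule.kind!r}")

    return violations


def _max_cyclic_run(seq: list[str]) -> tuple[int, int]:
    """Length and start index of the longest run of equal items on a cycle."""
    m = len(seq)
    if m == 0:
        return 0, 0
    if len(set(seq)) == 1:
        return m, 0
    # rotate so the sequence does not start mid-run across the boundary
    k = 0
    while seq[k - 1] == seq[k]:
        k -= 1
    rotated = seq[k:] + seq[:k] if k else seq
    best_len, best_start, run, start = 1, 0, 1, 0
    for i in range(1, m):
        if rotated[i] == rotated[i - 1]:
            run += 1
        else:
            run, start = 1, i
        if run > best_len:
            best_len, best_start = run, start
    return best_len, (best_start + k) % m


def _consecutive_pairs(pos: list[int], n: int) -> list[tuple[int, int]]:
    """Cyclically consecutive occurrence pairs among sorted positions."""
    if len(pos) < 2:
        if len(pos) == 1:
            return []  # single occurrence: gap is the full cycle
        return []
    pairs = [(pos[k], pos[k + 1]) for k in range(len(pos) - 1)]
    pairs.append((pos[-1], pos[0]))  # wrap around
    return pairs


def rotation_table(plan: RotationPlan) -> pd.DataFrame:
    """Flat per-position table for CSV export."""
    rows = []
    for i, s in enumerate(plan.seasons, start=1):
        rows.append(
            {
                "rotation": plan.name,
                "position": i,
                "crop": s.crop,
                "duration": s.duration,
                "residue_fate": s.residue_fate,
                "fertilizer_n": s.fertilizer_n,
                "manure_n": s.manure_n,
                "n_combine": s.operations.get("combine", 0),
                "n_plough": s.operations.get("plough", 0),
                "n_surface_tillage": s.operations.get("surface_tillage", 0),
                "cover_crop": s.cover_crop,
            }
        )
    return pd.DataFrame(rows)
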