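"""Productivity, stability, resistance and the BAU-referenced index.

Productivity is totalled per 8-year rotation cycle in three metrics:
harvested mass (Mg ha-1), energy (cereal units, CU ha-1) and money
(EUR ha-1, prices minus fixed costs); the crop-livestock rotation adds
sheep meat.  Stability is the ratio mu/sigma of the three cycle totals
over the 24-year run (sample standard deviation).  Resistance to a
classified climatic event is Omega = 1 / |Ye - Ybar_n|: the reciprocal
distance between the standardized wheat yield of the event season and
the mean standardized yield of normal seasons.  The multi-criteria
overview rescales every criterion so the business-as-usual rotation
reads 100 (or -100 where its value is negative, as for whole-profile
SOC change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import default_config

PRODUCTIVITY_METRICS = ("mass", "energy", "econ")


def productivity(
    seasons: pd.DataFrame,
    livestock: pd.DataFrame | None = None,
    tables: dict | None = None,
    cycle_length: int = 8,
) -> pd.DataFrame:
    """Per-cycle productivity totals in the three metrics.

    ``livestock`` optionally supplies per-year retail meat (kg ha-1,
    column ``meat_retail``) sold by the crop-livestock rotation.
    Raises ``KeyError`` when a crop lacks a value-table entry.
    """
    vt = tables if tables is not None else default_config()["value_tables"]
    if len(seasons) == 0:
        return pd.DataFrame(
            {"cycle": [], "mass": [], "energy": [], "econ": []}
        )
    for crop in seasons["crop"].unique():
        for tbl in ("cu", "price", "fixed_cost"):
            if crop not in vt[tbl]:
                raise KeyError(f"crop {crop!r} missing from value table {tbl!r}")

    df = seasons.copy()
    df["cycle"] = (df["year_index"] - 1) // cycle_length + 1
    df["cu_val"] = df["yield_mg_ha"] * df["crop"].map(vt["cu"])
    df["econ_val"] = df["yield_mg_ha"] * df["crop"].map(vt["price"]) - df[
        "duration"
    ] * df["crop"].map(vt["fixed_cost"])
    out = (
        df.groupby("cycle")
        .agg(mass=("yield_mg_ha", "sum"), energy=("cu_val", "sum"),
             econ=("econ_val", "sum"))
        .reset_index()
    )

    if livestock is not None and len(livestock) > 0:
        lv = livestock.copy()
        lv["cycle"] = (lv["year_index"] - 1) // cycle_length + 1
        meat = lv.groupby("cycle")["meat_retail"].sum() / 1000.0  # kg -> Mg
        meat = meat.reindex(out["cycle"]).fillna(0.0).to_numpy()
        out["mass"] = out["mass"] + meat
        out["energy"] = out["energy"] + meat * vt["cu"]["meat"]
        out["econ"] = out["econ"] + meat * vt["price"]["meat"]
    return out


def stability(cycle_totals) -> float:
    """mu/sigma across rotation-cycle totals; NaN when sigma is zero.

    The undefined (sigma = 0) case is flagged as NaN rather than
    infinity so that downstream medians simply skip it.
    """
    v = np.asarray(cycle_totals, dtype=float)
    if v.size < 2:
        raise ValueError("stability needs at least 2 rotation cycles")
    sigma = v.std(ddof=1)
    if sigma == 0:
        return float("nan")
    return float(v.mean() / sigma)


def standardize_yields(values) -> np.ndarray:
    """Within-group z-scores x 100 (sample standard deviation).

    Standardized anomalies are percentages of one within-group standard
    deviation, so between-class differences can fall below -100 %.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 wheat seasons per group")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero within-group yield variance")
    return (v - v.mean()) / sd * 100.0


def standardize_wheat(
    seasons: pd.DataFrame, positions: tuple[int, ...] = (2, 4)
) -> pd.DataFrame:
    """Standardized wheat yields, grouped by uid x climate scenario.

    Only the wheat seasons shared across rotations (positions 2 and 4)
    enter, so the same crop in the same years is compared everywhere;
    the three circularity scenarios are pooled within each group, which
    keeps their wheat responses on a common site-specific scale.
    """
    wheat = seasons[
        (seasons["crop"] == "WW") & seasons["position"].isin(positions)
    ].copy()
    wheat["yield_std"] = (
        wheat.groupby(["uid", "scenario"])["yield_mg_ha"]
        .transform(lambda v: standardize_yields(v.to_numpy()))
    )
    return wheat


@dataclass(frozen=True)
class ResistanceResult:
    ybar_normal: float
    omega: pd.Series  # per non-normal season, index aligned with input
    capped: pd.Series  # True where |Ye - Ybar_n| fell below eps


def resistance(
    standardized_yields: pd.Series,
    season_labels: pd.Series,
    eps: float = 1e-6,
) -> ResistanceResult:
    """Omega = 1/|Ye - Ybar_n| for every non-normal season in a group."""
    labels = season_labels.reindex(standardized_yields.index)
    normal = standardized_yields[labels == "normal"]
    if len(normal) == 0:
        raise ValueError("no normal seasons in group; resistance undefined")
    ybar = float(normal.mean())
    events = standardized_yields[labels != "normal"]
    dev = (events - ybar).abs()
    capped = dev < eps
    omega = 1.0 / dev.clip(lower=eps)
    return ResistanceResult(ybar_normal=ybar, omega=omega, capped=capped)


def summarize_omega(omega, iqr_multiplier: float = 1.5) -> float:
    """Median resistance after 1.5 x IQR outlier removal."""
    from .stats import iqr_outliers

    v = np.asarray(omega, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    if v.size >= 4:
        v = v[~iqr_outliers(v, iqr_multiplier)]
    return float(np.median(v))


def multicriteria_normalize(
    values: pd.Series | dict, reference: str = "BAU"
) -> pd.Series:
    """Index each scenario's criterion value against the reference.

    ``value / |value_ref| x 100``: a positive reference reads 100, a
    negative one (whole-profile SOC change under BAU) reads -100 while
    sequestering scenarios keep their positive sign.  Idempotent.
    """
    s = pd.Series(values, dtype=float)
    if reference not in s.index:
        raise KeyError(f"reference scenario {reference!r} not in values")
    ref = s[reference]
    if ref == 0:
        raise ValueError("reference value is zero; index undefined")
    return s / abs(ref) * 100.0
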