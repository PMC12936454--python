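"""Scenario-comparison statistics: Kruskal-Wallis + Dunn, IQR outliers.

Group differences between circularity scenarios are assessed
non-parametrically: a Kruskal-Wallis test on a common 1/100 subsample
(the same record indices drawn in every scenario, since records are
paired by site and year), followed by Dunn's pairwise z-tests on the
pooled ranks with tie correction.  Pairwise outcomes are condensed into
compact letter displays: scenarios sharing a letter are not
significantly different at the configured threshold.

Outliers are flagged by the 1.5 x IQR fence with type-7 (linear
interpolation) quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def iqr_outliers(values, multiplier: float = 1.5) -> np.ndarray:
    """Boolean mask of values outside [Q1 - m*IQR, Q3 + m*IQR]."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile fences")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    return (v < q1 - multiplier * iqr) | (v > q3 + multiplier * iqr)


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks (tie-corrected).

    Returns a symmetric frame of two-sided p-values.  No multiplicity
    adjustment beyond the test's construction is applied.
    """
    names = list(groups)
    sizes = {k: len(v) for k, v in groups.items()}
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for k in names:
        mean_ranks[k] = ranks[start : start + sizes[k]].mean()
        start += sizes[k]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            if se == 0:
                pv = 1.0
            else:
                z = (mean_ranks[a] - mean_ranks[b]) / se
                pv = 2.0 * sps.norm.sf(abs(z))
            p.loc[a, b] = p.loc[b, a] = pv
    return p


def _maximal_cliques(adjacency: dict[str, set[str]]) -> list[set[str]]:
    """Bron-Kerbosch without pivoting; fine for a handful of groups."""
    cliques: list[set[str]] = []

    def expand(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in sorted(p):
            expand(r | {v}, p & adjacency[v], x & adjacency[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(adjacency), set())
    return cliques


def letter_display(
    pvalues: pd.DataFrame, order: list[str], threshold: float = 0.05
) -> dict[str, str]:
    """Compact letter display from a pairwise p-value matrix.

    ``order`` fixes which group receives 'a' first (typically by median
    or mean rank).  Groups sharing a letter are not significantly
    different.
    """
    adjacency = {
        g: {h for h in order if h != g and pvalues.loc[g, h] >= threshold}
        for g in order
    }
    cliques = _maximal_cliques(adjacency)
    cliques.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in order}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in clique:
            letters[g] += ch
    return {g: "".join(sorted(s)) for g, s in letters.items()}


@dataclass(frozen=True)
class GroupComparison:
    kruskal_stat: float
    kruskal_p: float
    dunn_p: pd.DataFrame
    letters: dict[str, str]
    n_per_group: dict[str, int]


def compare_groups(
    groups: dict[str, np.ndarray],
    subsample_fraction: float = 0.01,
    seed: int = 0,
    p_threshold: float = 0.05,
) -> GroupComparison:
    """Kruskal-Wallis + Dunn on a common subsample of each group.

    When all groups have equal length (records paired across scenarios),
    the same subsample indices are used in every group; otherwise each
    group is subsampled independently with the same seeded generator.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")

    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    rng = np.random.default_rng(seed)
    lengths = {len(v) for v in arrays.values()}
    if subsample_fraction < 1.0:
        if len(lengths) == 1:
            n = lengths.pop()
            m = max(2, int(round(n * subsample_fraction)))
            idx = rng.choice(n, size=m, replace=False)
            arrays = {k: v[idx] for k, v in arrays.items()}
        else:
            arrays = {
                k: v[
                    rng.choice(
                        len(v),
                        size=max(2, int(round(len(v) * subsample_fraction))),
                        replace=False,
                    )
                ]
                for k, v in arrays.items()
            }
    for k, v in arrays.items():
        if len(v) == 0:
            raise ValueError(f"group {k!r} empty after subsampling")

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:  # all values identical: nothing to distinguish
        stat, pv = 0.0, 1.0
        dunn = pd.DataFrame(
            np.ones((len(arrays), len(arrays))),
            index=list(arrays), columns=list(arrays),
        )
    else:
        stat, pv = sps.kruskal(*arrays.values())
        dunn = dunn_test(arrays)

    order = sorted(arrays, key=lambda k: float(np.median(arrays[k])))
    letters = letter_display(dunn, order, threshold=p_threshold)
    return GroupComparison(
        kruskal_stat=float(stat),
        kruskal_p=float(pv),
        dunn_p=dunn,
        letters=letters,
        n_per_group={k: len(v) for k, v in arrays.items()},
    )
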