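"""Jaccard β-diversity partitioned into turnover and nestedness.

Pairwise incidence-based partition in the Baselga framework: with ``a``
shared species and ``b``, ``c`` unique to either unit,

* total dissimilarity  β_jac = (b + c)/(a + b + c)
* turnover (species replacement)  β_jtu = 2·min(b,c)/(a + 2·min(b,c))
* nestedness-resultant (species loss)  β_jne = β_jac − β_jtu

so the two components sum to the total exactly. Contrasts are evaluated at
three scales of the sampling design: sites within each area and state,
states within each area, and areas within each state (mean of pairwise
partitions when more than two units are compared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BetaPartition",
    "jaccard_partition",
    "presence_sets",
    "contrast_table",
    "exclusive_species",
]


@dataclass(frozen=True)
class BetaPartition:
    beta_jac: float
    beta_jtu: float
    beta_jne: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.beta_jac, self.beta_jtu, self.beta_jne)


def jaccard_partition(a_set: set, b_set: set) -> BetaPartition:
    """Partition the Jaccard dissimilarity between two presence sets.

    Both-empty input has no defined dissimilarity and returns NaN
    components.
    """
    a_set, b_set = set(a_set), set(b_set)
    if not a_set and not b_set:
        return BetaPartition(np.nan, np.nan, np.nan)
    a = len(a_set & b_set)
    b = len(a_set - b_set)
    c = len(b_set - a_set)
    jac = (b + c) / (a + b + c)
    m = min(b, c)
    jtu = 2 * m / (a + 2 * m) if (a + 2 * m) > 0 else 0.0
    return BetaPartition(jac, jtu, jac - jtu)


def _mean_partition(parts: list[BetaPartition]) -> BetaPartition:
    arr = np.array([p.as_tuple() for p in parts], dtype=float)
    jac, jtu = np.nanmean(arr[:, 0]), np.nanmean(arr[:, 1])
    # re-close on the means so additivity survives averaging
    return BetaPartition(float(jac), float(jtu), float(jac - jtu))


def presence_sets(community: pd.DataFrame, groups: pd.Series) -> dict[str, set]:
    """Pool counts over ``groups`` and threshold at presence (count ≥ 1)."""
    pooled = community.groupby(groups.reindex(community.index)).sum()
    return {
        str(label): set(pooled.columns[pooled.loc[label] > 0])
        for label in pooled.index
    }


def contrast_table(
    community: pd.DataFrame, design: pd.DataFrame, scale: str
) -> pd.DataFrame:
    """β-partitions at one contrast scale of the nested design.

    ``scale`` is one of:

    * ``"sites"`` — the two sites of each area × state cell;
    * ``"states"`` — barren vs meadow within each area, sites pooled;
    * ``"areas"`` — all area pairs within each state (sites pooled per
      area), reported as the mean of pairwise partitions.
    """
    design = design.reindex(community.index)
    rows = []
    if scale == "sites":
        for (area, state), sub in design.groupby(["area", "state"], sort=True):
            sets = presence_sets(community.loc[sub.index], sub["site"])
            labels = sorted(sets)
            for i, u in enumerate(labels):
                for v in labels[i + 1 :]:
                    p = jaccard_partition(sets[u], sets[v])
                    rows.append((scale, area, state, u, v, *p.as_tuple()))
    elif scale == "states":
        for area, sub in design.groupby("area", sort=True):
            sets = presence_sets(community.loc[sub.index], sub["state"])
            labels = sorted(sets)
            if len(labels) != 2:
                raise ValueError(f"area {area!r} does not have exactly two states")
            p = jaccard_partition(sets[labels[0]], sets[labels[1]])
            rows.append((scale, area, "", labels[0], labels[1], *p.as_tuple()))
    elif scale == "areas":
        for state, sub in design.groupby("state", sort=True):
            sets = presence_sets(community.loc[sub.index], sub["area"])
            labels = sorted(sets)
            parts = [
                jaccard_partition(sets[u], sets[v])
                for i, u in enumerate(labels)
                for v in labels[i + 1 :]
            ]
            p = _mean_partition(parts)
            rows.append((scale, "", state, "all-areas", "all-areas", *p.as_tuple()))
    else:
        raise ValueError(f"unknown contrast scale {scale!r}")
    return pd.DataFrame(
        rows,
        columns=[
            "contrast_scale",
            "area",
            "state",
            "unit_a",
            "unit_b",
            "beta_jac",
            "beta_jtu",
            "beta_jne",
        ],
    )


def exclusive_species(
    community: pd.DataFrame,
    design: pd.DataFrame,
    state_col: str = "state",
    pools: dict[str, set] | None = None,
) -> pd.Series:
    """Study-wide counts of species found in exactly one state.

    By default exclusivity is *observational*: a species counts as
    exclusive to a state when it was recorded there and nowhere else.
    With finite identification effort this overstates structural
    exclusivity (a shared species can simply go unobserved in one state),
    so when the per-state species ``pools`` are known — e.g. from a
    synthetic study's ground truth — pass them to count exclusivity at
    the pool level instead.

    Returns a Series indexed by state label (plus ``"shared"``); species
    absent everywhere are ignored.
    """
    groups = design.reindex(community.index)[state_col]
    if pools is not None:
        sets = {str(k): set(v) for k, v in pools.items()}
    else:
        sets = presence_sets(community, groups)
    labels = sorted(sets)
    out = {}
    for label in labels:
        others = set().union(*(sets[o] for o in labels if o != label)) if len(labels) > 1 else set()
        out[label] = len(sets[label] - others)
    if len(labels) > 1:
        out["shared"] = len(set.intersection(*(sets[l] for l in labels)))
    return pd.Series(out, dtype=int)
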