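"""α-diversity and functional indices for nematode assemblages.

Structural indices: species richness (SR), Margalef D, Pielou J, Shannon
H′ and Hurlbert's expected number of species ES(n). Functional indices:
the trophic-diversity complement 1-ITD over the four stoma-morphology
feeding guilds (1A selective deposit feeders, 1B non-selective deposit
feeders, 2A epigrowth feeders, 2B predators/omnivores) and the maturity
index MI, the abundance-weighted mean of genus coloniser–persister (c-p)
scores.

Shannon H′ is reported in natural-log units: that is the base under which
published J, H′ and SR tabulations for this system are mutually consistent
(J = H′/ln SR). A ``base`` argument is exposed for other conventions.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "alpha_indices",
    "expected_species",
    "pooled_profile",
    "diversity_profile",
    "trophic_diversity",
    "maturity_index",
    "genus_of",
    "GUILDS",
]

GUILDS = ("1A", "1B", "2A", "2B")


def _as_counts(v) -> np.ndarray:
    counts = np.asarray(v, dtype=float)
    if counts.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if (counts < 0).any():
        raise ValueError("abundances must be non-negative")
    return counts


def alpha_indices(v, base: float = np.e) -> dict[str, float]:
    """Species richness, Margalef D, Pielou J and Shannon H′.

    * ``SR`` = number of species with count > 0
    * ``D`` = (S − 1)/ln N
    * ``H`` = −Σ pᵢ log pᵢ (log base ``base``; natural log by default)
    * ``J`` = H/log S, undefined (NaN) for S = 1

    An empty vector returns NaN for every index.
    """
    counts = _as_counts(v)
    counts = counts[counts > 0]
    if counts.size == 0:
        return {"SR": np.nan, "D": np.nan, "J": np.nan, "H": np.nan}
    n = counts.sum()
    s = counts.size
    p = counts / n
    h = float(-(p * np.log(p)).sum() / np.log(base))
    d = float((s - 1) / np.log(n)) if n > 1 else 0.0
    j = float(h * np.log(base) / np.log(s)) if s > 1 else np.nan
    return {"SR": float(s), "D": d, "J": j, "H": h}


def expected_species(v, n: int) -> float:
    """Hurlbert rarefaction ES(n): expected species in a random subsample
    of ``n`` individuals drawn without replacement.

    ``ES(n) = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)]`` evaluated through log-gamma
    ratios, so large counts never overflow. Returns NaN when ``n``
    exceeds the available total N (mirrors "not available" entries for
    under-sampled units).
    """
    counts = _as_counts(v)
    counts = counts[counts > 0]
    if counts.size == 0 or n < 1:
        return np.nan
    total = counts.sum()
    if n > total:
        return np.nan

    def logcomb(a: np.ndarray, b: float) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = total - counts
    with np.errstate(invalid="ignore"):
        ratio = np.where(
            rest >= n, np.exp(logcomb(rest, n) - logcomb(total, n)), 0.0
        )
    return float(np.sum(1.0 - ratio))


def pooled_profile(
    vectors: pd.DataFrame,
    es_levels: Iterable[int] = (22, 51),
) -> dict[str, float]:
    """Diversity profile of the assemblage pooled over a set of samples.

    Counts are *summed* across the pooled unit before any index is
    computed (cumulative pooling, not averaging of per-sample indices):
    site-level pooling of the identified replicates gives point diversity,
    state-level pooling gives habitat diversity.
    """
    pooled = vectors.sum(axis=0) if isinstance(vectors, pd.DataFrame) else vectors
    out = alpha_indices(pooled)
    for level in es_levels:
        out[f"ES{level}"] = expected_species(pooled, level)
    return out


def trophic_diversity(guild_counts) -> float:
    """Trophic-diversity complement 1-ITD = 1 − Σ gₖ².

    ``gₖ`` is the relative contribution of guild k to classified
    individuals; the guild set is fixed at the four feeding types, so the
    index ranges over [0, 0.75]. All-zero counts return NaN.
    """
    if isinstance(guild_counts, dict):
        guild_counts = pd.Series(guild_counts)
    counts = np.asarray(guild_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("guild counts must be non-negative")
    total = counts.sum()
    if total == 0:
        return np.nan
    g = counts / total
    return float(1.0 - (g**2).sum())


def genus_of(species_name: str) -> str:
    """Genus label of a species name (first whitespace/underscore token)."""
    return str(species_name).replace("_", " ").split()[0]


def maturity_index(
    frequencies: pd.Series, cp_scores: pd.Series, missing: str = "error"
) -> float:
    """Maturity index MI = Σ ν(i)·f(i).

    ``ν(i)`` is the genus c-p score (1 colonisers … 5 persisters) and
    ``f(i)`` the relative frequency of genus i (frequencies are
    renormalised over scored genera). ``missing`` controls behaviour for
    genera lacking a score: ``"error"`` raises naming the genus,
    ``"drop"`` excludes them from the weighted mean.
    """
    freq = frequencies[frequencies > 0]
    if freq.empty:
        return np.nan
    scores = cp_scores.reindex(freq.index)
    unscored = list(scores.index[scores.isna()])
    if unscored:
        if missing == "error":
            raise KeyError(f"no c-p score for genera: {unscored}")
        freq = freq[scores.notna()]
        scores = scores.dropna()
        if freq.empty:
            return np.nan
    bad = scores[(scores < 1) | (scores > 5)]
    if len(bad):
        raise ValueError(f"c-p scores outside 1..5 for {list(bad.index)}")
    weights = freq / freq.sum()
    return float((weights * scores).sum())


def diversity_profile(
    species_counts: pd.Series,
    traits: pd.DataFrame,
    es_levels: Iterable[int] = (22, 51),
) -> dict[str, float]:
    """Full structural + functional profile for one pooled assemblage.

    ``traits`` carries per-species rows (``level == "species"``) with
    ``guild`` and ``cp_score`` columns; MI is computed at genus level by
    aggregating species frequencies over their genus epithet.
    """
    out = pooled_profile(species_counts.to_frame().T, es_levels=es_levels)
    sp = traits.loc[traits["level"] == "species"].set_index("name")
    present = species_counts[species_counts > 0]
    guilds = pd.Series(0.0, index=list(GUILDS))
    for name, count in present.items():
        if name in sp.index:
            guild = sp.at[name, "guild"]
            if guild in guilds.index:
                guilds[guild] += count
    out["itd"] = trophic_diversity(guilds)
    genus_freq = present.groupby(present.index.map(genus_of)).sum()
    genus_cp = (
        sp["cp_score"].groupby(sp.index.map(genus_of)).first()
        if len(sp)
        else pd.Series(dtype=float)
    )
    out["mi"] = maturity_index(genus_freq, genus_cp, missing="drop")
    return out
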