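"""Distance-based permutational inference for the nested sampling design.

The sampling layout has three crossed/nested factors: State (fixed, barren
vs meadow), Area (fixed) and Site (random, nested in State × Area), with
replicates within sites. All inference is distance-based in the
McArdle–Anderson framework: the total sum of squared interpoint
dissimilarities is partitioned through the Gower-centred inner-product
matrix ``G = −½ J D² J`` and projector traces ``tr(H G)``.

Mixed-model logic follows expected mean squares: fixed terms (State, Area,
State × Area) are tested over the Site(State × Area) mean square, the
random Site term over the residual. Significance is obtained by
permutation of the exchangeable units appropriate to each term — whole
sites for fixed terms (restricted to strata of the other fixed factor),
replicates within cells for the Site term — falling back to exact
enumeration when the permutation space is smaller than the requested
count.

Also here: PERMDISP (homogeneity of multivariate dispersions), SIMPER
(per-taxon decomposition of Bray–Curtis dissimilarity), DistLM-style
forward selection on distance matrices, and log-response-ratio effect
sizes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "distance_matrix",
    "gower_center",
    "permanova",
    "pairwise_tests",
    "permdisp",
    "simper",
    "distlm_forward",
    "log_response_ratio",
    "effect_table",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# distances


def distance_matrix(data: pd.DataFrame, metric: str = "bray-curtis") -> pd.DataFrame:
    """Square symmetric dissimilarity matrix between sample rows.

    ``"bray-curtis"`` works on untransformed non-negative data;
    a pair of all-zero samples is defined to have distance 0 (with a
    warning). ``"euclidean-normalized"`` z-scores every column (the
    PRIMER meaning of "normalisation") before Euclidean distance;
    zero-variance columns are dropped.
    """
    x = data.to_numpy(dtype=float)
    if metric in ("bray-curtis", "braycurtis"):
        if (x < 0).any():
            raise ValueError("Bray-Curtis requires non-negative data")
        with np.errstate(invalid="ignore", divide="ignore"):
            d = squareform(pdist(x, metric="braycurtis"))
        if np.isnan(d).any():
            warnings.warn(
                "all-zero sample pair(s) under Bray-Curtis; distance set to 0",
                stacklevel=2,
            )
            d = np.nan_to_num(d, nan=0.0)
    elif metric in ("euclidean-normalized", "euclidean"):
        if metric == "euclidean-normalized":
            sd = x.std(axis=0, ddof=1)
            keep = sd > 0
            x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
        d = squareform(pdist(x, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=data.index, columns=data.index)


def gower_center(d: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Gower-centred inner-product matrix ``G = −½ J D∘D J``."""
    a = -0.5 * np.asarray(d, dtype=float) ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _trace_group(g: np.ndarray, codes: np.ndarray, k: int) -> float:
    """tr(H G) for the group-mean projector of an integer label vector.

    On a doubly centred G the intercept contributes nothing, so this is
    the between-group sum of squares of the grouping."""
    z = np.zeros((len(codes), k))
    z[np.arange(len(codes)), codes] = 1.0
    m = z.T @ g @ z
    return float((np.diag(m) / z.sum(axis=0)).sum())


def _codes(labels) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    return codes, len(uniques)


def _interaction(*label_arrays) -> np.ndarray:
    combined = pd.Series(list(zip(*[np.asarray(a) for a in label_arrays])))
    return combined.to_numpy()


def _is_balanced(codes: np.ndarray, k: int) -> bool:
    counts = np.bincount(codes, minlength=k)
    return bool((counts == counts[0]).all())


def _ss_additive(g: np.ndarray, f1, f2) -> float:
    """tr(H G) for the additive two-factor model [1, f1, f2].

    Balanced designs use the orthogonal shortcut H = H1 + H2 − H0; the
    general case falls back to a QR projector on dummy codes."""
    c1, k1 = _codes(f1)
    c2, k2 = _codes(f2)
    cc, kk = _codes(_interaction(f1, f2))
    if _is_balanced(cc, kk):
        return _trace_group(g, c1, k1) + _trace_group(g, c2, k2)
    x = np.hstack(
        [
            np.ones((len(c1), 1)),
            np.eye(k1)[c1][:, 1:],
            np.eye(k2)[c2][:, 1:],
        ]
    )
    q, _ = np.linalg.qr(x)
    return float(np.trace(q.T @ g @ q))


@dataclass
class PermResult:
    """One line of a permutational ANOVA table."""

    term: str
    df: int
    ss: float
    ms: float
    statistic: float
    p_perm: float
    n_perm: int
    method: str = "sampled"

    @property
    def pseudo_f(self) -> float:
        return self.statistic


def _results_frame(results: list[PermResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "df": r.df,
                "SS": r.ss,
                "MS": r.ms,
                "pseudo_F": r.statistic,
                "p_perm": r.p_perm,
                "n_perm": r.n_perm,
                "method": r.method,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _partition(g, design, factors, site, unit_cells=None):
    """Sequential partition of tr(G) for the supported designs.

    ``unit_cells`` fixes the physical site-unit identities: under
    permutation of fixed-factor labels the sample→site-unit partition
    must not change, so the Site(cells) grouping is always built from the
    *original* cell labels (passed here) crossed with the site labels.
    """
    n = g.shape[0]
    total = float(np.trace(g))
    parts = {}  # name -> (ss, df)
    f_labels = [design[f].to_numpy() for f in factors]
    c1, k1 = _codes(f_labels[0])
    b1 = _trace_group(g, c1, k1)
    parts[factors[0]] = (b1, k1 - 1)
    cum = b1
    cells = f_labels[0]
    k_cells = k1
    if len(factors) == 2:
        c2, k2 = _codes(f_labels[1])
        b_add = _ss_additive(g, f_labels[0], f_labels[1])
        parts[factors[1]] = (b_add - b1, k2 - 1)
        cells = _interaction(*f_labels)
        cc, k_cells = _codes(cells)
        b_cells = _trace_group(g, cc, k_cells)
        parts[f"{factors[0]} x {factors[1]}"] = (
            b_cells - b_add,
            (k_cells - 1) - (k1 - 1) - (k2 - 1),
        )
        cum = b_cells
    elif len(factors) > 2:
        raise ValueError("at most two crossed fixed factors are supported")
    if site is not None:
        base_cells = cells if unit_cells is None else unit_cells
        sc, k_sc = _codes(_interaction(base_cells, design[site].to_numpy()))
        b_site = _trace_group(g, sc, k_sc)
        parts[f"{site}({' x '.join(factors)})"] = (b_site - cum, k_sc - k_cells)
        cum = b_site
    parts["residual"] = (total - cum, n - 1 - sum(df for _, df in parts.values()))
    return parts, total


def _perm_space_size(strata_codes, tested_codes) -> float:
    """Number of distinct label arrangements under stratified shuffling."""
    from math import factorial

    total = 1.0
    for s in np.unique(strata_codes):
        labels = tested_codes[strata_codes == s]
        counts = np.bincount(labels - labels.min())
        size = factorial(len(labels))
        for c in counts:
            size //= factorial(int(c))
        total *= size
    return total


def _enumerate_arrangements(strata_codes, tested_labels):
    """All distinct stratified arrangements of ``tested_labels``."""
    strata = np.unique(strata_codes)
    per_stratum = []
    for s in strata:
        idx = np.flatnonzero(strata_codes == s)
        opts = sorted({tuple(p) for p in itertools.permutations(tested_labels[idx])})
        per_stratum.append((idx, opts))
    for combo in itertools.product(*(opts for _, opts in per_stratum)):
        out = np.array(tested_labels, dtype=object)
        for (idx, _), labels in zip(per_stratum, combo):
            out[idx] = labels
        yield out


def _permuted_labels(rng, strata_codes, tested_labels):
    out = np.array(tested_labels, dtype=object)
    for s in np.unique(strata_codes):
        idx = np.flatnonzero(strata_codes == s)
        out[idx] = out[idx[rng.permutation(len(idx))]]
    return out


def permanova(
    dm: pd.DataFrame,
    design: pd.DataFrame,
    factors: tuple[str, ...] | list[str],
    site: str | None = None,
    n_perm: int = 4999,
    seed=None,
    terms: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA for the nested mixed design.

    Parameters
    ----------
    dm
        Square dissimilarity matrix (DataFrame, index aligned with
        ``design``).
    design
        One row per sample with the factor columns.
    factors
        One or two crossed fixed factors (e.g. ``("state", "area")``).
    site
        Column naming the random factor nested in the cells of the fixed
        factors; ``None`` for a purely fixed model tested over residual.
    n_perm
        Requested permutations; fewer are used (exactly enumerated) when
        the restricted permutation space is smaller.
    terms
        Restrict the (costly) permutation p-values to these terms; all
        rows of the partition are still reported.

    Returns
    -------
    ANOVA-style table with df, SS, MS, pseudo-F and permutation p per
    term. Pseudo-F for fixed terms uses the Site mean square as
    denominator when ``site`` is given; the Site term (and everything in
    fixed-only models) is tested over the residual mean square.
    """
    factors = tuple(factors)
    design = design.loc[dm.index]
    g = gower_center(dm.to_numpy())
    rng = np.random.default_rng(seed)
    unit_cells = (
        _interaction(*[design[f].to_numpy() for f in factors])
        if site is not None
        else None
    )
    parts, _ = _partition(g, design, factors, site, unit_cells)
    names = list(parts)
    res_name = "residual"
    site_name = names[-2] if site is not None else None

    ms = {name: (ss / df if df > 0 else np.nan) for name, (ss, df) in parts.items()}

    def denom_name(term: str) -> str:
        if site is not None and term != site_name:
            return site_name
        return res_name

    results: list[PermResult] = []
    for term in names[:-1]:
        ss, df = parts[term]
        if df <= 0:
            continue
        f_obs = ms[term] / ms[denom_name(term)]
        if terms is None or term in terms:
            p, used, method = _permanova_p(
                g, design, factors, site, term, f_obs, n_perm, rng, unit_cells
            )
        else:
            p, used, method = np.nan, 0, "skipped"
        results.append(PermResult(term, df, ss, ms[term], f_obs, p, used, method))
    ss_r, df_r = parts[res_name]
    results.append(
        PermResult(res_name, df_r, ss_r, ms[res_name], np.nan, np.nan, 0, "")
    )
    return _results_frame(results)


def _permanova_f(
    g, design, factors, site, term, tested_labels=None, tested_factor=None,
    unit_cells=None,
):
    """Recompute the pseudo-F of ``term`` for (possibly permuted) labels."""
    d = design
    if tested_labels is not None:
        d = design.copy()
        d[tested_factor] = tested_labels
    parts, _ = _partition(g, d, factors, site, unit_cells)
    names = list(parts)
    site_name = names[-2] if site is not None else None
    ss, df = parts[term]
    num = ss / df
    if site is not None and term != site_name:
        dss, ddf = parts[site_name]
    else:
        dss, ddf = parts["residual"]
    return num / (dss / ddf)


def _permanova_p(g, design, factors, site, term, f_obs, n_perm, rng, unit_cells=None):
    """Permutation p for one term under unit-level exchangeability."""
    factors = tuple(factors)
    is_site_term = site is not None and term.startswith(f"{site}(")
    is_interaction = " x " in term

    if is_site_term:
        # replicates exchangeable across sites within each fixed-factor cell
        cells = _interaction(*[design[f].to_numpy() for f in factors])
        strata, _ = _codes(cells)
        tested = design[site].to_numpy()
        tested_factor = site
        unit_index = None  # sample-level
    else:
        # whole sites exchangeable; restrict within the other fixed factor
        tested_factor = term if not is_interaction else None
        site_labels = (
            _interaction(*[design[f].to_numpy() for f in factors], design[site].to_numpy())
            if site is not None
            else None
        )
        if site_labels is not None:
            unit_ids, unit_first = np.unique(site_labels, return_index=True)
            unit_of_sample = np.searchsorted(
                unit_ids, site_labels
            )
            unit_index = (unit_of_sample, unit_first)
        else:
            unit_index = None
        others = [f for f in factors if f != term]
        if is_interaction or not others:
            strata_samples = np.zeros(len(design), dtype=int)
        else:
            strata_samples, _ = _codes(design[others[0]].to_numpy())
        if is_interaction:
            # free shuffling of units among cells tests the joint null
            tested_factor = "__cells__"
            tested_samples = _interaction(*[design[f].to_numpy() for f in factors])
        else:
            tested_samples = design[tested_factor].to_numpy()
        if unit_index is not None:
            unit_of_sample, unit_first = unit_index
            strata = strata_samples[unit_first]
            tested = tested_samples[unit_first]
        else:
            strata = strata_samples
            tested = tested_samples

    def f_for(unit_labels):
        if is_site_term or unit_index is None:
            sample_labels = unit_labels
        else:
            unit_of_sample, _ = unit_index
            sample_labels = np.asarray(unit_labels, dtype=object)[unit_of_sample]
        if tested_factor == "__cells__":
            d = design.copy()
            pairs = [tuple(t) for t in sample_labels]
            for j, f in enumerate(factors):
                d[f] = [p[j] for p in pairs]
            return _permanova_f(g, d, factors, site, term, unit_cells=unit_cells)
        return _permanova_f(
            g, design, factors, site, term, sample_labels, tested_factor,
            unit_cells=unit_cells,
        )

    space = _perm_space_size(strata, _codes(tested)[0])
    if space <= n_perm:
        stats = np.array([f_for(lab) for lab in _enumerate_arrangements(strata, tested)])
        p = float((stats >= f_obs - _EPS).sum() / len(stats))
        return p, int(len(stats)), "exact"
    stats = np.empty(n_perm)
    for i in range(n_perm):
        stats[i] = f_for(_permuted_labels(rng, strata, tested))
    p = float(((stats >= f_obs - _EPS).sum() + 1) / (n_perm + 1))
    return p, n_perm, "sampled"


def pairwise_tests(
    dm: pd.DataFrame,
    design: pd.DataFrame,
    factor: str,
    site: str | None = None,
    n_perm: int = 4999,
    seed=None,
) -> pd.DataFrame:
    """Pairwise pseudo-t comparisons between the levels of one factor.

    Each pair is the two-level sub-design PERMANOVA with
    ``t = sqrt(pseudo-F)``. No multiplicity correction is applied (raw
    pairwise outcomes are reported; correct downstream if desired).
    """
    design = design.loc[dm.index]
    levels = sorted(pd.unique(design[factor]))
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        mask = design[factor].isin([a, b]).to_numpy()
        if mask.sum() < 4:
            continue
        sub_dm = dm.loc[mask, mask]
        sub_design = design.loc[mask]
        table = permanova(
            sub_dm,
            sub_design,
            factors=(factor,),
            site=site,
            n_perm=n_perm,
            seed=rng.integers(2**31 - 1),
        )
        row = table.iloc[0]
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": float(np.sqrt(row["pseudo_F"])),
                "p_perm": row["p_perm"],
                "n_perm": row["n_perm"],
                "method": row["method"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PERMDISP


def _pcoa_coords(dm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary parts.

    Negative eigenvalues of the Gower matrix (non-Euclidean
    dissimilarities) are kept as a separate "imaginary" block whose
    squared distances are subtracted, the standard bookkeeping for
    dispersion analysis."""
    g = gower_center(dm)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = np.abs(evals).max() * 1e-10 if evals.size else 0.0
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return real, imag


def _center(points: np.ndarray, how: str) -> np.ndarray:
    if how == "centroid" or len(points) == 0:
        return points.mean(axis=0)
    # geometric (spatial) median by Weiszfeld iteration
    c = points.mean(axis=0)
    for _ in range(200):
        d = np.linalg.norm(points - c, axis=1)
        d = np.where(d < 1e-12, 1e-12, d)
        new = (points / d[:, None]).sum(axis=0) / (1.0 / d).sum()
        if np.linalg.norm(new - c) < 1e-10:
            return new
        c = new
    return c


def permdisp(
    dm: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 4999,
    seed=None,
    center: str = "centroid",
) -> PermResult:
    """Homogeneity of multivariate dispersions (PERMDISP).

    Embeds the dissimilarity matrix by principal coordinates, measures
    every sample's distance to its group centre (centroid by default,
    spatial median optionally) with imaginary-axis correction, and tests
    equality of mean distances by an ANOVA F whose p-value comes from
    permuting the distances among groups.
    """
    groups = groups.loc[dm.index]
    codes, k = _codes(groups.to_numpy())
    if k < 2:
        raise ValueError("PERMDISP needs at least two groups")
    counts = np.bincount(codes, minlength=k)
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    real, imag = _pcoa_coords(dm.to_numpy())
    n = len(codes)
    z = np.empty(n)
    for gidx in range(k):
        mask = codes == gidx
        c_real = _center(real[mask], center)
        d2 = ((real[mask] - c_real) ** 2).sum(axis=1)
        if imag.shape[1]:
            c_imag = _center(imag[mask], center)
            d2 = d2 - ((imag[mask] - c_imag) ** 2).sum(axis=1)
        z[mask] = np.sqrt(np.clip(d2, 0.0, None))

    def anova_f(values: np.ndarray) -> float:
        grand = values.mean()
        ss_b = sum(
            counts[gi] * (values[codes == gi].mean() - grand) ** 2 for gi in range(k)
        )
        ss_w = sum(
            ((values[codes == gi] - values[codes == gi].mean()) ** 2).sum()
            for gi in range(k)
        )
        if ss_w < _EPS:
            return np.inf if ss_b > _EPS else np.nan
        return (ss_b / (k - 1)) / (ss_w / (n - k))

    f_obs = anova_f(z)
    if np.isnan(f_obs):
        return PermResult("dispersion", k - 1, 0.0, 0.0, np.nan, np.nan, 0, "degenerate")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p = anova_f(z[rng.permutation(n)])
        if not np.isnan(f_p) and f_p >= f_obs - _EPS:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermResult("dispersion", k - 1, np.nan, np.nan, float(f_obs), p, n_perm)


# ---------------------------------------------------------------------------
# SIMPER


def simper(community: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-taxon contributions to average between-group Bray–Curtis
    dissimilarity between exactly two groups.

    For every between-group sample pair the taxon term
    ``|xᵢ − yᵢ| / Σ(x + y)`` is averaged over pairs; the contributions sum
    to the average dissimilarity. Output rows are ranked by contribution
    and include cumulative percentages.
    """
    groups = groups.loc[community.index]
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("SIMPER compares exactly two groups")
    xa = community.loc[groups == levels[0]].to_numpy(dtype=float)
    xb = community.loc[groups == levels[1]].to_numpy(dtype=float)
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("empty group in SIMPER")
    contrib = np.zeros(community.shape[1])
    n_pairs = 0
    for i in range(len(xa)):
        diffs = np.abs(xa[i] - xb)  # (nb, p)
        denoms = (xa[i] + xb).sum(axis=1)
        ok = denoms > 0
        contrib += (diffs[ok] / denoms[ok, None]).sum(axis=0)
        n_pairs += int(ok.sum())
    if n_pairs == 0:
        raise ValueError("no valid between-group pairs")
    contrib = contrib / n_pairs
    avg = contrib.sum()
    out = pd.DataFrame(
        {
            "taxon": community.columns,
            "contribution": contrib,
            "pct_contribution": 100.0 * contrib / avg if avg > 0 else 0.0,
        }
    ).sort_values("contribution", ascending=False, ignore_index=True)
    out["cum_pct"] = out["pct_contribution"].cumsum()
    out.attrs["average_dissimilarity"] = float(avg)
    out.attrs["groups"] = (levels[0], levels[1])
    return out


# ---------------------------------------------------------------------------
# DistLM forward selection


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(np.column_stack([np.ones(len(x)), x]))
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def distlm_forward(
    dm: pd.DataFrame,
    predictors: pd.DataFrame,
    n_perm: int = 4999,
    seed=None,
    criterion: str = "adjusted_r2",
) -> pd.DataFrame:
    """Forward selection of predictors explaining a dissimilarity matrix.

    Distance-based redundancy analysis: the proportion of tr(G) explained
    by a predictor set X is ``R² = tr(H_X G)/tr(G)``. At each step the
    candidate maximizing adjusted R² joins the model; selection stops when
    no candidate improves it. Each added term gets a sequential pseudo-F
    and a p-value by permutation of residuals under the reduced
    (already-selected) model. Collinear candidates (no rank gain) are
    skipped.

    Returns a table with one row per selected predictor: marginal R²,
    sequential (added) R², cumulative and adjusted R², pseudo-F and p.
    """
    predictors = predictors.loc[dm.index]
    g = gower_center(dm.to_numpy())
    n = g.shape[0]
    total = float(np.trace(g))
    if total <= 0:
        raise ValueError("degenerate response: zero total sum of squares")
    rng = np.random.default_rng(seed)
    x_all = {c: predictors[c].to_numpy(dtype=float) for c in predictors.columns}

    marginal = {
        c: float(np.trace(_hat(x[:, None]) @ g)) / total for c, x in x_all.items()
    }

    def adj(r2: float, m: int) -> float:
        if n - m - 1 <= 0:
            return -np.inf
        return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)

    selected: list[str] = []
    rows = []
    current_r2, current_adj = 0.0, 0.0
    while True:
        best = None
        x_sel = (
            np.column_stack([x_all[c] for c in selected])
            if selected
            else np.empty((n, 0))
        )
        h_sel = _hat(x_sel)
        rank_sel = int(round(np.trace(h_sel)))
        b_sel = float(np.trace(h_sel @ g))
        for cand in predictors.columns:
            if cand in selected:
                continue
            x_new = np.column_stack([x_sel, x_all[cand]])
            h_new = _hat(x_new)
            if int(round(np.trace(h_new))) <= rank_sel:
                warnings.warn(f"predictor {cand!r} is collinear; skipped", stacklevel=2)
                continue
            b_new = float(np.trace(h_new @ g))
            r2 = b_new / total
            m = len(selected) + 1
            score = adj(r2, m) if criterion == "adjusted_r2" else r2
            if best is None or score > best[0]:
                best = (score, cand, r2, b_new, h_new, m)
        if best is None:
            break
        score, cand, r2, b_new, h_new, m = best
        if criterion == "adjusted_r2" and score <= current_adj and selected:
            break
        df_res = n - m - 1
        f_obs = (b_new - b_sel) / ((total - b_new) / df_res)
        resid = np.eye(n) - h_sel
        g_r = resid @ g @ resid
        exceed = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            g_p = g_r[np.ix_(idx, idx)]
            b_sel_p = float(np.trace(h_sel @ g_p))
            b_new_p = float(np.trace(h_new @ g_p))
            tot_p = float(np.trace(g_p))
            f_p = (b_new_p - b_sel_p) / ((tot_p - b_new_p) / df_res)
            if f_p >= f_obs - _EPS:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
        rows.append(
            {
                "step": len(selected) + 1,
                "predictor": cand,
                "marginal_r2": marginal[cand],
                "r2_added": r2 - current_r2,
                "cum_r2": r2,
                "adj_r2": adj(r2, m),
                "pseudo_F": f_obs,
                "p_perm": p,
                "n_perm": n_perm,
            }
        )
        selected.append(cand)
        current_r2, current_adj = r2, adj(r2, m)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# effect sizes


def log_response_ratio(
    barren_mean: float,
    meadow_mean: float,
    barren_sd: float = 0.0,
    meadow_sd: float = 0.0,
    n_barren: int = 1,
    n_meadow: int = 1,
) -> tuple[float, float]:
    """Log-response ratio ``R = ln(X_B / X_M)`` with delta-method SE.

    ``se² = sd_B²/(n_B·X_B²) + sd_M²/(n_M·X_M²)``. Non-positive means
    leave the ratio undefined (NaN, NaN).
    """
    if not (barren_mean > 0 and meadow_mean > 0):
        return (np.nan, np.nan)
    r = float(np.log(barren_mean / meadow_mean))
    se = float(
        np.sqrt(
            barren_sd**2 / (n_barren * barren_mean**2)
            + meadow_sd**2 / (n_meadow * meadow_mean**2)
        )
    )
    return r, se


def effect_table(
    values: pd.DataFrame,
    value_cols: list[str],
    barren_label: str = "Barren",
    meadow_label: str = "Meadow",
) -> pd.DataFrame:
    """Per-area and cumulative log-response effect sizes.

    ``values`` holds one row per replicate with ``area`` and ``state``
    columns. For every variable and area, R = ln(mean in barrens / mean
    in meadows) with delta-method SE; the cumulative row is the unweighted
    mean of area effects, its SE = sqrt(Σ seᵢ²)/k over areas with defined
    effects.
    """
    rows = []
    areas = sorted(pd.unique(values["area"]))
    for col in value_cols:
        per_area = []
        for area in areas:
            sub = values[values["area"] == area]
            xb = sub.loc[sub["state"] == barren_label, col].dropna()
            xm = sub.loc[sub["state"] == meadow_label, col].dropna()
            if len(xb) == 0 or len(xm) == 0:
                continue
            r, se = log_response_ratio(
                xb.mean(), xm.mean(), xb.std(ddof=1) if len(xb) > 1 else 0.0,
                xm.std(ddof=1) if len(xm) > 1 else 0.0, len(xb), len(xm)
            )
            rows.append({"variable": col, "area": area, "R": r, "se": se})
            if np.isfinite(r):
                per_area.append((r, se))
        if per_area:
            rs = np.array([r for r, _ in per_area])
            ses = np.array([se for _, se in per_area])
            rows.append(
                {
                    "variable": col,
                    "area": "all",
                    "R": float(rs.mean()),
                    "se": float(np.sqrt((ses**2).sum()) / len(ses)),
                }
            )
    return pd.DataFrame(rows)
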