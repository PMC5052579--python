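"""End-to-end orchestration: inputs → derived tables → inference outputs.

``run_pipeline`` executes the full analysis in stage order — sediment
biochemistry, standing stocks, α-diversity, β-partitions, then the
permutational inference suite and effect sizes — writing every result as
CSV into the output directory together with a serialized config and a
stage log, so a run is reproducible from its own provenance.

``validate_printed`` machine-checks the internal identities of the
bundled published summary tables (BPC additivity, the Pielou relation,
β-partition additivity, the per-area taxon-loss range) using the
package's own operations.
"""

from __future__ import annotations

import dataclasses
import itertools
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta_diversity, diversity, io, organic_matter, perm_stats, printed
from .organic_matter import CarbonFactors, round_half_up
from .standing_stocks import stocks_table
from .synthetic_data import GeneratorConfig, SyntheticStudy, generate_study

__all__ = ["RunConfig", "run_pipeline", "validate_printed", "site_diversity_table", "taxa_loss_pct"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on (fully serialized as provenance)."""

    input_dir: str | None = None  # None → generate synthetically
    output_dir: str = "results/run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    community_metric: str = "bray-curtis"
    biochem_metric: str = "euclidean-normalized"
    n_perm: int = 4999
    seed: int = 1
    c_factors: CarbonFactors = field(default_factory=CarbonFactors)
    es_levels: tuple[int, int] = (22, 51)

    def to_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        return yaml.safe_dump(payload, sort_keys=False)


def _load_study(config: RunConfig) -> SyntheticStudy:
    if config.input_dir is None:
        return generate_study(config.generator)
    d = Path(config.input_dir)
    samples = io.read_samples(d / "samples.csv")
    meio = io.read_community(d / "meiofauna.csv")
    nema = io.read_community(d / "nematodes.csv")
    traits = io.read_traits(d / "traits.csv")
    return SyntheticStudy(config.generator, samples, meio, nema, traits, truth=None)


def site_diversity_table(nematodes, meiofauna, traits, design, es_levels):
    """Per-site (identified replicates pooled) and per-state profiles."""
    rows = []
    for (area, state, site), sub in design.loc[nematodes.index].groupby(
        ["area", "state", "site"], sort=True
    ):
        pooled = nematodes.loc[sub.index].sum(axis=0)
        prof = diversity.diversity_profile(pooled, traits, es_levels=es_levels)
        meio_sub = meiofauna.loc[
            meiofauna.index.intersection(
                design.index[
                    (design["area"] == area)
                    & (design["state"] == state)
                    & (design["site"] == site)
                ]
            )
        ]
        n_taxa = float((meio_sub > 0).sum(axis=1).mean()) if len(meio_sub) else np.nan
        rows.append(
            {"scale": "site", "area": area, "state": state, "site": site,
             "richness_taxa": n_taxa, **prof}
        )
    for (area, state), sub in design.loc[nematodes.index].groupby(
        ["area", "state"], sort=True
    ):
        pooled = nematodes.loc[sub.index].sum(axis=0)
        prof = diversity.diversity_profile(pooled, traits, es_levels=es_levels)
        rows.append(
            {"scale": "state", "area": area, "state": state, "site": "pooled",
             "richness_taxa": np.nan, **prof}
        )
    return pd.DataFrame(rows)


def _replicate_diversity(nematodes, meiofauna, traits, design, es_levels):
    """Per-replicate indices, the sampling units of effect sizes."""
    rows = []
    for sid in nematodes.index:
        prof = diversity.diversity_profile(
            nematodes.loc[sid], traits, es_levels=es_levels[:1]
        )
        rows.append({"sample_id": sid, **prof})
    rep = pd.DataFrame(rows).set_index("sample_id")
    rep["richness_taxa"] = (meiofauna.loc[rep.index] > 0).sum(axis=1)
    return rep.join(design[["area", "state"]])


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages and write the result bundle to ``output_dir``.

    Returns the bundle as a dict of DataFrames keyed by output name.
    Identical config (including seed) yields byte-identical outputs.
    """
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed={config.seed} n_perm={config.n_perm}"]
    rng = np.random.default_rng(config.seed)

    def stage(name):
        log_lines.append(f"{name}: t+{time.time() - t0:.2f}s")

    study = _load_study(config)
    design = io.design_from_community(study.meiofauna.index)
    samples = study.samples
    stage("load")

    bundle: dict[str, pd.DataFrame] = {}

    # --- organic matter -------------------------------------------------
    biochem = organic_matter.derive_biochemistry(samples, config.c_factors)
    bundle["biochem_derived"] = biochem
    stage("organic_matter")

    # --- standing stocks -------------------------------------------------
    stocks = stocks_table(study.meiofauna, study.traits)
    bundle["stocks"] = stocks.join(design)
    stage("standing_stocks")

    # --- diversity --------------------------------------------------------
    bundle["diversity"] = site_diversity_table(
        study.nematodes, study.meiofauna, study.traits, design, config.es_levels
    )
    rep_div = _replicate_diversity(
        study.nematodes, study.meiofauna, study.traits, design, config.es_levels
    )
    bundle["diversity_replicates"] = rep_div.reset_index()
    stage("diversity")

    # --- beta diversity ---------------------------------------------------
    beta = pd.concat(
        [
            beta_diversity.contrast_table(study.nematodes, design, scale)
            for scale in ("sites", "states", "areas")
        ],
        ignore_index=True,
    )
    bundle["beta"] = beta
    excl = beta_diversity.exclusive_species(study.nematodes, design)
    bundle["exclusive_species"] = pd.DataFrame(
        {"state": excl.index, "n_species": excl.to_numpy()}
    )
    stage("beta_diversity")

    # --- permutational inference -----------------------------------------
    def sub_seed():
        return int(rng.integers(2**31 - 1))

    perm_tables = []
    sample_design = samples[["area", "state", "site"]].copy()
    sample_design.index = pd.Index(
        [f"b{i}" for i in range(len(samples))], name="sample_id"
    )
    for var in ("protein_mg_g", "phytopigment_ug_g", "lipid_mg_g", "carbohydrate_mg_g"):
        dm = perm_stats.distance_matrix(
            pd.DataFrame({var: samples[var].to_numpy()}, index=sample_design.index),
            "euclidean",
        )
        tab = perm_stats.permanova(
            dm, sample_design, ("state", "area"), site="site",
            n_perm=config.n_perm, seed=sub_seed(),
        )
        tab.insert(0, "analysis", f"univariate {var}")
        perm_tables.append(tab)
    biochem_mat = samples[
        ["phytopigment_ug_g", "protein_mg_g", "carbohydrate_mg_g", "lipid_mg_g"]
    ].set_axis(sample_design.index, axis=0)
    dm = perm_stats.distance_matrix(biochem_mat, config.biochem_metric)
    tab = perm_stats.permanova(
        dm, sample_design, ("state", "area"), site="site",
        n_perm=config.n_perm, seed=sub_seed(),
    )
    tab.insert(0, "analysis", "multivariate biochemistry")
    perm_tables.append(tab)

    for name, mat in (("abundance", stocks[["abundance_ind_10cm2"]]),
                      ("biomass", stocks[["biomass_ugc_10cm2"]])):
        dm = perm_stats.distance_matrix(mat, "euclidean")
        tab = perm_stats.permanova(
            dm, design, ("state", "area"), site="site",
            n_perm=config.n_perm, seed=sub_seed(),
        )
        tab.insert(0, "analysis", f"univariate {name}")
        perm_tables.append(tab)

    dm_meio = perm_stats.distance_matrix(study.meiofauna, config.community_metric)
    tab = perm_stats.permanova(
        dm_meio, design, ("state", "area"), site="site",
        n_perm=config.n_perm, seed=sub_seed(),
    )
    tab.insert(0, "analysis", "meiofaunal community")
    perm_tables.append(tab)

    dm_nema = perm_stats.distance_matrix(study.nematodes, config.community_metric)
    nema_design = design.loc[study.nematodes.index]
    tab = perm_stats.permanova(
        dm_nema, nema_design, ("state", "area"), site="site",
        n_perm=config.n_perm, seed=sub_seed(),
    )
    tab.insert(0, "analysis", "nematode assemblage")
    perm_tables.append(tab)

    # per-area tests of State on the meiofaunal community
    for area in sorted(design["area"].unique()):
        mask = design["area"] == area
        tab = perm_stats.permanova(
            dm_meio.loc[mask.to_numpy(), mask.to_numpy()],
            design.loc[mask.to_numpy()],
            ("state",), site="site", n_perm=config.n_perm, seed=sub_seed(),
        )
        tab.insert(0, "analysis", f"meiofaunal community | {area}")
        perm_tables.append(tab)
    bundle["permanova"] = pd.concat(perm_tables, ignore_index=True)
    stage("permanova")

    # pairwise area contrasts within each state (forced per-state analysis)
    pw_tables = []
    for state in sorted(design["state"].unique()):
        mask = (design["state"] == state).to_numpy()
        pw = perm_stats.pairwise_tests(
            dm_meio.loc[mask, mask], design.loc[mask], "area",
            site="site", n_perm=config.n_perm, seed=sub_seed(),
        )
        pw.insert(0, "state", state)
        pw_tables.append(pw)
    bundle["pairwise"] = pd.concat(pw_tables, ignore_index=True)
    stage("pairwise")

    disp = perm_stats.permdisp(
        dm_meio, design["state"], n_perm=config.n_perm, seed=sub_seed()
    )
    bundle["permdisp"] = pd.DataFrame(
        [{"analysis": "meiofaunal community by state", "F": disp.statistic,
          "p_perm": disp.p_perm, "n_perm": disp.n_perm}]
    )
    stage("permdisp")

    simper_rows = []
    for area in sorted(design["area"].unique()):
        mask = (design["area"] == area).to_numpy()
        tab = perm_stats.simper(study.meiofauna.loc[mask], design.loc[mask, "state"])
        top = ", ".join(tab["taxon"].head(3))
        simper_rows.append(
            {"contrast": f"barren vs meadow | {area}",
             "avg_dissimilarity_pct": 100 * tab.attrs["average_dissimilarity"],
             "top_taxa": top}
        )
    for state in sorted(design["state"].unique()):
        sub = design[design["state"] == state]
        for a1, a2 in itertools.combinations(sorted(sub["area"].unique()), 2):
            mask = sub["area"].isin([a1, a2])
            tab = perm_stats.simper(
                study.meiofauna.loc[sub.index[mask]], sub.loc[mask, "area"]
            )
            simper_rows.append(
                {"contrast": f"{a1} vs {a2} | {state}",
                 "avg_dissimilarity_pct": 100 * tab.attrs["average_dissimilarity"],
                 "top_taxa": ", ".join(tab["taxon"].head(3))}
            )
    bundle["simper"] = pd.DataFrame(simper_rows)
    stage("simper")

    # DistLM: site-scale diversity against environment
    site_div = bundle["diversity"].query("scale == 'site'")
    site_key = site_div[["area", "state", "site"]]
    biochem_site = (
        biochem.assign(bpc=biochem["bpc_mg_g"])
        .groupby(["area", "state", "site"], sort=True)[
            ["bpc", "protein_c", "carbohydrate_c", "lipid_c", "phytopigment_c"]
        ]
        .mean()
        .reset_index()
    )
    merged = site_key.merge(biochem_site, on=["area", "state", "site"], how="left")
    coverage_map = (
        study.truth.barren_coverage_pct
        if study.truth is not None
        else dict(
            samples.groupby("area")["barren_coverage_pct"].first()
            if "barren_coverage_pct" in samples.columns
            else {}
        )
    )
    merged["barren_coverage_pct"] = merged["area"].map(coverage_map)
    response = site_div[["richness_taxa", "SR"]].copy()
    response.index = pd.Index(range(len(response)))
    merged.index = response.index
    predictors = merged[
        ["barren_coverage_pct", "bpc", "protein_c", "carbohydrate_c",
         "lipid_c", "phytopigment_c"]
    ].dropna(axis=1, how="all")
    dm_resp = perm_stats.distance_matrix(response, "euclidean-normalized")
    bundle["distlm"] = perm_stats.distlm_forward(
        dm_resp, predictors, n_perm=config.n_perm, seed=sub_seed()
    )
    stage("distlm")

    # effect sizes (forest-plot data)
    stock_vals = bundle["stocks"].rename(
        columns={"abundance_ind_10cm2": "abundance",
                 "biomass_ugc_10cm2": "biomass",
                 "individual_biomass_ugc": "individual_biomass"}
    )
    eff_stocks = perm_stats.effect_table(
        stock_vals, ["abundance", "biomass", "individual_biomass"]
    )
    biochem_vals = biochem.assign(bpc=biochem["bpc_mg_g"])
    eff_biochem = perm_stats.effect_table(
        biochem_vals, ["protein_c", "carbohydrate_c", "lipid_c",
                       "phytopigment_c", "bpc"]
    )
    eff_div = perm_stats.effect_table(
        rep_div, ["richness_taxa", "SR", "H", "J", f"ES{config.es_levels[0]}",
                  "itd", "mi"]
    )
    bundle["effects"] = pd.concat(
        [eff_stocks, eff_biochem, eff_div], ignore_index=True
    )
    stage("effects")

    # β vs barren coverage (plot data; no shape asserted)
    states_beta = beta[beta["contrast_scale"] == "states"].copy()
    states_beta["barren_coverage_pct"] = states_beta["area"].map(coverage_map)
    bundle["beta_coverage"] = states_beta[
        ["area", "barren_coverage_pct", "beta_jac", "beta_jtu", "beta_jne"]
    ]
    stage("beta_coverage")

    for name, df in bundle.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "config.yaml").write_text(config.to_yaml())
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle


# ---------------------------------------------------------------------------
# printed-table identity checks


def validate_printed(
    t1a: pd.DataFrame | None = None,
    t1b: pd.DataFrame | None = None,
    t3: pd.DataFrame | None = None,
    bpc_tol: float = 0.1,
    pielou_tol: float = 0.05,
    beta_tol: float = 0.01,
    taxa_loss_range: tuple[int, int] = (26, 47),
) -> pd.DataFrame:
    """Machine-check the published tables' internal identities.

    Each check row reports the computed quantity, the printed one, the
    tolerance and a pass flag; perturbing any input value fails the
    corresponding named row.
    """
    t1a = t1a if t1a is not None else printed.table1a()
    t1b = t1b if t1b is not None else printed.table1b()
    t3 = t3 if t3 is not None else printed.table3()
    rows = []

    carbon = organic_matter.carbon_equivalents(t1a)
    bpc = organic_matter.biopolymeric_c(carbon)
    for i, row in t1a.iterrows():
        rows.append(
            {
                "check": "bpc_sum",
                "row": f"{row['area']} {row['state']} {row['site']}",
                "computed": float(bpc[i]),
                "printed": float(row["bpc_mg_g"]),
                "tolerance": bpc_tol,
                "passed": abs(bpc[i] - row["bpc_mg_g"]) <= bpc_tol,
            }
        )

    for _, row in t1b.iterrows():
        j = row["shannon"] / np.log(row["sr"]) if row["sr"] > 1 else np.nan
        rows.append(
            {
                "check": "pielou_identity",
                "row": f"{row['area']} {row['state']} {row['site']}",
                "computed": float(j),
                "printed": float(row["pielou"]),
                "tolerance": pielou_tol,
                "passed": bool(abs(j - row["pielou"]) <= pielou_tol),
            }
        )

    for _, row in t3.iterrows():
        gap = abs(row["beta_jac"] - (row["beta_jtu"] + row["beta_jne"]))
        rows.append(
            {
                "check": "beta_additivity",
                "row": f"{row['scale']} {row['area']} {row['state']}".strip(),
                "computed": float(row["beta_jtu"] + row["beta_jne"]),
                "printed": float(row["beta_jac"]),
                "tolerance": beta_tol,
                "passed": bool(gap <= beta_tol + 1e-12),
            }
        )

    losses = taxa_loss_pct(t1b)
    lo, hi = int(losses.min()), int(losses.max())
    rows.append(
        {
            "check": "taxa_loss_range",
            "row": "all areas",
            "computed": float(lo),
            "printed": float(taxa_loss_range[0]),
            "tolerance": 0.0,
            "passed": (lo, hi) == taxa_loss_range,
        }
    )
    rows.append(
        {
            "check": "taxa_loss_range",
            "row": "all areas (max)",
            "computed": float(hi),
            "printed": float(taxa_loss_range[1]),
            "tolerance": 0.0,
            "passed": (lo, hi) == taxa_loss_range,
        }
    )
    return pd.DataFrame(rows)


def taxa_loss_pct(t1b: pd.DataFrame | None = None) -> pd.Series:
    """Per-area % loss of mean higher-taxon richness in barrens relative
    to meadows, rounded to integer percentages."""
    t1b = t1b if t1b is not None else printed.table1b()
    means = t1b.groupby(["area", "state"], sort=True)["n_taxa"].mean().unstack()
    barren_col = [c for c in means.columns if c.lower().startswith("barren")][0]
    meadow_col = [c for c in means.columns if c.lower().startswith("meadow")][0]
    loss = 100.0 * (1.0 - means[barren_col] / means[meadow_col])
    return pd.Series(round_half_up(loss, 0), index=loss.index).astype(int)
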