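"""Synthetic studies emulating the alternative-states sampling design.

The generator reproduces the field layout — six areas, two states
(macroalgal meadow vs barren) per area, two sites per state, five
meiofauna replicates and three sediment-biochemistry replicates per
site — and imposes known multiplicative state effects so that every
downstream estimator can be checked against ground truth:

* barrens suppress total meiofaunal abundance (default ×0.2) with a
  body-size tilt: small-bodied taxa are suppressed more than large-bodied
  ones, which lowers total biomass but *raises* mean individual biomass,
  the compositional mechanism behind the individual-biomass response;
* barrens carry a structurally reduced nematode species pool (meadow- and
  barren-exclusive subsets are absent from the other state's pool by
  construction) scaled by a richness effect;
* barrens reduce protein, lipid and phytopigment concentrations
  (default ×0.5); carbohydrates are deliberately left unaffected, since
  sediment carbohydrate pools do not track the state contrast.

All noise terms are mean-one lognormals so the generating state means —
and hence the imposed log-response ratios ``ln(barren/meadow)`` recorded
in :class:`GroundTruth` — are exact expectations, not approximations.
Nematode species counts arise by multinomial subsampling of (at most) 100
individuals per identified replicate from the site's species
relative-abundance vector, mirroring bench practice of identifying 100
specimens or all of them when fewer were retrieved.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "GroundTruth", "SyntheticStudy", "generate_study", "write_fixtures"]

#: Higher-taxon pool; the first five are structurally meadow-exclusive.
MEADOW_EXCLUSIVE_TAXA = (
    "Priapulida",
    "Gnathostomulida",
    "Gastrotricha",
    "Holothuroidea",
    "Thermosbaenacea",
)
SHARED_TAXA = (
    "Nematoda",
    "Copepoda",
    "Polychaeta",
    "Ostracoda",
    "Kinorhyncha",
    "Halacaroidea",
    "Amphipoda",
    "Isopoda",
    "Tanaidacea",
    "Cumacea",
    "Turbellaria",
    "Oligochaeta",
    "Bivalvia",
    "Gastropoda",
    "Cnidaria",
    "Tardigrada",
    "Sipuncula",
    "Echinodermata",
    "Rotifera",
)

BIOCHEM_VARS = ("phytopigment_ug_g", "protein_mg_g", "carbohydrate_mg_g", "lipid_mg_g")

#: Meadow-state mean concentrations (units as the column names).
MEADOW_BIOCHEM_MEANS = {
    "phytopigment_ug_g": 500.0,
    "protein_mg_g": 10.0,
    "carbohydrate_mg_g": 13.0,
    "lipid_mg_g": 2.5,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Design counts, state effects and noise levels of one synthetic study."""

    n_areas: int = 6
    n_sites_per_state: int = 2
    n_meio_reps: int = 5
    n_biochem_reps: int = 3
    n_nematode_ids_per_rep: int = 100
    n_identified_reps: int = 3
    pool_taxa: int = 24
    pool_species: int = 174
    exclusive_meadow_taxa: int = 5
    exclusive_meadow_species: int = 78
    exclusive_barren_species: int = 12
    barren_effect_abundance: float = 0.2
    barren_effect_richness: float = 0.6
    barren_effect_biochem: float = 0.5
    abundance_dispersion: float = 0.5
    barren_coverage_pct: tuple[float, ...] | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.exclusive_meadow_species + self.exclusive_barren_species > self.pool_species:
            raise ValueError("exclusive species subsets exceed the species pool")
        if self.exclusive_meadow_taxa > self.pool_taxa:
            raise ValueError("exclusive taxa exceed the taxon pool")
        for name in ("barren_effect_abundance", "barren_effect_richness", "barren_effect_biochem"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be a positive multiplicative effect")
        if self.barren_coverage_pct is not None:
            cov = tuple(float(c) for c in self.barren_coverage_pct)
            if len(cov) != self.n_areas:
                raise ValueError("barren_coverage_pct needs one value per area")
            if any(not (0 <= c <= 100) for c in cov):
                raise ValueError("coverage percentages must lie in [0, 100]")
            object.__setattr__(self, "barren_coverage_pct", cov)
        else:
            # default coverage gradient: patchy barrens in the western
            # areas through fully formed barrens in the eastern ones
            base = np.linspace(25.0, 100.0, self.n_areas)
            object.__setattr__(
                self, "barren_coverage_pct", tuple(float(x) for x in base)
            )


@dataclass
class GroundTruth:
    """Generating parameters needed for parameter-recovery tests."""

    area_state_means: pd.DataFrame  # rows area×state, columns variables
    meadow_species: list[str]
    barren_species: list[str]
    exclusive_meadow_species: list[str]
    exclusive_barren_species: list[str]
    meadow_taxa: list[str]
    barren_taxa: list[str]
    imposed_log_response: pd.DataFrame  # rows area, columns variables
    barren_coverage_pct: dict[str, float]

    def to_json(self) -> str:
        payload = {
            "area_state_means": self.area_state_means.reset_index().to_dict(orient="list"),
            "meadow_species": self.meadow_species,
            "barren_species": self.barren_species,
            "exclusive_meadow_species": self.exclusive_meadow_species,
            "exclusive_barren_species": self.exclusive_barren_species,
            "meadow_taxa": self.meadow_taxa,
            "barren_taxa": self.barren_taxa,
            "imposed_log_response": self.imposed_log_response.reset_index().to_dict(orient="list"),
            "barren_coverage_pct": self.barren_coverage_pct,
        }
        return json.dumps(payload, indent=1)


@dataclass
class SyntheticStudy:
    """One complete generated study and its provenance."""

    config: GeneratorConfig
    samples: pd.DataFrame  # biochemistry replicates
    meiofauna: pd.DataFrame  # samples × higher taxa, ind / 10 cm²
    nematodes: pd.DataFrame  # identified samples × species counts
    traits: pd.DataFrame
    truth: GroundTruth


def _mean_one_lognormal(rng, sigma, size=None):
    """Lognormal noise with expectation exactly 1."""
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _taxon_pool(config: GeneratorConfig) -> list[str]:
    names = list(MEADOW_EXCLUSIVE_TAXA[: config.exclusive_meadow_taxa])
    shared_needed = config.pool_taxa - len(names)
    shared = list(SHARED_TAXA)
    while len(shared) < shared_needed:
        shared.append(f"Taxon{len(shared) + 1:02d}")
    return names + shared[:shared_needed]


def _species_pool(config: GeneratorConfig, rng) -> tuple[list[str], pd.DataFrame]:
    """Species names, genus assignment, guilds and c-p scores."""
    n_genera = max(10, config.pool_species // 3)
    genus_names = [f"Genus{g + 1:03d}" for g in range(n_genera)]
    genus_of_species = rng.integers(0, n_genera, size=config.pool_species)
    counters: dict[int, int] = {}
    names = []
    for gidx in genus_of_species:
        counters[gidx] = counters.get(gidx, 0) + 1
        names.append(f"{genus_names[gidx]}_sp{counters[gidx]}")
    # feeding-guild frequencies follow the dominance order typical of
    # hard-bottom assemblages: epigrowth feeders >> predators > deposit feeders
    guilds = rng.choice(["2A", "2B", "1B", "1A"], p=[0.55, 0.2, 0.15, 0.1],
                        size=config.pool_species)
    genus_cp = rng.choice([1, 2, 3, 4, 5], p=[0.1, 0.35, 0.3, 0.15, 0.1], size=n_genera)
    cp = genus_cp[genus_of_species]
    table = pd.DataFrame(
        {"name": names, "guild": guilds, "cp_score": cp.astype(float)}
    )
    return names, table


def generate_study(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Draw one full synthetic study under ``config`` (see module docstring)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    areas = [f"Area{i + 1}" for i in range(config.n_areas)]
    states = ("Barren", "Meadow")
    sites = [f"Site{i + 1}" for i in range(config.n_sites_per_state)]

    # ------------------------------------------------------------------ taxa
    taxa = _taxon_pool(config)
    exclusive_taxa = taxa[: config.exclusive_meadow_taxa]
    # decreasing geometric base abundances over a shuffled dominance order,
    # anchored so total meadow abundance is ~250 ind / 10 cm²
    dominance = np.concatenate(
        [
            # exclusives are uncommon; dominant taxa are shared
            rng.uniform(8, 20, size=config.exclusive_meadow_taxa),
            250.0 * 0.62 ** np.arange(config.pool_taxa - config.exclusive_meadow_taxa),
        ]
    )
    total = dominance.sum()
    meadow_taxon_means = pd.Series(dominance * 250.0 / total, index=taxa)

    # individual biomass per taxon (μg C): lognormal sizes, with the two
    # dominants pinned to their field contrast (nematodes small-bodied,
    # copepods an order of magnitude heavier); the barren suppression
    # factor is tilted by body size so small-bodied taxa lose relatively
    # more individuals — the compositional route to a higher mean
    # individual biomass in barrens
    indiv_biomass = pd.Series(
        np.exp(rng.normal(np.log(0.15), 0.9, size=config.pool_taxa)), index=taxa
    )
    if "Nematoda" in indiv_biomass.index:
        indiv_biomass["Nematoda"] = 0.04
    if "Copepoda" in indiv_biomass.index:
        indiv_biomass["Copepoda"] = 0.5
    small = indiv_biomass < indiv_biomass.median()
    tilt = np.where(small, 1.5, 0.4)
    barren_factor = np.minimum(config.barren_effect_abundance ** tilt, 1.0)
    barren_taxon_means = meadow_taxon_means * barren_factor
    barren_taxon_means[exclusive_taxa] = 0.0

    # --------------------------------------------------------------- species
    species, species_traits = _species_pool(config, rng)
    order = rng.permutation(config.pool_species)
    meadow_excl = [species[i] for i in order[: config.exclusive_meadow_species]]
    barren_excl = [
        species[i]
        for i in order[
            config.exclusive_meadow_species : config.exclusive_meadow_species
            + config.exclusive_barren_species
        ]
    ]
    shared_species = [
        species[i]
        for i in order[config.exclusive_meadow_species + config.exclusive_barren_species :]
    ]
    meadow_pool = meadow_excl + shared_species
    target_barren = int(round(config.barren_effect_richness * len(meadow_pool)))
    n_shared_in_barren = min(
        len(shared_species), max(0, target_barren - len(barren_excl))
    )
    barren_pool = barren_excl + shared_species[:n_shared_in_barren]

    base_weight = pd.Series(
        np.exp(rng.normal(0.0, 1.2, size=config.pool_species)), index=species
    )

    # ------------------------------------------------------------- biochem
    area_mult = {a: _mean_one_lognormal(rng, 0.35, len(BIOCHEM_VARS)) for a in areas}
    biochem_effect = {
        "phytopigment_ug_g": config.barren_effect_biochem,
        "protein_mg_g": config.barren_effect_biochem,
        "carbohydrate_mg_g": 1.0,  # carbohydrates do not track the state contrast
        "lipid_mg_g": config.barren_effect_biochem,
    }

    mean_rows = []
    for area in areas:
        for state in states:
            row = {"area": area, "state": state}
            for j, var in enumerate(BIOCHEM_VARS):
                eff = biochem_effect[var] if state == "Barren" else 1.0
                row[var] = MEADOW_BIOCHEM_MEANS[var] * area_mult[area][j] * eff
            taxon_means = barren_taxon_means if state == "Barren" else meadow_taxon_means
            row["abundance"] = float(taxon_means.sum())
            row["biomass"] = float((taxon_means * indiv_biomass).sum())
            row["individual_biomass"] = row["biomass"] / row["abundance"]
            mean_rows.append(row)
    area_state_means = pd.DataFrame(mean_rows).set_index(["area", "state"])

    imposed = {}
    for area in areas:
        bar = area_state_means.loc[(area, "Barren")]
        mea = area_state_means.loc[(area, "Meadow")]
        imposed[area] = {
            var: float(np.log(bar[var] / mea[var])) if bar[var] > 0 and mea[var] > 0 else np.nan
            for var in area_state_means.columns
        }
    imposed_df = pd.DataFrame(imposed).T
    imposed_df.index.name = "area"

    # -------------------------------------------------------------- samples
    sample_rows = []
    meio_rows = {}
    nema_rows = {}
    coverage = dict(zip(areas, config.barren_coverage_pct))
    for area in areas:
        for state in states:
            pool = barren_pool if state == "Barren" else meadow_pool
            taxon_means = barren_taxon_means if state == "Barren" else meadow_taxon_means
            for site in sites:
                site_mult_biochem = _mean_one_lognormal(rng, 0.2, len(BIOCHEM_VARS))
                site_mult_fauna = _mean_one_lognormal(rng, 0.3)
                # site-level species relative abundances on the state pool
                w = base_weight[pool].to_numpy() * _mean_one_lognormal(
                    rng, 0.8, len(pool)
                )
                p_site = w / w.sum()
                for rep in range(1, config.n_biochem_reps + 1):
                    row = {
                        "area": area,
                        "state": state,
                        "site": site,
                        "replicate": rep,
                        "barren_coverage_pct": coverage[area],
                    }
                    for j, var in enumerate(BIOCHEM_VARS):
                        mean = area_state_means.loc[(area, state), var] * site_mult_biochem[j]
                        row[var] = mean * _mean_one_lognormal(rng, 0.25)
                    sample_rows.append(row)
                for rep in range(1, config.n_meio_reps + 1):
                    sample_id = f"{area}_{state}_{site}_r{rep}"
                    lam = (
                        taxon_means.to_numpy()
                        * site_mult_fauna
                        * _mean_one_lognormal(rng, config.abundance_dispersion)
                    )
                    counts = rng.poisson(lam)
                    meio_rows[sample_id] = pd.Series(counts, index=taxa)
                    if rep <= config.n_identified_reps:
                        available = int(counts[taxa.index("Nematoda")])
                        n_ids = min(config.n_nematode_ids_per_rep, available)
                        sp_counts = (
                            rng.multinomial(n_ids, p_site)
                            if n_ids > 0
                            else np.zeros(len(pool), dtype=int)
                        )
                        nema_rows[sample_id] = pd.Series(sp_counts, index=pool)

    samples = pd.DataFrame(sample_rows)
    meiofauna = pd.DataFrame.from_dict(meio_rows, orient="index").fillna(0).astype(int)
    meiofauna = meiofauna[taxa]
    meiofauna.index.name = "sample_id"
    nematodes = (
        pd.DataFrame.from_dict(nema_rows, orient="index").fillna(0).astype(int)
    )
    nematodes = nematodes.reindex(columns=species, fill_value=0)
    nematodes.index.name = "sample_id"

    trait_rows = [
        {
            "name": t,
            "level": "taxon",
            "guild": "",
            "cp_score": np.nan,
            "biovol_factor": np.nan,
            "individual_biomass_ugc": indiv_biomass[t],
        }
        for t in taxa
    ]
    # biovolume conversion factors around the nematode constant, so the
    # biovolumetric route stays available for measured specimens
    biovol = np.exp(rng.normal(np.log(0.063e-5), 0.5, size=config.pool_taxa))
    for row, f in zip(trait_rows, biovol):
        row["biovol_factor"] = float(f)
    for _, sp_row in species_traits.iterrows():
        trait_rows.append(
            {
                "name": sp_row["name"],
                "level": "species",
                "guild": sp_row["guild"],
                "cp_score": sp_row["cp_score"],
                "biovol_factor": np.nan,
                "individual_biomass_ugc": np.nan,
            }
        )
    traits = pd.DataFrame(trait_rows)

    truth = GroundTruth(
        area_state_means=area_state_means,
        meadow_species=meadow_pool,
        barren_species=barren_pool,
        exclusive_meadow_species=meadow_excl,
        exclusive_barren_species=barren_excl,
        meadow_taxa=taxa,
        barren_taxa=[t for t in taxa if t not in exclusive_taxa],
        imposed_log_response=imposed_df,
        barren_coverage_pct=coverage,
    )
    return SyntheticStudy(config, samples, meiofauna, nematodes, traits, truth)


def write_fixtures(
    study: SyntheticStudy, directory: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Serialize a study to the flat-CSV exchange format.

    Emits ``samples.csv``, ``meiofauna.csv``, ``nematodes.csv``,
    ``traits.csv`` and ``truth.json``; refuses to clobber existing files
    unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": directory / "samples.csv",
        "meiofauna": directory / "meiofauna.csv",
        "nematodes": directory / "nematodes.csv",
        "traits": directory / "traits.csv",
        "truth": directory / "truth.json",
    }
    if not overwrite:
        clashes = [str(p) for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(f"refusing to overwrite: {clashes}")
    study.samples.to_csv(paths["samples"], index=False)
    study.meiofauna.to_csv(paths["meiofauna"])
    study.nematodes.to_csv(paths["nematodes"])
    study.traits.to_csv(paths["traits"], index=False)
    paths["truth"].write_text(study.truth.to_json())
    config_path = directory / "generator_config.json"
    config_path.write_text(json.dumps(dataclasses.asdict(study.config), indent=1))
    paths["config"] = config_path
    return paths
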