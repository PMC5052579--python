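# meiostates

Quantitative comparison of the two alternative states of Mediterranean
shallow hard bottoms — erect macroalgal meadows and urchin-grazed barren
grounds — through the lens of the sediment-dwelling meiofauna: sedimentary
organic-matter biochemistry, meiofaunal standing stocks, nematode α-, β-
and functional diversity, and distance-based permutational inference over
a nested sampling design. It is written for benthic ecologists who want a
tested, scriptable re-implementation of the standard PRIMER-style analysis
chain for meadow/barren (or any two-state) comparisons, plus a synthetic
study generator with known ground truth for validating every estimator.

## What it computes

**Sediment food availability.** Protein, carbohydrate and lipid
concentrations are converted to carbon equivalents (0.49, 0.40, 0.75 mg C
per mg) and summed into biopolymeric carbon, BPC = C_prt + C_cho + C_lip;
nutritional quality is described by the protein-C share of BPC, the
phytopigment-C share and the protein:carbohydrate ratio.

**Standing stocks.** Body volume V = L·W²·c (the nematode constant is
c = 0.063·10⁻⁵ with L, W in μm and V in nL), wet weight from a tissue
density of 1.13 g cm⁻³, carbon as 40 % of dry weight; per-sample
abundance (ind. 10 cm⁻²), biomass (μg C 10 cm⁻²) and mean individual
biomass.

**α- and functional diversity.** SR, Margalef D = (S−1)/ln N, Shannon
H′ (log_e), Pielou J = H′/ln S, Hurlbert rarefaction
ES(n) = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)] at n = 22 (point diversity, site-pooled)
and n = 51 (habitat diversity, state-pooled); the trophic-diversity
complement 1-ITD = 1 − Σ g² over the four feeding guilds (1A, 1B, 2A, 2B)
and the maturity index MI = Σ ν(i)·f(i) over genus c-p scores.

**β-diversity.** Pairwise Jaccard dissimilarity partitioned into turnover
and nestedness-resultant components (β_jac = β_jtu + β_jne, with
β_jtu = 2 min(b,c)/(a + 2 min(b,c))), at three scales: sites within each
area and state, states within each area, areas within each state.

**Inference.** PERMANOVA for the mixed model State (fixed) × Area (fixed)
with Site random and nested in State × Area — fixed terms tested over the
Site mean square, permutation of whole-site units with exact enumeration
when the permutation space is small; pairwise pseudo-t tests; PERMDISP
(distances to group centroids in principal-coordinate space, with
negative-eigenvalue correction); SIMPER decomposition of Bray–Curtis
dissimilarity; DistLM-style forward selection on adjusted R² with
Freedman–Lane permutation; and log-response-ratio effect sizes
R = ln(X_barren / X_meadow) with delta-method standard errors.

## Worked example

Generate a synthetic study with the survey's layout (6 areas × 2 states ×
2 sites; 5 meiofauna and 3 sediment replicates per site; 100 nematodes
identified in 3 replicates), then run the full pipeline:

```bash
python analysis/01_generate_study.py --seed 1
python analysis/06_inference.py --seed 1 --n-perm 999
```

The first command reports the imposed state effects (ground truth), e.g.
for Area1:

```
abundance            -1.460
biomass              -0.933
individual_biomass    0.527
```

i.e. barrens are built with ~4.3× fewer meiofaunal individuals, ~2.5×
less biomass, but *larger-bodied* individuals on average (small-bodied
taxa are suppressed hardest). The second command recovers exactly this
signature from the generated data:

```
meiofaunal community, State term: pseudo-F=53.54 p=0.0010 (999 permutations)
cumulative effect sizes (ln barren/meadow):
          variable      R    se
         abundance -1.335 0.105
           biomass -0.799 0.105
individual_biomass  0.541 0.016
                SR -1.791 0.108
                 J  0.033 0.011
```

Stocks and richness come out strongly negative, individual biomass
positive, evenness (J) indistinguishable from zero — the forest-plot sign
pattern expected of a meadow→barren shift. `effects.csv`, `beta.csv`,
`permanova.csv` etc. are written under `results/inference/`.

The same operations run from the shell via the console script:
`meiostates generate`, `meiostates run`, `meiostates validate`.

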