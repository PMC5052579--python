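# Methods

This note documents the models, conventions and numerical choices behind
`meiostates`, in the order data flow through the pipeline.

## Sampling design and data model

All analyses assume the three-factor layout of a two-state benthic
survey: **State** (fixed; meadow vs barren), **Area** (fixed; six
geographic areas), **Site** (random, nested in State × Area; two sites),
with five replicate samples per site for fauna and three for sediment
biochemistry. Nematodes are identified to species in three of the five
faunal replicates, 100 individuals per replicate or all of them when
fewer were retrieved — so species counts are a multinomial subsample of
the assemblage, not a census, and all richness comparisons must respect
that (hence rarefaction).

Data travel as flat CSV: a sample table of biochemistry replicates,
samples × taxa and samples × species count matrices keyed by
`sample_id = Area_State_Site_rN`, and a trait table (per-taxon biovolume
conversion factor and mean individual biomass; per-species feeding guild
and genus c-p score).

## Organic matter

Concentrations convert to carbon equivalents with 0.49 (protein), 0.40
(carbohydrate) and 0.75 (lipid) mg C per mg — the standard factors of the
sediment-biochemistry protocols, overridable via `CarbonFactors`. Their
sum is biopolymeric carbon (BPC). Conventions fixed by internal
consistency of published per-site tabulations for this system:

* the protein share of BPC is computed on **carbon** equivalents;
* the protein:carbohydrate ratio is computed on **raw mass**
  concentrations (C-based ratios are not consistent with the published
  column);
* the phytopigment→C factor (default 40 μg C per μg pigment) is exposed
  but *untrusted*: no single factor reconciles the published
  phytopigment-share column across sites, so `pct_phyto_bpc` should be
  read as a relative index only.

Zero denominators (BPC or carbohydrate = 0) propagate as NaN
("not available"), never as zero. Report rounding is half-away-from-zero
at one decimal, matching the published presentation; full-precision
values are always retained in the CSV outputs.

## Standing stocks

Biovolume V = L·W²·c with L, W in **μm** and V in nL (nematode constant
c = 0.063·10⁻⁵). Statements of this formula sometimes print "mm", which
is dimensionally inconsistent — with mm inputs a typical nematode would
come out nine orders of magnitude too small; μm inputs reproduce the
nanolitre volumes standard in the meiobenthos literature, so μm is the
contract here. Wet weight = V × 1.13 g cm⁻³; carbon = 40 % of dry weight
with a dry:wet ratio of 0.25 (standard meiobenthos practice; the
alternative convention of applying 40 % to wet weight directly is
available behind `apply_dry_wet=False`, since published methods rarely
state which was used). For synthetic runs the trait table supplies mean
individual biomass per taxon directly, bypassing specimen-level
measurement. Individual biomass = biomass/abundance, undefined for empty
samples.

## Diversity

Shannon H′ uses the natural log: the published site table heads the
column "H′(log_e)" and only ln makes the printed J, H′ and SR mutually
consistent; the base is an argument for other conventions. ES(n) is
Hurlbert's expectation evaluated through log-gamma ratios (no factorials,
stable for arbitrarily large counts); n larger than the available total
returns NaN. Pooling for ES is **cumulative** — counts are summed across
the pooled unit before rarefying — with site-level pooling of the three
identified replicates giving point diversity (ES22) and state-level
pooling giving habitat diversity (ES51). 1-ITD is computed over the fixed
four-guild set, so its maximum is 0.75; lumping guilds can only lower it,
which is why a published 1-ITD may exceed what lumped percentage columns
imply. MI operates at genus level (c-p scores are genus-level by
definition); species epithets are stripped, unscored genera either raise
an error or drop with renormalisation. Undefined indices are excluded
pairwise from downstream means, never imputed as zero.

## β-diversity

Pairwise Baselga-family Jaccard partition on presence/absence after
pooling (presence = pooled count ≥ 1; no abundance weighting):
β_jac = (b+c)/(a+b+c), β_jtu = 2·min(b,c)/(a+2·min(b,c)),
β_jne = β_jac − β_jtu, additive by construction. Multi-unit contrasts
(areas within a state) report the mean of pairwise partitions, re-closed
on the means so additivity survives averaging; multiple-site (non-pairwise)
variants are out of scope. The β-vs-coverage output pairs each area's
state contrast with its barren-coverage percentage and asserts nothing
about the relationship's shape.

Exclusive-species accounting has two modes: observational (recorded in
exactly one state) and structural (membership of known state species
pools). With 100-individual subsamples the observational count
systematically overstates structural exclusivity — rare shared species go
unobserved on one side — so ground-truth comparisons use the pool mode.

## Permutational inference

All tests are distance-based in the Gower/McArdle–Anderson frame:
G = −½ J D∘D J, sum of squares of a model term = tr(H G) differences
along the sequential model, pseudo-F from mean squares. Expected-mean-
square logic for the mixed model: State, Area and State × Area are tested
over the Site(State × Area) mean square; Site over the residual. On
univariate Euclidean distances the pseudo-F reproduces classical ANOVA F
to machine precision (tested for one- and two-factor balanced designs).

**Permutation scheme.** Exchangeable units are permuted directly: whole
site units for fixed terms (restricted within the levels of the other
fixed factor, so an Area test never mixes states and vice versa;
interaction terms shuffle site units freely), and replicates within
State × Area cells for the Site term. When the restricted arrangement
space is smaller than the requested count (e.g. the per-area State test
has C(4,2) = 6 site arrangements) the space is enumerated exactly and the
result flagged `exact`; otherwise permutations are sampled and the
p-value uses the add-one convention, so p is never 0 and is reproducible
given a seed. This unit-level scheme was preferred over residual rotation
for the ANOVA terms because it is exactly valid under the null in the
balanced design; simulation over 200 effect-free studies puts the State
test's rejection rate at 0.04 at α = 0.05. A *null* study means neutral
multiplicative effects **and** no structural exclusivity — exclusive taxa
are themselves a state effect.

DistLM forward selection does use permutation of residuals under the
reduced model (Freedman–Lane on the residualized G), with adjusted R² as
the selection criterion and collinear candidates skipped; the marginal R²
of a single predictor on a univariate Euclidean response equals the
squared Pearson correlation (oracle-tested). PERMDISP embeds the
distance matrix by eigendecomposition keeping the negative-eigenvalue
block as an imaginary part whose squared distances are subtracted,
measures distances to group centroids (spatial median optional, via
Weiszfeld iteration) and permutes those distances among groups. SIMPER
averages each taxon's Bray–Curtis numerator share over all between-group
pairs; contributions sum to the average dissimilarity to 1e-10.
Pairwise tests report raw p-values (pseudo-t = √pseudo-F of the
two-level sub-design) with no multiplicity correction, mirroring standard
reporting practice for this design; correct downstream if needed.

Default permutation count is 4999 everywhere. Bray–Curtis distances come
from untransformed counts; "normalised Euclidean" z-scores each variable
(the PRIMER meaning of normalisation). A pair of all-zero samples has
Bray–Curtis distance defined as 0, with a warning.

**Effect sizes.** R = ln(X_B/X_M) per area from state means, with
delta-method SE, se² = sd_B²/(n_B X_B²) + sd_M²/(n_M X_M²); the
cumulative effect is the unweighted mean of area effects with
SE = √(Σ seᵢ²)/k. The SE formula is this package's choice — forest-plot
error bars in the literature are rarely defined. With only two sites per
state the per-area SE understates site-level variance, so parameter
recovery is assessed as unbiasedness across studies and as sign recovery,
not per-area interval coverage.

## Synthetic-data generator

The generator reproduces the survey design exactly (720 biochemistry
values, 120 faunal samples × 24 taxa, 72 identified samples × 174
species) and imposes the state contrast the system is known for:

| parameter | default | meaning |
|---|---|---|
| `barren_effect_abundance` | 0.2 | multiplicative suppression of faunal abundance in barrens (~5× lower, the order seen in per-site tabulations) |
| `barren_effect_richness` | 0.6 | barren species pool ≈ 60 % of the meadow pool (96 vs 162 species at defaults) |
| `barren_effect_biochem` | 0.5 | suppression of protein, lipid and phytopigments; carbohydrates deliberately unaffected (they do not track the contrast in the field data) |
| `abundance_dispersion` | 0.5 | lognormal σ of replicate-level abundance noise |
| `barren_coverage_pct` | 25–100 across areas | per-area barren extent, a DistLM predictor |

Structure: 78 meadow-exclusive and 12 barren-exclusive species (and 5
meadow-exclusive higher taxa) are absent from the other state's pool *by
construction*, so exclusivity is testable bookkeeping rather than an
emergent accident. Abundances are lognormal-Poisson (site-level mean-one
lognormal multipliers σ = 0.3, replicate-level σ = `abundance_dispersion`,
Poisson counts), reproducing the overdispersion of real per-site tables.
All noise is mean-one lognormal, so the generating area × state means —
and hence the imposed log-response ratios recorded in `GroundTruth` — are
exact expectations. The barren suppression is tilted by body size
(exponent 1.5 below the median individual biomass, 0.4 above; nematodes
pinned small at 0.04 μg C, copepods large at 0.5 μg C), which lowers
abundance and biomass while *raising* mean individual biomass — the
compositional mechanism behind the positive individual-biomass response
of a meadow→barren shift. Species counts arise by multinomial subsampling
of min(100, available nematodes) per identified replicate from site-level
relative abundances (lognormal species weights σ = 1.2, site jitter
σ = 0.8). One `numpy` Generator seeded once drives every draw: same seed,
byte-identical study.

What the generator does **not** emulate: spatial autocorrelation within
sites, taxonomic identification error, temporal dynamics of the regime
shift, abundance-dependent detection of higher taxa beyond Poisson
sampling, and any feedback between organic matter and fauna (biochemistry
and community are drawn independently given the state). Passing recovery
tests therefore demonstrates estimator correctness under the design's
sampling structure, not realism of any particular ecological mechanism.

## Problem sizes and determinism

Simulation-based checks run at sizes chosen to make their Monte-Carlo
error small relative to the property tested: type-I error rates use 200
null studies at 99 permutations (binomial 95 % CI half-width ±0.03 around
0.05); power and recovery checks use the default study size with 4999
permutations where a p ≤ 0.001 claim requires them. Every stochastic
routine takes an explicit seed; the pipeline derives per-stage seeds from
one master seed, and identical configuration yields byte-identical
outputs.

## Known limitations

* The mixed-model PERMANOVA supports at most two crossed fixed factors
  with one nested random factor — the design here — not arbitrary models.
* Interaction-term p-values use free unit shuffling, which tests the
  joint null rather than the pure interaction null; interpret marginally
  significant interactions cautiously.
* The published phytopigment-share column is not reproducible from any
  single pigment→C factor; the corresponding output is flagged advisory.
* Three published site rows violate J = H′/ln SR by slightly more than
  0.05; this is attributable to the two independent 1-decimal roundings
  in the printed table (bound 0.05 + 0.05/ln SR) and is reported as-is by
  `validate_printed` rather than smoothed over.
* Constrained ordination (CAP) is out of scope; unconstrained principal
  coordinates are available for plotting through the PERMDISP embedding.
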