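# Methods

This note documents the models, conventions and numerical choices behind
`poolcomm`, in the order data flows through the pipeline.

## Synthetic survey model

The generator emulates the *processed* level of a site × month amplicon
survey of small wetland pools — ASV count tables, taxonomy, sample
metadata and water chemistry — not raw reads (no sequencing error,
chimeras or primer artifacts are simulated).

**Design.** Default: 8 sites (a water inlet, six pools, an outlet) × 11
months (February excluded, as surveys of this kind commonly suspend
mid-winter sampling) = 88 samples. Sites 3–5 form the "core" zone, the
rest the "edge" (configurable). Seasons derive from calendar months
(Mar–May spring, Jun–Aug summer, Sep–Nov autumn, Dec + Jan winter).

**Chemistry.** Nine variables with fixed baselines chosen to resemble
weakly acidic, low-conductivity peatland pool water (pH 5.2 ± 0.3, DO
8 ± 1.5 mg/L, EC 40 ± 8 µS/cm, turbidity 5 ± 2 NTU, TN 0.8 ± 0.25 mg/L,
TP 0.05 ± 0.015 mg/L, COD_Mn 4 ± 1 mg/L, Chl a 5 ± 2 µg/L). Temperature
follows a sinusoid peaking in July with amplitude `temperature_amplitude`
(default 12 °C around a 14 °C mean, i.e. ~2–26 °C over the year). The four
eutrophication covariates (TN, TP, COD_Mn, Chl a) are raised by
`eutrophication_effect` baseline SDs (default 1.5) in core-zone samples
and again in summer samples.

**Communities.** Per sample, taxon log-abundances are
`baseline + forcing + noise` (log-normal compositional model; a
Dirichlet–multinomial alternative was rejected as adding a dispersion
parameter nothing downstream needs):

* baseline per taxon ~ N(0, 1.2), plus +3.0 for guild members so they
  stay above downstream prevalence/abundance filters in every site;
* chemistry forcing: selected phylum groups are linear in a z-scored
  chemistry variable with slope ±`chem_link_strength` (default 1.5) —
  by default Cyanobacteria −Temp, Proteobacteria +Temp, Bacteroidetes
  +TP (16S) and Alveolata +Temp, Stramenopiles −Temp (18S). The default
  slope puts the temperature Mantel R near 0.13, the order of magnitude
  field surveys of this kind report;
* guilds: `n_guilds` (3) groups of `guild_size` (8) bacterial ASVs drawn
  from phyla with no chemistry forcing. Each guild shares one AR(1)
  monthly trajectory per site (φ = 0.5, unit SD, scaled by 2.5 in log
  space); members add independent N(0, `guild_noise_sd`) (default 0.15).
  The generic per-taxon overdispersion (SD 0.5) applies only to non-guild
  taxa, so at `guild_noise_sd = 0` the members' latent composition series
  within a site are identical up to a positive factor (Spearman r exactly
  1; `generate_relative_abundances` exposes these latent compositions).
  Within a site the guild trajectories are orthogonalized (QR): two
  independent smooth series of 11 points correlate by chance alarmingly
  often, which would merge planted guilds into one module and make
  recovery scoring ambiguous rather than harder;
* core-zone evenness: core-sample log-abundance vectors are scaled by
  `1 + diversity_gradient` (default 1.5×), sharpening dominance and
  lowering Shannon diversity without touching ranks within a site;
* counts: multinomial at depth ~ Poisson(`sequencing_depth_mean`,
  default 50 000 reads/sample).

The 18S table mixes fungal phyla (Chytridiomycota, Basidiomycota,
Ascomycota), protist groups (Alveolata, Stramenopiles, Euglenozoa,
Chlorophyta) and the contaminant/unassigned lineages (Metazoa,
Streptophyta, Rhodophyta, Opisthokonta, unassigned) the protist-table
filter must remove; the planted truth records contaminant ids, guild
membership, within-guild pairs, chemistry–taxon links and the expected
evenness ordering so every recovery claim is checkable by id.

Each artifact (chemistry, 16S, 18S, guilds) draws from its own RNG stream
derived from the master seed by a fixed label, so regenerating one
artifact never shifts another. The null scenario (`ScenarioConfig.null`)
zeroes every effect and removes guilds; downstream false-positive
behavior is measured against it.

**What passing tests do and do not show.** The generator produces
independent Gaussian noise, a single seasonal driver, clean guild
trajectories, and taxonomically uniform lineages. Real amplicon data add
compositional coupling, zero inflation beyond the multinomial, spatial
autocorrelation among neighboring pools, and month-to-month dependence —
so recovery results here validate the machinery (filters, statistics,
thresholds, seeding), not the field performance of the survey design.

## Community tables

Counts are samples × taxa int64 internally; on disk the amplicon
convention (taxa as rows, first column the ASV id) is the default.
Rarefaction is multivariate-hypergeometric subsampling without
replacement to a fixed depth; samples below depth are dropped and logged.
The prevalence/abundance filter retains a taxon only if it is present
(count > 0) in ≥ 7 of the site's 11 monthly samples **and** sums to ≥ 12
reads — both bounds inclusive, and the two clauses combined as
AND-retention (the stricter reading of "removed if present in fewer
months … and with lower total abundance"). Filters are idempotent. The
pipeline rarefies first and filters per site afterwards; whether the
original protocol filtered raw or rarefied counts is not stated anywhere
we could find, so the order is configurable in principle but
rarefy-then-filter is the default.

## Diversity

Shannon uses the natural log (consistent with reported per-site values
near ln-scale magnitudes in comparable surveys). Chao1 defaults to the
bias-corrected form `S_obs + F₁(F₁−1)/(2(F₂+1))`; the classic
`S_obs + F₁²/(2F₂)` sits behind `bias_corrected=False`. Group contrasts
pool all months per site as replicates (the month-as-replicate reading of
per-site boxplots "over all sampling months"). ANOVA is classical one-way;
Tukey HSD uses the studentized-range distribution with the Tukey–Kramer
adjustment on unbalanced groups; letters come from insert–absorb and are
asserted consistent with the pairwise p matrix in both directions. Zero
within-group variance degenerates F; the convention is p = 0 when group
means differ (flagged), p = 1 when all values are identical.

## Ordination

NMDS minimizes Kruskal stress-1 with primary tie handling in the
isotonic regression (tied dissimilarities may reorder freely; implemented
by lex-sorting on (dissimilarity, embedded distance) before pooled
adjacent violators). Configuration updates are Guttman/SMACOF steps,
accepted only if stress does not increase (up to six step-halvings toward
the previous configuration otherwise), which makes the per-iteration
stress sequence provably non-increasing — the property the tests assert.
Twenty starts by default: one classical-scaling (PCoA) start plus
nineteen seeded random starts; best final stress wins. Coordinates are
centered, rotated to principal axes and sign-fixed purely for
reproducible output; stress is invariant to that orientation. PCA
standardizes by default because the chemistry variables mix units;
contributions are `100 · loading² / Σ loading²` per component.

## Association

The Mantel statistic correlates the upper triangles of two distance
matrices (Pearson default, Spearman option). Significance is one-sided
for positive association — the standard choice for distance–distance
tests, under which small negative statistics report as non-significant —
with `p = (1 + #{permuted R ≥ observed}) / (n_perm + 1)` over joint
row/column relabelings of one matrix (9999 by default). Permutation of
sample labels permutes the condensed distance vector, so its mean and
norm are invariant and the permuted statistics reduce to dot products;
they are evaluated in vectorized chunks. Per-variable chemistry distances
are Euclidean on z-scored values (recorded as a choice, not an inference
about any particular study's protocol).

The Pearson screen reports two-sided t-based p (df = n − 2) per cell with
no multiplicity adjustment by default, mirroring per-cell "p < 0.05"
heat-map displays; a BH option exists. Constant columns yield undefined r:
masked non-significant and flagged.

## Co-occurrence networks

Spearman correlations use midranks and the t approximation for p
(df = n − 2); with 11 samples per site an exact permutation p would add
nothing at the thresholds used. BH-FDR is applied over each site's upper
triangle, and the edge criterion is `|r| > 0.7` **and** adjusted
`p < 0.01`, both strict. Two readings deserve flagging:

* **|r| versus signed r.** A positive-only rule cannot produce the
  majority-negative edge fractions that motivate this analysis style, so
  the absolute-value reading is the default and the sign is stored per
  edge.
* **Adjusted versus raw p.** The default thresholds BH-adjusted p (the
  stricter reading); `use_raw_p=True` reproduces the raw-p behavior.

Isolated taxa are excluded from the node set. Modules come from
networkx's seeded Louvain on the unweighted, unsigned graph (resolution
1); modularity Q is computed from the partition by the standard formula.
Topology follows the conventions that make the numbers comparable with
Gephi-style reports: betweenness unnormalized; closeness per node as
`(n_c − 1)/Σd` within its connected component; clustering with degree-1
nodes contributing 0; path distance averaged over connected ordered
pairs. Module counts report only modules with **more than** 5 nodes
(strict). Zi is the within-module degree z-score with population SD and
the convention Zi = 0 when the SD is 0; Pi is `1 − Σ (k_is/k_i)²`. Role
boundaries: Zi = 2.5 and Pi = 0.62 fall on the non-hub/non-connector
side, so the four roles tile the plane with no unassigned points.
Degenerate (empty) graphs produce a flagged all-zero summary rather than
an error.

## Pipeline

Defaults are the reference protocol's parameters: rarefaction depths
44 465 (16S) and 39 865 (18S) for real-data mode; 7-month/12-read filter;
0.7/0.01 edge thresholds; 9999 Mantel permutations; α = 0.05; Zi/Pi
2.5/0.62. In simulation mode the rarefaction depth rescales to each
marker's minimum sample total (simulated depth is a free parameter); the
resolved values land in `resolved_config.json`. Networks are built only
for sites with a complete monthly series; incomplete sites are skipped
and recorded. Every stage logs its removal counts, and the run report
reconciles `taxa_out = taxa_in − taxa_removed` at each filter. No output
embeds timestamps, so runs are byte-identical under a fixed seed.

## Problem sizes used in validation

The test suite exercises: brute-force oracle comparisons on ≥ 50 random
instances per statistic (graphs ≤ 12 nodes, tolerance 1e-10); null
calibrations with 500 Mantel replicates at 999 permutations and 1000
ANOVA replicates; planted-structure recovery over 10 seeds of the full
default scenario (all 8 site networks each); and two full pipeline runs
for bytewise determinism. The default scenario's 300 + 200 taxa at
50 000 reads/sample keep these checks comfortably inside a single-CPU
run while preserving the survey's 88-sample geometry.

## Known limitations

* Correlation-based networks on compositional data are biased toward
  negative association; compositionality-aware estimators (SparCC,
  SPIEC-EASI) are out of scope by design.
* n = 11 time points bounds the detectable correlation strength; at the
  default thresholds only very strong co-occurrence survives BH, which is
  faithful to the protocol but means weak guilds are invisible.
* Months are treated as independent replicates in ANOVA and Mantel;
  temporal autocorrelation is not modeled.
* NMDS stress values on survey-like data have no external reference here;
  no claim is made about expected stress magnitudes for real communities.
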