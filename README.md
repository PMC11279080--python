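# poolcomm

Spatial–seasonal analysis of microbial communities in wetland breeding
pools: alpha diversity, ordination, environment–community association, and
per-site co-occurrence networks with keystone (Zi–Pi) classification.

`poolcomm` is aimed at microbial ecologists working with amplicon surveys
of small water bodies sampled on a site × month grid — e.g. the breeding
pools of an endangered amphibian in a *Sphagnum* peatland, monitored at 8
sites over 11 months (88 samples) with paired 16S (bacteria) and 18S
(fungi + protists) ASV tables and a 9-variable water-chemistry profile
(pH, temperature, DO, EC, turbidity, TN, TP, COD_Mn, Chl a). It packages
the full downstream chain from processed ASV tables to reportable
statistics, plus a synthetic-data generator that plants known structure so
every stage can be validated by recovery.

## What it computes

* **Alpha diversity** — Shannon–Wiener `H = −Σ pᵢ ln pᵢ` and bias-corrected
  Chao1 `S_obs + F₁(F₁−1)/(2(F₂+1))` per sample after seeded rarefaction
  (subsampling without replacement to a common depth); group contrasts by
  one-way ANOVA with Tukey HSD and a compact letter display.
* **Ordination** — Bray–Curtis dissimilarities; non-metric MDS minimizing
  Kruskal stress-1 (isotonic regression + Guttman updates, best of many
  seeded starts); PCA of standardized chemistry with per-variable %
  contributions.
* **Association** — Mantel tests (Pearson or Spearman flavor, one-sided,
  permutation p over 9999 relabelings) between community distance and
  Euclidean distance on z-scored chemistry ("All" or single variables);
  a Pearson screen of chemistry against rank-aggregated relative
  abundances (phylum level, or the top-20 genera).
* **Co-occurrence networks** — per site, over the 11 monthly samples:
  taxa filtered to ≥ 7 months' presence and ≥ 12 total reads, all-pairs
  Spearman correlation, Benjamini–Hochberg FDR adjustment, and an edge
  wherever |r| > 0.7 with adjusted p < 0.01 (sign = sign of r). Modules by
  seeded Louvain modularity maximization; topology summary (degree, edge
  sign %, modularity Q, betweenness/closeness/clustering/path length);
  node roles from within-module degree z-score Zi and participation
  coefficient Pi: network hubs (Zi > 2.5, Pi > 0.62), module hubs
  (Zi > 2.5, Pi ≤ 0.62), connectors (Pi > 0.62), peripherals.
* **Synthetic surveys** — `ScenarioConfig` / `generate_bundle` produce
  metadata, chemistry, taxonomy and count tables with a core-vs-edge
  evenness gradient, seasonal temperature forcing, eutrophication
  covariates, and planted co-occurring guilds, together with a
  `PlantedTruth` record for scoring recovery. See `docs/methods.md` for
  the model.

## Worked example

```python
import poolcomm as pc
from poolcomm import tables, diversity, network, recovery

cfg = pc.ScenarioConfig(seed=1)          # default 8-site x 11-month survey
frame, chem, t16, t18, taxonomy, truth = pc.generate_bundle(cfg)

depth = int(t16.totals().min())          # rarefy to the minimum sample total
r16 = tables.rarefy(t16, depth, seed=7)

alpha = diversity.alpha_table(r16).join(frame["zone"])
print(alpha.groupby("zone")[["shannon", "chao1"]].mean().round(2))

inlet = frame.index[frame["site"] == "Inlet"]
filtered = tables.prevalence_abundance_filter(tables.CountTable(r16.data.loc[inlet]))
graph, partition, summary, roles = network.site_network(filtered, seed=1)
print(f"Inlet 16S network: {summary.n_nodes} nodes, {summary.n_edges} edges, "
      f"Q = {summary.modularity:.3f}")
sens, n = recovery.guild_edge_sensitivity(graph, truth, filtered.taxon_ids)
print(f"planted guild pairs recovered: {sens:.2f} of {n}")
```

prints

```
      shannon   chao1
zone
core     2.40  190.59
edge     3.22  279.22
Inlet 16S network: 288 nodes, 7016 edges, Q = 0.545
planted guild pairs recovered: 1.00 of 84
```

The central pools ("core" zone) are less even by construction, so their
mean Shannon (2.40) sits below the edge pools (3.22) — the diversity
gradient the survey design is meant to detect. The Inlet network recovers
all 84 planted within-guild pairs as edges at |r| > 0.7, BH-adjusted
p < 0.01.

The same analysis runs end-to-end from the command line:

```bash
poolcomm simulate --seed 1 --out bundle/       # write the TSV bundle
poolcomm validate bundle/                      # cross-check sample ids
poolcomm all --seed 1 --out results/           # full pipeline, all outputs
```

`poolcomm all` writes alpha-diversity and Tukey tables, NMDS coordinates,
PCA scores/contributions, the Mantel property table, per-site GraphML
networks with Zi–Pi roles, a one-column-per-site topology table, and a
reconciled `run_report.json`. Runs are byte-for-byte reproducible under a
fixed seed.

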