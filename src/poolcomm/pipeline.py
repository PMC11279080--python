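"""End-to-end orchestration: simulate/ingest -> rarefy -> filter -> diversity
-> ordination -> association -> per-site networks, with a reconciled run
report and fully seeded determinism.

Defaults mirror the reference survey protocol: rarefaction depths 44465
(16S) and 39865 (18S); network-stage prevalence filter of 7 months and 12
reads; edge thresholds |r| > 0.7 with BH-adjusted p < 0.01; 9999 Mantel
permutations; Zi/Pi role thresholds 2.5 and 0.62. In simulation mode the
rarefaction depth is rescaled to each marker's minimum sample total, since
synthetic sequencing depth is a free parameter; the resolved values are
recorded in the report.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import association, diversity, network, ordination, recovery, tables
from .simulate import FUNGAL_PHYLA, PlantedTruth, ScenarioConfig, generate_bundle
from .tables import CountTable, TaxonomyTable


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 0
    output_dir: str = "poolcomm_output"
    scenario: ScenarioConfig | None = None
    input_dir: str | None = None
    rarefaction_depth_16s: int = 44465
    rarefaction_depth_18s: int = 39865
    min_months: int = 7
    min_total_reads: int = 12
    r_threshold: float = 0.7
    p_threshold: float = 0.01
    mantel_permutations: int = 9999
    alpha: float = 0.05
    zi_threshold: float = network.ZI_THRESHOLD
    pi_threshold: float = network.PI_THRESHOLD
    nmds_starts: int = 20
    scale_rarefaction_to_simulated: bool = True

    def resolved(self) -> dict:
        payload = dataclasses.asdict(self)
        if self.scenario is not None:
            payload["scenario"] = dataclasses.asdict(self.scenario)
        return payload


@dataclass
class RunReport:
    """Per-stage record of inputs, filter counts, seeds and written outputs."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def validate_inputs(paths: dict) -> dict:
    """Cross-check sample ids across community, chemistry and metadata files.

    Report-only: returns duplicate ids per file and per-table orphan
    sample ids (present in a community/chemistry table but absent from the
    metadata, or vice versa) without mutating anything.
    """
    report: dict = {"duplicates": {}, "orphans": {}, "issues": 0}
    frames = {}
    for name, path in paths.items():
        orientation_taxa_rows = name.startswith("asv")
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = list(df.columns) if orientation_taxa_rows else list(df.index)
        dups = sorted({i for i in ids if ids.count(i) > 1})
        if dups:
            report["duplicates"][name] = dups
        frames[name] = set(ids)
    if "metadata" in frames:
        reference = frames["metadata"]
        for name, ids in frames.items():
            if name in ("metadata", "taxonomy"):
                continue
            missing = sorted(reference - ids)
            extra = sorted(ids - reference)
            if missing or extra:
                report["orphans"][name] = {"missing": missing, "unexpected": extra}
    report["issues"] = len(report["duplicates"]) + len(report["orphans"])
    return report


def _load_inputs(config: PipelineConfig):
    if config.scenario is not None:
        return generate_bundle(config.scenario)
    if config.input_dir is None:
        raise ValueError("either a scenario or an input directory is required")
    d = config.input_dir
    required = ["metadata.tsv", "chemistry.tsv", "asv_16s.tsv", "asv_18s.tsv", "taxonomy.tsv"]
    missing = [f for f in required if not os.path.exists(os.path.join(d, f))]
    if missing:
        raise FileNotFoundError(f"missing required input tables: {missing}")
    frame = pd.read_csv(os.path.join(d, "metadata.tsv"), sep="\t", index_col=0)
    chem = pd.read_csv(os.path.join(d, "chemistry.tsv"), sep="\t", index_col=0)
    t16 = CountTable.read_tsv(os.path.join(d, "asv_16s.tsv"))
    t18 = CountTable.read_tsv(os.path.join(d, "asv_18s.tsv"))
    taxonomy = TaxonomyTable.read_tsv(os.path.join(d, "taxonomy.tsv"))
    truth_path = os.path.join(d, "truth.json")
    truth = PlantedTruth.from_json(truth_path) if os.path.exists(truth_path) else None
    return frame, chem, t16, t18, taxonomy, truth


def _split_eukaryotes(t18: CountTable, taxonomy: TaxonomyTable):
    """Fungal vs protist 18S sub-tables; protists get the non-target filter."""
    phyla = taxonomy.data.loc[t18.taxon_ids, "phylum"]
    fungal = [t for t, ph in phyla.items() if ph in FUNGAL_PHYLA]
    other = [t for t in t18.taxon_ids if t not in set(fungal)]
    fungi = CountTable(t18.data.loc[:, fungal])
    protist_raw = CountTable(t18.data.loc[:, other])
    protist = tables.filter_nontarget_protists(protist_raw, taxonomy)
    return fungi, protist_raw, protist


def _tsv(df: pd.DataFrame, path: str, label: str = "") -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=label or None)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and write all outputs under ``output_dir``."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    report = RunReport(config=config.resolved())

    frame, chem, t16, t18, taxonomy, truth = _load_inputs(config)
    report.record(
        "ingest",
        n_samples=len(frame),
        n_taxa_16s=t16.shape[1],
        n_taxa_18s=t18.shape[1],
        simulated=config.scenario is not None,
    )
    with open(os.path.join(out, "resolved_config.json"), "w") as fh:
        json.dump(config.resolved(), fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    report.outputs.append("resolved_config.json")

    # --- validation -------------------------------------------------------
    shared = [s for s in frame.index if s in chem.index and s in t16.data.index]
    if len(shared) < len(frame):
        report.warnings.append(
            f"{len(frame) - len(shared)} metadata samples missing from chemistry or counts"
        )
    report.record("validate", n_shared_samples=len(shared))

    # --- rarefaction ------------------------------------------------------
    depths = {"16s": config.rarefaction_depth_16s, "18s": config.rarefaction_depth_18s}
    if config.scenario is not None and config.scale_rarefaction_to_simulated:
        depths = {"16s": int(t16.totals().min()), "18s": int(t18.totals().min())}
    r16 = tables.rarefy(t16, depths["16s"], seed=[config.seed, 11])
    r18 = tables.rarefy(t18, depths["18s"], seed=[config.seed, 12])
    report.record(
        "rarefy",
        depth_16s=depths["16s"],
        depth_18s=depths["18s"],
        samples_dropped_16s=t16.shape[0] - r16.shape[0],
        samples_dropped_18s=t18.shape[0] - r18.shape[0],
        seed=config.seed,
    )

    # --- taxon filtering --------------------------------------------------
    fungi, protist_raw, protist = _split_eukaryotes(r18, taxonomy)
    report.record(
        "filter_protists",
        taxa_in=protist_raw.shape[1],
        taxa_removed=protist_raw.shape[1] - protist.shape[1],
        taxa_out=protist.shape[1],
    )
    groups = {"bacteria": r16, "fungi": fungi, "protist": protist}

    # --- alpha diversity + group comparisons ------------------------------
    meta = frame.loc[r16.sample_ids]
    for name, table in groups.items():
        alpha = diversity.alpha_table(table)
        _tsv(alpha.join(frame[["site", "month", "season", "zone"]]),
             os.path.join(out, f"alpha_{name}.tsv"), "sample_id")
        report.outputs.append(f"alpha_{name}.tsv")
        for factor in ("site", "month"):
            comparison = diversity.anova_tukey(
                alpha["shannon"], meta.loc[alpha.index, factor],
                factor=factor, alpha=config.alpha,
            )
            comparison.to_tsv(os.path.join(out, f"tukey_{name}_{factor}.tsv"))
            report.outputs.append(f"tukey_{name}_{factor}.tsv")
        report.record(f"diversity_{name}", n_samples=alpha.shape[0])

    # --- ordination -------------------------------------------------------
    distances = {}
    for i, (name, table) in enumerate(groups.items()):
        dmat = ordination.bray_curtis(table)
        distances[name] = dmat
        result = ordination.nmds(
            dmat, k=2, n_starts=config.nmds_starts, seed=[config.seed, 30, i]
        )
        coords = result.coordinates.join(frame[["site", "season"]])
        _tsv(coords, os.path.join(out, f"nmds_{name}.tsv"), "sample_id")
        report.outputs.append(f"nmds_{name}.tsv")
        report.record(f"nmds_{name}", stress=result.stress, converged=result.converged)
    chem_used = chem.loc[meta.index]
    pca_result = ordination.pca(chem_used)
    _tsv(pca_result.scores, os.path.join(out, "pca_scores.tsv"), "sample_id")
    _tsv(pca_result.contributions, os.path.join(out, "pca_contributions.tsv"), "variable")
    report.outputs.extend(["pca_scores.tsv", "pca_contributions.tsv"])
    report.record("pca", explained_pc1=float(pca_result.explained_variance_ratio.iloc[0]))

    # --- association ------------------------------------------------------
    mantel_frame = association.mantel_table(
        distances, chem_used,
        n_permutations=config.mantel_permutations, seed=[config.seed, 40],
    )
    _tsv(mantel_frame, os.path.join(out, "mantel.tsv"), "property")
    report.outputs.append("mantel.tsv")
    report.record("mantel", n_permutations=config.mantel_permutations)

    phylum_rel = tables.aggregate_relative_abundance(r16, taxonomy, "phylum")
    screen = association.pearson_screen(chem_used, phylum_rel, alpha=config.alpha)
    _tsv(screen.r, os.path.join(out, "pearson_phylum_r.tsv"), "variable")
    _tsv(screen.p, os.path.join(out, "pearson_phylum_p.tsv"), "variable")
    report.outputs.extend(["pearson_phylum_r.tsv", "pearson_phylum_p.tsv"])
    genus_rel = tables.aggregate_relative_abundance(r16, taxonomy, "genus")
    genus_screen = association.pearson_screen(
        chem_used, genus_rel, alpha=config.alpha, top_n_taxa=20
    )
    _tsv(genus_screen.r, os.path.join(out, "pearson_genus_r.tsv"), "variable")
    report.outputs.append("pearson_genus_r.tsv")
    report.record("pearson_screen", n_phyla=screen.r.shape[1], n_genera=genus_screen.r.shape[1])

    # --- per-site networks ------------------------------------------------
    all_months = list(dict.fromkeys(frame["month"]))
    taxonomy_group = {}
    for name, table in groups.items():
        for t in table.taxon_ids:
            taxonomy_group[t] = name
    summaries = {}
    for si, site in enumerate(dict.fromkeys(frame["site"])):
        site_samples = meta.index[meta["site"] == site]
        site_months = set(meta.loc[site_samples, "month"])
        if site_months != set(all_months):
            report.warnings.append(f"network skipped for {site}: incomplete monthly series")
            report.record(f"network_{site}", skipped=True)
            continue
        parts = []
        filter_in = filter_out = 0
        for name, table in groups.items():
            sub = CountTable(table.data.loc[site_samples])
            filtered = tables.prevalence_abundance_filter(
                sub, config.min_months, config.min_total_reads
            )
            filter_in += sub.shape[1]
            filter_out += filtered.shape[1]
            parts.append(filtered.data)
        pooled = CountTable(pd.concat(parts, axis=1))
        attrs = {
            "group": taxonomy_group,
            "phylum": taxonomy.data["phylum"].to_dict(),
            "genus": taxonomy.data["genus"].to_dict(),
        }
        graph, partition, summary, roles = network.site_network(
            pooled,
            r_threshold=config.r_threshold,
            p_threshold=config.p_threshold,
            seed=(config.seed * 1009 + 700 + si) % (2**31),
            node_attributes=attrs,
        )
        summaries[site] = summary.to_series()
        tag = site.replace(" ", "")
        network.write_graphml(graph, partition, roles, os.path.join(out, f"network_{tag}.graphml"))
        _tsv(roles, os.path.join(out, f"zipi_{tag}.tsv"), "ASV_ID")
        report.outputs.extend([f"network_{tag}.graphml", f"zipi_{tag}.tsv"])
        report.record(
            f"network_{site}",
            taxa_in=filter_in,
            taxa_removed=filter_in - filter_out,
            taxa_out=filter_out,
            n_nodes=summary.n_nodes,
            n_edges=summary.n_edges,
            modularity=summary.modularity,
        )
    if summaries:
        _tsv(pd.DataFrame(summaries), os.path.join(out, "network_topology.tsv"), "property")
        report.outputs.append("network_topology.tsv")

    # --- truth recovery (simulation mode only) ----------------------------
    if truth is not None and config.scenario is not None:
        alpha16 = diversity.alpha_table(r16)
        gradient = recovery.diversity_gradient_recovered(alpha16, meta)
        report.record("recovery", shannon_gradient_core_below_edge=bool(gradient))

    report.to_json(os.path.join(out, "run_report.json"))
    report.outputs.append("run_report.json")
    return report
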