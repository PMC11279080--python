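"""Synthetic multi-marker community generator for a pool-survey design.

Emulates the processed data level of a year-long wetland survey: 8 sampling
sites (a water inlet, six breeding pools, a water outlet) visited in 11
months (no February), yielding 88 water samples, each with

* a 9-variable water-chemistry profile (pH, temperature, DO, EC, turbidity,
  TN, TP, COD_Mn, Chl a),
* a bacterial (16S) and a eukaryotic (18S) ASV count table, and
* a ranked taxonomy per ASV.

The generator plants the statistical structure the downstream analysis is
meant to detect, and records it in a :class:`PlantedTruth` so recovery can
be scored by id:

* a core-vs-edge evenness gradient (central pools less even, hence lower
  Shannon diversity),
* eutrophication covariates (TP, COD_Mn, Chl a, TN) elevated in core sites
  and in summer,
* a sinusoidal temperature cycle that forces the abundance of selected
  taxon groups (e.g. Cyanobacteria anti-correlated with temperature), and
* co-occurring ASV guilds sharing a latent monthly trajectory per site, so
  within-guild cross-month Spearman correlations are high.

Counts follow a log-normal compositional model (per-sample log relative
abundances, softmax-normalized) with multinomial sampling at a Poisson
sequencing depth. Each output artifact draws from its own RNG stream
derived from the master seed by a fixed label, so regenerating chemistry
alone does not shift the community draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import RANKS, CountTable, TaxonomyTable

MONTHS_ALL = ("Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
#: study design: no February sampling
DEFAULT_MONTHS = tuple(m for m in MONTHS_ALL if m != "Feb")

#: season assignment: Mar-May spring, Jun-Aug summer, Sep-Nov autumn, Dec+Jan winter
SEASON_OF_MONTH = {
    "Mar": "Spring", "Apr": "Spring", "May": "Spring",
    "Jun": "Summer", "Jul": "Summer", "Aug": "Summer",
    "Sep": "Autumn", "Oct": "Autumn", "Nov": "Autumn",
    "Dec": "Winter", "Jan": "Winter", "Feb": "Winter",
}

DEFAULT_SITES = ("Inlet", "Site 1", "Site 2", "Site 3", "Site 4", "Site 5", "Site 6", "Outlet")
DEFAULT_CORE_SITES = ("Site 3", "Site 4", "Site 5")

CHEM_VARIABLES = ("pH", "Temp", "DO", "EC", "NTU", "TN", "TP", "COD_Mn", "Chla")

# baseline (mean, SD) per variable; units: pH unitless, Temp degC, DO mg/L,
# EC uS/cm, NTU turbidity units, TN/TP/COD_Mn mg/L, Chla ug/L. Values chosen
# to resemble weakly acidic, low-conductivity Sphagnum-peatland pool water.
CHEM_BASELINE = {
    "pH": (5.2, 0.3),
    "Temp": (14.0, 1.5),
    "DO": (8.0, 1.5),
    "EC": (40.0, 8.0),
    "NTU": (5.0, 2.0),
    "TN": (0.8, 0.25),
    "TP": (0.05, 0.015),
    "COD_Mn": (4.0, 1.0),
    "Chla": (5.0, 2.0),
}

#: variables receiving the core-site / summer eutrophication uplift
EUTROPHIC_VARIABLES = ("TN", "TP", "COD_Mn", "Chla")

# community-model constants (log scale)
_BASE_LOG_SD = 1.2          # spread of taxon baseline log-abundances
_TAXON_NOISE_SD = 0.5       # per-taxon per-sample overdispersion
_GUILD_BASE_BOOST = 3.0     # guild members kept common so they pass filters
_GUILD_LATENT_SCALE = 2.5   # amplitude of the shared guild trajectory
_AR_PHI = 0.5               # smoothness of the guild AR(1) trajectory

# bacterial phylum composition (fractions of ASVs)
_BACT_PHYLA = (
    ("Proteobacteria", 0.35),
    ("Cyanobacteria", 0.15),
    ("Actinobacteria", 0.12),
    ("Bacteroidetes", 0.12),
    ("Firmicutes", 0.08),
    ("Acidobacteria", 0.08),
    ("Verrucomicrobia", 0.05),
    ("Planctomycetes", 0.05),
)
# eukaryotic lineages: fungal phyla, protist supergroups, and the
# contaminant / unassigned lineages the protist-table filter must remove
_EUK_PHYLA = (
    ("Chytridiomycota", 0.18),
    ("Basidiomycota", 0.12),
    ("Ascomycota", 0.10),
    ("Alveolata", 0.15),
    ("Stramenopiles", 0.15),
    ("Euglenozoa", 0.08),
    ("Chlorophyta", 0.05),
    ("Metazoa", 0.05),
    ("Streptophyta", 0.04),
    ("Rhodophyta", 0.02),
    ("Opisthokonta", 0.03),
    ("unassigned", 0.03),
)
FUNGAL_PHYLA = ("Chytridiomycota", "Basidiomycota", "Ascomycota")
CONTAMINANT_PHYLA = ("Metazoa", "Streptophyta", "Rhodophyta", "Opisthokonta")

#: chemistry -> taxon-group forcing, as (variable, phylum label, sign);
#: applied on the log scale, recovered by the Pearson screen and Mantel test
BACTERIAL_CHEM_LINKS = (
    ("Temp", "Cyanobacteria", -1),
    ("Temp", "Proteobacteria", +1),
    ("TP", "Bacteroidetes", +1),
)
EUK_CHEM_LINKS = (
    ("Temp", "Alveolata", +1),
    ("Temp", "Stramenopiles", -1),
)

_STREAMS = {"chemistry": 2, "bacteria": 3, "eukaryote": 4, "guilds": 5}

_GENUS_POOL = (
    "Rhodoferax", "Pseudomonas", "Flavobacterium", "Herminiimonas",
    "Mucilaginibacter", "Massilia", "Polynucleobacter", "Limnohabitans",
)


def _stream(seed: int, label: str) -> np.random.Generator:
    """One RNG stream per output artifact, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[label]]))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic survey.

    The defaults reproduce the reference design: 8 sites x 11 months,
    core pools (Site 3-5) with reduced evenness and elevated nutrients,
    temperature-forced composition, and three planted co-occurrence guilds.
    """

    seed: int
    n_sites: int = 8
    months: tuple[str, ...] = DEFAULT_MONTHS
    n_asvs_bacteria: int = 300
    n_asvs_euk: int = 200
    sequencing_depth_mean: int = 50_000
    diversity_gradient: float = 0.5
    eutrophication_effect: float = 1.5
    temperature_amplitude: float = 12.0
    n_guilds: int = 3
    guild_size: int = 8
    guild_noise_sd: float = 0.15
    chem_link_strength: float = 1.5
    core_sites: tuple[str, ...] = DEFAULT_CORE_SITES

    def __post_init__(self):
        object.__setattr__(self, "months", tuple(self.months))
        object.__setattr__(self, "core_sites", tuple(self.core_sites))
        if "Feb" in self.months:
            raise ValueError("months must not contain February (no February sampling)")
        unknown = set(self.months) - set(MONTHS_ALL)
        if unknown:
            raise ValueError(f"unknown month labels: {sorted(unknown)}")
        if len(set(self.months)) != len(self.months):
            raise ValueError("duplicate months")
        if self.n_sites < 1 or not self.months:
            raise ValueError("need at least one site and one month")
        for name in ("diversity_gradient", "eutrophication_effect",
                     "temperature_amplitude", "guild_noise_sd", "chem_link_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_guilds < 0 or self.guild_size < 0:
            raise ValueError("guild counts must be >= 0")
        if self.n_guilds * self.guild_size > self.n_asvs_bacteria:
            raise ValueError(
                f"n_guilds x guild_size = {self.n_guilds * self.guild_size} exceeds "
                f"n_asvs_bacteria = {self.n_asvs_bacteria}"
            )
        if self.sequencing_depth_mean < 1:
            raise ValueError("sequencing_depth_mean must be >= 1")

    @property
    def sites(self) -> tuple[str, ...]:
        if self.n_sites == len(DEFAULT_SITES):
            return DEFAULT_SITES
        return tuple(f"Site {i + 1}" for i in range(self.n_sites))

    @classmethod
    def null(cls, seed: int, **overrides) -> "ScenarioConfig":
        """Scenario with no planted structure (all effects 0, no guilds)."""
        params = dict(
            seed=seed,
            diversity_gradient=0.0,
            eutrophication_effect=0.0,
            temperature_amplitude=0.0,
            n_guilds=0,
            chem_link_strength=0.0,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure, sufficient to score recovery."""

    site_zone: dict[str, str]
    guild_membership: dict[str, int]
    planted_pairs: list[tuple[str, str]]
    chem_taxon_links: list[tuple[str, str, int]]
    expected_diversity_order: list[str]
    contaminant_taxa: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["planted_pairs"] = [list(p) for p in self.planted_pairs]
        payload["chem_taxon_links"] = [list(l) for l in self.chem_taxon_links]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["planted_pairs"] = [tuple(p) for p in payload["planted_pairs"]]
        payload["chem_taxon_links"] = [tuple(l) for l in payload["chem_taxon_links"]]
        return cls(**payload)


def sample_id(site: str, month: str) -> str:
    return f"{site.replace(' ', '')}.{month}"


def generate_metadata(config: ScenarioConfig) -> pd.DataFrame:
    """One row per (site, month) with derived season and core/edge zone."""
    rows = []
    seen = set()
    core = set(config.core_sites)
    for site in config.sites:
        for month in config.months:
            if (site, month) in seen:
                raise ValueError(f"duplicate (site, month): {(site, month)}")
            seen.add((site, month))
            rows.append(
                {
                    "sample_id": sample_id(site, month),
                    "site": site,
                    "month": month,
                    "season": SEASON_OF_MONTH[month],
                    "zone": "core" if site in core else "edge",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_chemistry(config: ScenarioConfig, frame: pd.DataFrame) -> pd.DataFrame:
    """9 physicochemical variables per sample.

    Temperature follows a sinusoid over calendar months peaking in July with
    amplitude ``temperature_amplitude``; TN, TP, COD_Mn and Chl a are lifted
    by ``eutrophication_effect`` baseline SDs in core-zone samples and again
    in summer samples. All variables carry seeded Gaussian noise and are
    floored at a small positive value (pH excepted).
    """
    rng = _stream(config.seed, "chemistry")
    n = len(frame)
    chem = pd.DataFrame(index=frame.index, columns=CHEM_VARIABLES, dtype=float)
    month_num = frame["month"].map({m: i + 1 for i, m in enumerate(MONTHS_ALL)})
    core = (frame["zone"] == "core").to_numpy()
    summer = (frame["season"] == "Summer").to_numpy()
    for var in CHEM_VARIABLES:
        mean, sd = CHEM_BASELINE[var]
        values = mean + rng.normal(0.0, sd, size=n)
        if var == "Temp":
            values = values + config.temperature_amplitude * np.cos(
                2 * np.pi * (month_num.to_numpy() - 7) / 12.0
            )
        if var in EUTROPHIC_VARIABLES:
            values = values + config.eutrophication_effect * sd * core
            values = values + config.eutrophication_effect * sd * summer
        if var != "pH":
            values = np.maximum(values, 0.01 * sd)
        chem[var] = values
    return chem


def _assign_phyla(spec, n, prefix):
    """Deterministic phylum labels following the configured fractions."""
    counts = [int(round(frac * n)) for _, frac in spec]
    while sum(counts) < n:
        counts[0] += 1
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    phyla = []
    for (name, _), c in zip(spec, counts):
        phyla.extend([name] * c)
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    return ids, phyla


def _taxonomy_frame(ids, phyla, genus_rng):
    rows = []
    for i, (tid, ph) in enumerate(zip(ids, phyla)):
        if ph == "unassigned":
            lineage = {r: "unassigned" for r in RANKS[1:]}
            domain = "Eukaryota"
        else:
            domain = "Bacteria" if tid.startswith("B") else "Eukaryota"
            genus = (
                _GENUS_POOL[i % len(_GENUS_POOL)]
                if domain == "Bacteria" and genus_rng.random() < 0.15
                else f"{ph}_genus_{i % 40 + 1}"
            )
            lineage = {
                "phylum": ph,
                "class": f"{ph}_cls",
                "order": f"{ph}_ord",
                "family": f"{ph}_fam",
                "genus": genus,
            }
        rows.append({"ASV_ID": tid, "domain": domain, **lineage})
    return pd.DataFrame(rows).set_index("ASV_ID")


def _guild_latents(config, _frame, rng):
    """Shared AR(1) monthly trajectory per (guild, site), unit SD.

    Within a site the guild trajectories are orthogonalized (QR) so
    distinct guilds do not co-occur by chance over the short monthly
    series; each guild then reads as its own seasonal bloom cohort.
    """
    n_months = len(config.months)
    latents = {}
    for site in config.sites:
        series = np.empty((n_months, config.n_guilds))
        for g in range(config.n_guilds):
            series[0, g] = rng.normal()
            for m in range(1, n_months):
                series[m, g] = _AR_PHI * series[m - 1, g] + np.sqrt(1 - _AR_PHI**2) * rng.normal()
        if 1 < config.n_guilds < n_months:
            centered = series - series.mean(axis=0)
            q_mat, r_mat = np.linalg.qr(centered)
            series = q_mat * np.sign(np.diag(r_mat))  # keep each guild's own direction
        if config.n_guilds:
            sd = series.std(axis=0)
            series = series / np.where(sd > 0, sd, 1.0)
        for g in range(config.n_guilds):
            latents[(g, site)] = series[:, g]
    return latents


def _community_rel(config, frame, chem, ids, phyla, links, guilds, rng, guild_latents):
    """Latent relative-abundance matrix for one marker (log-normal model).

    Guild members carry their shared trajectory plus member noise of SD
    exactly ``guild_noise_sd``; the generic per-taxon overdispersion
    applies only to non-guild taxa, so ``guild_noise_sd = 0`` makes guild
    members' composition series identical up to a positive factor.
    """
    n_samples, n_taxa = len(frame), len(ids)
    member_idx = sorted({i for members in guilds.values() for i in members})
    mu = rng.normal(0.0, _BASE_LOG_SD, size=n_taxa)
    mu[member_idx] += _GUILD_BASE_BOOST
    noise = rng.normal(0.0, _TAXON_NOISE_SD, size=(n_samples, n_taxa))
    noise[:, member_idx] = 0.0
    logit = mu[None, :] + noise

    phyla_arr = np.asarray(phyla)
    for var, group, sign in links:
        cols = np.flatnonzero(phyla_arr == group)
        if cols.size == 0:
            continue
        z = (chem[var] - chem[var].mean()) / chem[var].std(ddof=0)
        logit[:, cols] += config.chem_link_strength * sign * z.to_numpy()[:, None]

    month_pos = {m: i for i, m in enumerate(config.months)}
    site_arr = frame["site"].to_numpy()
    month_idx = frame["month"].map(month_pos).to_numpy()
    for g, members in guilds.items():
        member_noise = rng.normal(0.0, config.guild_noise_sd, size=(n_samples, len(members)))
        for row in range(n_samples):
            lat = guild_latents[(g, site_arr[row])][month_idx[row]]
            logit[row, members] += _GUILD_LATENT_SCALE * lat + member_noise[row]

    core_rows = (frame["zone"] == "core").to_numpy()
    logit[core_rows] *= 1.0 + config.diversity_gradient

    logit -= logit.max(axis=1, keepdims=True)
    rel = np.exp(logit)
    rel /= rel.sum(axis=1, keepdims=True)
    return rel


def _community_counts(config, frame, chem, ids, phyla, links, guilds, rng, guild_latents):
    """Latent composition -> multinomial counts at Poisson depth."""
    rel = _community_rel(config, frame, chem, ids, phyla, links, guilds, rng, guild_latents)
    n_samples, n_taxa = rel.shape
    depths = rng.poisson(config.sequencing_depth_mean, size=n_samples)
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for row in range(n_samples):
        counts[row] = rng.multinomial(depths[row], rel[row])
    return CountTable(pd.DataFrame(counts, index=frame.index, columns=ids))


def _planted_guilds(config: ScenarioConfig, b_phyla) -> tuple[dict[int, list[int]], dict]:
    """Guild membership (bacterial column indices) and shared latents.

    Members are drawn from phyla carrying no chemistry forcing so guild
    co-occurrence and environmental forcing stay separable signals.
    """
    guild_rng = _stream(config.seed, "guilds")
    linked_phyla = {group for _, group, _ in BACTERIAL_CHEM_LINKS}
    pool = [i for i, ph in enumerate(b_phyla) if ph not in linked_phyla]
    need = config.n_guilds * config.guild_size
    if need > len(pool):
        raise ValueError(
            f"guild capacity exceeded: need {need} unforced bacterial taxa, have {len(pool)}"
        )
    chosen = guild_rng.choice(len(pool), size=need, replace=False) if need else np.array([], int)
    guilds: dict[int, list[int]] = {}
    for g in range(config.n_guilds):
        guilds[g] = [pool[j] for j in chosen[g * config.guild_size : (g + 1) * config.guild_size]]
    latents = _guild_latents(config, None, guild_rng)
    return guilds, latents


def generate_relative_abundances(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent (pre-sequencing) relative abundances for both markers.

    Uses the same RNG streams as :func:`generate_asv_tables`, so these are
    exactly the compositions underlying the multinomial count draws.
    """
    frame = generate_metadata(config)
    chem = generate_chemistry(config, frame)
    b_ids, b_phyla = _assign_phyla(_BACT_PHYLA, config.n_asvs_bacteria, "B")
    e_ids, e_phyla = _assign_phyla(_EUK_PHYLA, config.n_asvs_euk, "E")
    guilds, latents = _planted_guilds(config, b_phyla)
    rel16 = _community_rel(
        config, frame, chem, b_ids, b_phyla, BACTERIAL_CHEM_LINKS,
        guilds, _stream(config.seed, "bacteria"), latents,
    )
    rel18 = _community_rel(
        config, frame, chem, e_ids, e_phyla, EUK_CHEM_LINKS,
        {}, _stream(config.seed, "eukaryote"), latents,
    )
    return (
        pd.DataFrame(rel16, index=frame.index, columns=b_ids),
        pd.DataFrame(rel18, index=frame.index, columns=e_ids),
    )


def generate_asv_tables(
    config: ScenarioConfig, frame: pd.DataFrame, chem: pd.DataFrame
) -> tuple[CountTable, CountTable, TaxonomyTable, PlantedTruth]:
    """Generate the 16S and 18S count tables, taxonomy, and planted truth."""
    b_ids, b_phyla = _assign_phyla(_BACT_PHYLA, config.n_asvs_bacteria, "B")
    e_ids, e_phyla = _assign_phyla(_EUK_PHYLA, config.n_asvs_euk, "E")
    guilds, guild_latents = _planted_guilds(config, b_phyla)

    table_16s = _community_counts(
        config, frame, chem, b_ids, b_phyla, BACTERIAL_CHEM_LINKS,
        guilds, _stream(config.seed, "bacteria"), guild_latents,
    )
    table_18s = _community_counts(
        config, frame, chem, e_ids, e_phyla, EUK_CHEM_LINKS,
        {}, _stream(config.seed, "eukaryote"), guild_latents,
    )

    taxonomy = TaxonomyTable(
        pd.concat(
            [
                _taxonomy_frame(b_ids, b_phyla, _stream(config.seed, "bacteria")),
                _taxonomy_frame(e_ids, e_phyla, _stream(config.seed, "eukaryote")),
            ]
        )
    )

    membership = {b_ids[i]: g for g, members in guilds.items() for i in members}
    pairs = []
    for g, members in guilds.items():
        names = sorted(b_ids[i] for i in members)
        pairs.extend((a, b) for k, a in enumerate(names) for b in names[k + 1 :])
    contaminants = [
        tid for tid, ph in zip(e_ids, e_phyla) if ph in CONTAMINANT_PHYLA or ph == "unassigned"
    ]
    edge_sites = [s for s in config.sites if s not in config.core_sites]
    truth = PlantedTruth(
        site_zone={s: ("core" if s in config.core_sites else "edge") for s in config.sites},
        guild_membership=membership,
        planted_pairs=pairs,
        chem_taxon_links=list(BACTERIAL_CHEM_LINKS) + list(EUK_CHEM_LINKS),
        expected_diversity_order=edge_sites + list(config.core_sites),
        contaminant_taxa=contaminants,
    )
    return table_16s, table_18s, taxonomy, truth


def generate_bundle(config: ScenarioConfig):
    """Generate all artifacts: (metadata, chemistry, 16S, 18S, taxonomy, truth)."""
    frame = generate_metadata(config)
    chem = generate_chemistry(config, frame)
    t16, t18, taxonomy, truth = generate_asv_tables(config, frame, chem)
    return frame, chem, t16, t18, taxonomy, truth


def write_bundle(config: ScenarioConfig, out_dir) -> dict[str, str]:
    """Generate and write all artifacts as TSV/JSON; returns written paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    frame, chem, t16, t18, taxonomy, truth = generate_bundle(config)
    paths = {
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "chemistry": os.path.join(out_dir, "chemistry.tsv"),
        "asv_16s": os.path.join(out_dir, "asv_16s.tsv"),
        "asv_18s": os.path.join(out_dir, "asv_18s.tsv"),
        "taxonomy": os.path.join(out_dir, "taxonomy.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    frame.to_csv(paths["metadata"], sep="\t")
    chem.to_csv(paths["chemistry"], sep="\t", float_format="%.10g")
    t16.to_tsv(paths["asv_16s"])
    t18.to_tsv(paths["asv_18s"])
    taxonomy.to_tsv(paths["taxonomy"])
    truth.to_json(paths["truth"])
    return paths
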