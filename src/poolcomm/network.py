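"""Per-site co-occurrence networks with modules and Zi-Pi keystone roles.

A network is built from one site's monthly series: all-pairs Spearman
correlations among filtered taxa (bacteria, fungi, protists pooled), BH-FDR
adjustment of the two-sided p values over the upper triangle, and an edge
wherever |r| exceeds the correlation threshold and the adjusted p falls
below the significance threshold (both strict). Edge sign is the sign of
r. Modules come from seeded Louvain modularity maximization on the
unweighted graph; node roles follow the Zi-Pi scheme: within-module degree
z-score (Zi) against the participation coefficient (Pi), with hubs above
Zi = 2.5 and connectors above Pi = 0.62.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLE_NETWORK_HUB = "network_hub"
ROLE_MODULE_HUB = "module_hub"
ROLE_CONNECTOR = "connector"
ROLE_PERIPHERAL = "peripheral"


def correlation_matrices(site_table) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman r and two-sided p across one site's monthly samples.

    Ranks use midranks for ties; p comes from the t approximation with
    df = n - 2. Pairs involving a constant taxon are undefined (NaN) and
    can never become edges. The diagonal is set to NaN (no self-loops).
    """
    df = site_table.data if hasattr(site_table, "data") else site_table
    n, m = df.shape
    if n < 4:
        raise ValueError("need at least 4 samples per site")
    x = df.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    constant = x.std(axis=0) == 0
    r_c = ranks - ranks.mean(axis=0)
    norm = np.sqrt((r_c**2).sum(axis=0))
    norm_safe = np.where(norm == 0, 1.0, norm)
    r = (r_c.T @ r_c) / np.outer(norm_safe, norm_safe)
    r = np.clip(r, -1.0, 1.0)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    np.fill_diagonal(r, np.nan)
    np.fill_diagonal(p, np.nan)
    cols = df.columns
    return pd.DataFrame(r, index=cols, columns=cols), pd.DataFrame(p, index=cols, columns=cols)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def adjust_p_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """BH adjustment applied over the finite upper triangle of a p matrix."""
    mat = p.to_numpy(dtype=float)
    ii, jj = np.triu_indices(mat.shape[0], k=1)
    upper = mat[ii, jj]
    finite = np.isfinite(upper)
    adjusted = np.full_like(upper, np.nan)
    if finite.any():
        adjusted[finite] = bh_adjust(upper[finite])
    out = np.full_like(mat, np.nan)
    out[ii, jj] = adjusted
    out[jj, ii] = adjusted
    return pd.DataFrame(out, index=p.index, columns=p.columns)


def build_network(
    r: pd.DataFrame,
    p_adjusted: pd.DataFrame,
    r_threshold: float = 0.7,
    p_threshold: float = 0.01,
    p_raw: pd.DataFrame | None = None,
    node_attributes: dict[str, dict] | None = None,
) -> nx.Graph:
    """Graph with an edge wherever |r| > r_threshold and p_adjusted < p_threshold.

    Both inequalities are strict. Taxa left without any edge are excluded
    from the node set. Edge attributes: ``spearman_r``, ``p_adjusted``,
    optionally ``p_raw``, and ``sign`` ("+" or "-").
    """
    if list(r.index) != list(p_adjusted.index) or list(r.columns) != list(p_adjusted.columns):
        raise ValueError("r and p matrices must be aligned on the same taxa")
    graph = nx.Graph()
    taxa = list(r.index)
    r_mat = r.to_numpy()
    p_mat = p_adjusted.to_numpy()
    ii, jj = np.triu_indices(len(taxa), k=1)
    with np.errstate(invalid="ignore"):
        hit = (np.abs(r_mat[ii, jj]) > r_threshold) & (p_mat[ii, jj] < p_threshold)
    hit &= np.isfinite(r_mat[ii, jj]) & np.isfinite(p_mat[ii, jj])
    for a, b in zip(ii[hit], jj[hit]):
        attrs = {
            "spearman_r": float(r_mat[a, b]),
            "p_adjusted": float(p_mat[a, b]),
            "sign": "+" if r_mat[a, b] > 0 else "-",
        }
        if p_raw is not None:
            attrs["p_raw"] = float(p_raw.iloc[a, b])
        graph.add_edge(taxa[a], taxa[b], **attrs)
    if node_attributes:
        for attr, mapping in node_attributes.items():
            nx.set_node_attributes(
                graph, {n: mapping[n] for n in graph.nodes if n in mapping}, attr
            )
    return graph


def detect_modules(graph: nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Louvain modularity-maximizing partition on the unweighted graph.

    Returns the node -> module-id mapping (module ids ordered by first
    node appearance) and the modularity Q of the returned partition.
    """
    if graph.number_of_nodes() == 0:
        return {}, 0.0
    communities = nx.community.louvain_communities(graph, weight=None, seed=seed)
    partition: dict = {}
    order = {n: i for i, n in enumerate(graph.nodes)}
    for community in sorted(communities, key=lambda c: min(order[n] for n in c)):
        mid = len(set(partition.values()))
        for node in community:
            partition[node] = mid
    return partition, modularity(graph, partition)


def modularity(graph: nx.Graph, partition: dict) -> float:
    """Newman modularity Q = sum_s ( l_s/m - (d_s / 2m)^2 ) of a partition."""
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    intra: dict = {}
    degree: dict = {}
    for u, v in graph.edges:
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0) + 1
    for node, deg in graph.degree:
        degree[partition[node]] = degree.get(partition[node], 0) + deg
    return float(
        sum(intra.get(s, 0) / m - (degree.get(s, 0) / (2 * m)) ** 2 for s in set(partition.values()))
    )


@dataclass
class TopologySummary:
    """Whole-network topological properties (one network, one site)."""

    n_modules_gt5: int
    n_nodes: int
    n_edges: int
    pct_positive: float
    pct_negative: float
    average_degree: float
    modularity: float
    avg_betweenness: float
    avg_closeness: float
    avg_clustering: float
    avg_path_distance: float
    degenerate: bool = False

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Modules (>5 nodes)": self.n_modules_gt5,
                "Nodes": self.n_nodes,
                "Edges": self.n_edges,
                "Positive edges (%)": self.pct_positive,
                "Negative edges (%)": self.pct_negative,
                "Average degree": self.average_degree,
                "Modularity": self.modularity,
                "Average betweenness centrality": self.avg_betweenness,
                "Average closeness centrality": self.avg_closeness,
                "Average clustering coefficient": self.avg_clustering,
                "Average path distance": self.avg_path_distance,
            }
        )


def topology_summary(graph: nx.Graph, partition: dict | None = None) -> TopologySummary:
    """Module counts, edge-sign percentages, and average centralities.

    Betweenness is unnormalized; closeness of a node is (n_c - 1) / sum of
    distances within its connected component of size n_c; clustering of
    degree < 2 nodes is 0; path distance averages over connected ordered
    pairs. An empty graph yields flagged zeros.
    """
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    if n_nodes == 0 or n_edges == 0:
        return TopologySummary(0, n_nodes, n_edges, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, True)
    if partition is None:
        partition, _ = detect_modules(graph)
    sizes: dict = {}
    for node, mid in partition.items():
        sizes[mid] = sizes.get(mid, 0) + 1
    n_modules_gt5 = sum(1 for size in sizes.values() if size > 5)
    signs = [d.get("sign", "+") for _, _, d in graph.edges(data=True)]
    pct_pos = 100.0 * signs.count("+") / n_edges
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness = nx.closeness_centrality(graph, wf_improved=False)
    path_sum, path_count = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        for target, dist in lengths.items():
            if dist > 0:
                path_sum += dist
                path_count += 1
    return TopologySummary(
        n_modules_gt5=n_modules_gt5,
        n_nodes=n_nodes,
        n_edges=n_edges,
        pct_positive=pct_pos,
        pct_negative=100.0 - pct_pos,
        average_degree=2.0 * n_edges / n_nodes,
        modularity=modularity(graph, partition),
        avg_betweenness=float(np.mean(list(betweenness.values()))),
        avg_closeness=float(np.mean(list(closeness.values()))),
        avg_clustering=float(nx.average_clustering(graph, count_zeros=True)),
        avg_path_distance=path_sum / path_count if path_count else 0.0,
    )


def zi_pi(graph: nx.Graph, partition: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's
    mean and (population) SD, with Zi = 0 when the SD is 0. Pi is
    1 - sum_s (k_is / k_i)^2 over modules s.
    """
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    nodes = list(graph.nodes)
    kappa = {}
    links_by_module: dict = {}
    for node in nodes:
        per_module: dict = {}
        for neighbor in graph.neighbors(node):
            per_module[partition[neighbor]] = per_module.get(partition[neighbor], 0) + 1
        links_by_module[node] = per_module
        kappa[node] = per_module.get(partition[node], 0)
    module_stats = {}
    for mid in set(partition[n] for n in nodes):
        values = np.array([kappa[n] for n in nodes if partition[n] == mid], dtype=float)
        module_stats[mid] = (values.mean(), values.std(ddof=0))
    rows = {}
    for node in nodes:
        mean, sd = module_stats[partition[node]]
        zi = (kappa[node] - mean) / sd if sd > 0 else 0.0
        degree = graph.degree[node]
        pi = 1.0 - sum((k / degree) ** 2 for k in links_by_module[node].values())
        rows[node] = {
            "module": partition[node],
            "degree": degree,
            "within_module_degree": kappa[node],
            "Zi": zi,
            "Pi": pi,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame["role"] = [classify_roles(z, p) for z, p in zip(frame["Zi"], frame["Pi"])]
    return frame


def classify_roles(zi: float, pi: float) -> str:
    """Zi-Pi role: hubs above Zi = 2.5, connectors above Pi = 0.62.

    Boundary values (Zi = 2.5, Pi = 0.62) fall on the non-hub /
    non-connector side so every (Zi, Pi) point gets exactly one role.
    """
    if not (np.isfinite(zi) and np.isfinite(pi)):
        raise ValueError("Zi and Pi must be finite")
    if zi > ZI_THRESHOLD:
        return ROLE_NETWORK_HUB if pi > PI_THRESHOLD else ROLE_MODULE_HUB
    return ROLE_CONNECTOR if pi > PI_THRESHOLD else ROLE_PERIPHERAL


def site_network(
    site_table,
    r_threshold: float = 0.7,
    p_threshold: float = 0.01,
    seed: int = 0,
    node_attributes: dict[str, dict] | None = None,
    use_raw_p: bool = False,
):
    """Full per-site analysis: correlations -> BH -> graph -> modules -> roles.

    Returns ``(graph, partition, TopologySummary, zi_pi frame)``. With
    ``use_raw_p`` the threshold applies to unadjusted p values instead of
    the BH-adjusted ones.
    """
    r, p = correlation_matrices(site_table)
    p_adj = adjust_p_matrix(p)
    threshold_p = p if use_raw_p else p_adj
    graph = build_network(
        r, threshold_p, r_threshold=r_threshold, p_threshold=p_threshold,
        p_raw=p, node_attributes=node_attributes,
    )
    partition, _ = detect_modules(graph, seed=seed)
    summary = topology_summary(graph, partition)
    roles = zi_pi(graph, partition) if graph.number_of_nodes() else pd.DataFrame(
        columns=["module", "degree", "within_module_degree", "Zi", "Pi", "role"]
    )
    return graph, partition, summary, roles


def write_graphml(graph: nx.Graph, partition: dict, roles: pd.DataFrame, path) -> None:
    """GraphML export with module, degree, Zi, Pi and role node attributes."""
    out = graph.copy()
    for node in out.nodes:
        out.nodes[node]["module"] = int(partition.get(node, -1))
        if node in roles.index:
            out.nodes[node]["degree"] = int(roles.loc[node, "degree"])
            out.nodes[node]["Zi"] = float(roles.loc[node, "Zi"])
            out.nodes[node]["Pi"] = float(roles.loc[node, "Pi"])
            out.nodes[node]["role"] = str(roles.loc[node, "role"])
    nx.write_graphml(out, path)


def edge_list(graph: nx.Graph) -> pd.DataFrame:
    """Edge list with correlation, p values and sign, one row per edge."""
    rows = [
        {"source": u, "target": v, **data}
        for u, v, data in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "spearman_r", "p_adjusted", "p_raw", "sign"])
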