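"""Independent brute-force reference implementations used to cross-check
the package. Everything here is written from first principles (explicit
loops, exhaustive enumeration) and never calls into poolcomm.
"""

import itertools
import math

import numpy as np


def shannon_bf(counts):
    total = sum(c for c in counts if c > 0)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def chao1_bf(counts):
    pos = [c for c in counts if c > 0]
    f1 = sum(1 for c in pos if c == 1)
    f2 = sum(1 for c in pos if c == 2)
    return len(pos) + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def bray_curtis_bf(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def spearman_bf(x, y):
    """Spearman rho via explicit midranks and the Pearson formula."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def bh_bf(pvals):
    """Step-up BH from the definition: adj_i = min_{j>=i} p_(j) m / j, capped."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    for pos, i in enumerate(order):
        candidates = [
            pvals[order[j]] * m / (j + 1) for j in range(pos, m)
        ]
        adjusted[i] = min(1.0, min(candidates))
    return adjusted


def modularity_bf(edges, partition):
    m = len(edges)
    if m == 0:
        return 0.0
    modules = set(partition.values())
    degree = {}
    for u, v in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    q = 0.0
    for s in modules:
        l_s = sum(1 for u, v in edges if partition[u] == s and partition[v] == s)
        d_s = sum(d for n, d in degree.items() if partition[n] == s)
        q += l_s / m - (d_s / (2 * m)) ** 2
    return q


def _adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def clustering_bf(nodes, edges):
    """Mean local clustering coefficient; degree < 2 nodes contribute 0."""
    adj = _adjacency(nodes, edges)
    values = []
    for n in nodes:
        neigh = list(adj[n])
        k = len(neigh)
        if k < 2:
            values.append(0.0)
            continue
        links = sum(
            1
            for a, b in itertools.combinations(neigh, 2)
            if b in adj[a]
        )
        values.append(2.0 * links / (k * (k - 1)))
    return sum(values) / len(values) if values else 0.0


def shortest_paths_bf(nodes, edges):
    """All-pairs shortest path lengths by Floyd-Warshall."""
    inf = float("inf")
    dist = {a: {b: (0 if a == b else inf) for b in nodes} for a in nodes}
    for u, v in edges:
        dist[u][v] = dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return dist


def avg_path_bf(nodes, edges):
    dist = shortest_paths_bf(nodes, edges)
    lengths = [
        dist[a][b]
        for a in nodes
        for b in nodes
        if a != b and dist[a][b] < float("inf")
    ]
    return sum(lengths) / len(lengths) if lengths else 0.0


def closeness_bf(nodes, edges):
    """Per-node (n_c - 1) / sum of distances within the node's component."""
    dist = shortest_paths_bf(nodes, edges)
    out = {}
    for n in nodes:
        reach = [dist[n][b] for b in nodes if b != n and dist[n][b] < float("inf")]
        out[n] = len(reach) / sum(reach) if reach and sum(reach) > 0 else 0.0
    return out


def betweenness_bf(nodes, edges):
    """Unnormalized shortest-path betweenness via path counting.

    sigma_st(v) / sigma_st summed over unordered pairs {s, t} not
    containing v (ordered-pair sum halved).
    """
    dist = shortest_paths_bf(nodes, edges)
    adj = _adjacency(nodes, edges)

    def n_shortest(s, t):
        if dist[s][t] == float("inf"):
            return 0
        if s == t:
            return 1
        return sum(n_shortest(s, u) for u in adj[t] if dist[s][u] + 1 == dist[s][t])

    out = {}
    for v in nodes:
        total = 0.0
        for s in nodes:
            for t in nodes:
                if s == t or v in (s, t):
                    continue
                sigma = n_shortest(s, t)
                if sigma == 0:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    total += n_shortest(s, v) * n_shortest(v, t) / sigma
        out[v] = total / 2.0
    return out


def zi_bf(nodes, edges, partition):
    adj = _adjacency(nodes, edges)
    kappa = {
        n: sum(1 for u in adj[n] if partition[u] == partition[n]) for n in nodes
    }
    out = {}
    for n in nodes:
        same = [kappa[u] for u in nodes if partition[u] == partition[n]]
        mean = sum(same) / len(same)
        sd = math.sqrt(sum((k - mean) ** 2 for k in same) / len(same))
        out[n] = (kappa[n] - mean) / sd if sd > 0 else 0.0
    return out


def pi_bf(nodes, edges, partition):
    adj = _adjacency(nodes, edges)
    out = {}
    for n in nodes:
        k = len(adj[n])
        per_module = {}
        for u in adj[n]:
            per_module[partition[u]] = per_module.get(partition[u], 0) + 1
        out[n] = 1.0 - sum((c / k) ** 2 for c in per_module.values())
    return out


def pearson_bf(x, y):
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def random_graph(rng, n_nodes, p_edge):
    nodes = list(range(n_nodes))
    edges = [
        (a, b)
        for a, b in itertools.combinations(nodes, 2)
        if rng.random() < p_edge
    ]
    return nodes, edges


def hypergeom_mean_sd(total_first, total, depth):
    """Mean and SD of the first taxon's count after subsampling to depth."""
    p = total_first / total
    mean = depth * p
    var = depth * p * (1 - p) * (total - depth) / (total - 1)
    return mean, math.sqrt(var)
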