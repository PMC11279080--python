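"""Score pipeline output against the planted truth of a synthetic scenario."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score


def guild_edge_sensitivity(graph, truth, candidate_taxa) -> tuple[float, int]:
    """Fraction of planted within-guild pairs recovered as edges.

    Only pairs whose both members survived upstream filtering (are in
    ``candidate_taxa``) count as recoverable. Returns (sensitivity,
    n_recoverable); sensitivity is NaN when nothing is recoverable.
    """
    candidates = set(candidate_taxa)
    recoverable = [
        (a, b) for a, b in truth.planted_pairs if a in candidates and b in candidates
    ]
    if not recoverable:
        return float("nan"), 0
    hits = sum(1 for a, b in recoverable if graph.has_edge(a, b))
    return hits / len(recoverable), len(recoverable)


def module_ari(partition: dict, truth) -> float:
    """Adjusted Rand index between detected modules and planted guilds.

    Compared over guild-member nodes present in the partition; NaN when
    fewer than 2 such nodes exist.
    """
    members = [n for n in partition if n in truth.guild_membership]
    if len(members) < 2:
        return float("nan")
    detected = [partition[n] for n in members]
    planted = [truth.guild_membership[n] for n in members]
    return float(adjusted_rand_score(planted, detected))


def false_edge_rate(graph, truth) -> float:
    """Fraction of edges joining taxa from different (or no) guilds."""
    n_edges = graph.number_of_edges()
    if n_edges == 0:
        return 0.0
    planted = set(map(tuple, truth.planted_pairs))
    false = sum(
        1
        for u, v in graph.edges
        if (u, v) not in planted and (v, u) not in planted
    )
    return false / n_edges


def diversity_gradient_recovered(alpha_frame, metadata, index: str = "shannon") -> bool:
    """True when core-zone samples average below edge-zone samples."""
    joined = alpha_frame.join(metadata["zone"])
    means = joined.groupby("zone")[index].mean()
    return bool(means.get("core", np.inf) < means.get("edge", -np.inf))
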