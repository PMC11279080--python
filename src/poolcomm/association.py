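"""Environment-community association: Mantel tests and the Pearson screen.

The Mantel statistic is the Pearson correlation between the upper
triangles of two distance matrices over the same samples (a Spearman
variant is available); significance comes from jointly permuting rows and
columns of one matrix, with the one-sided estimate

    p = (1 + #{ permuted R >= observed R }) / (n_permutations + 1).

The Pearson screen correlates each physicochemical variable against each
rank-aggregated taxon abundance with two-sided t-based p values and no
multiplicity adjustment by default (each cell is reported at its own p,
as in heat-map style displays; a Benjamini-Hochberg option exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .simulate import CHEM_VARIABLES


def chem_distance(chem: pd.DataFrame, variables="All") -> DistanceMatrix:
    """Euclidean distance among samples on z-scored chemistry variables.

    ``variables`` may be "All" (all nine), one variable name, or a list of
    names. Standardization puts heterogeneous units on a common scale, so a
    single-variable distance is measured in SD units.
    """
    if isinstance(variables, str):
        selected = list(chem.columns) if variables == "All" else [variables]
    else:
        selected = list(variables)
    unknown = [v for v in selected if v not in chem.columns]
    if unknown:
        raise KeyError(f"unknown chemistry variables: {unknown}")
    x_mat = chem[selected].to_numpy(dtype=float)
    sd = x_mat.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = [v for v, s in zip(selected, sd) if s == 0]
        raise ValueError(f"zero-variance variables: {dead}")
    z = (x_mat - x_mat.mean(axis=0)) / sd
    return DistanceMatrix(squareform(pdist(z)), ids=[str(i) for i in chem.index])


@dataclass
class MantelResult:
    statistic: float
    pvalue: float
    n_permutations: int
    method: str
    property_name: str = ""


def _condensed_index_matrix(n: int) -> np.ndarray:
    idx = np.zeros((n, n), dtype=np.int64)
    ii, jj = np.triu_indices(n, k=1)
    idx[ii, jj] = np.arange(ii.size)
    idx[jj, ii] = idx[ii, jj]
    return idx


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "pearson",
    property_name: str = "",
) -> MantelResult:
    """Mantel test between two distance matrices over identical samples.

    Sample ids must match in the same order. Permutations relabel the
    samples of the second matrix (rows and columns jointly). The test is
    one-sided for positive association, so negative statistics are
    reported with large p.
    """
    if list(dist_a.ids) != list(dist_b.ids):
        raise ValueError("distance matrices must share sample ids in the same order")
    n = len(dist_a.ids)
    if n < 4:
        raise ValueError("need at least 4 samples for a Mantel test")
    a = squareform(np.asarray(dist_a.data, dtype=float), checks=False)
    b = squareform(np.asarray(dist_b.data, dtype=float), checks=False)
    if method == "spearman":
        a = stats.rankdata(a)
        b = stats.rankdata(b)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    a_c = a - a.mean()
    b_c = b - b.mean()
    norm = np.sqrt((a_c**2).sum() * (b_c**2).sum())
    if norm == 0:
        raise ValueError("degenerate (constant) distance matrix")
    observed = float(a_c @ b_c / norm)

    rng = np.random.default_rng(seed)
    pair_index = _condensed_index_matrix(n)
    ii, jj = np.triu_indices(n, k=1)
    exceed = 0
    chunk = max(1, min(2000, n_permutations))
    done = 0
    # permuting sample labels permutes the condensed vector, so its mean and
    # norm are invariant and only the dot product needs recomputation
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = np.array([rng.permutation(n) for _ in range(m)])
        cond_idx = pair_index[perms[:, ii], perms[:, jj]]
        stats_perm = b[cond_idx] @ a_c / norm
        exceed += int((stats_perm >= observed).sum())
        done += m
    pvalue = (1 + exceed) / (n_permutations + 1)
    return MantelResult(observed, float(pvalue), n_permutations, method, property_name)


def mantel_table(
    community_distances: dict[str, DistanceMatrix],
    chem: pd.DataFrame,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "pearson",
) -> pd.DataFrame:
    """All-properties-plus-each-variable Mantel screen per organism group.

    Rows are "All" followed by each chemistry variable; columns carry the
    Mantel R and p for each community distance matrix (e.g. bacteria,
    fungi, protist).
    """
    rows = ["All"] + [v for v in CHEM_VARIABLES if v in chem.columns]
    out = {}
    for group, dmat in community_distances.items():
        chem_aligned = chem.loc[[str(i) for i in dmat.ids]]
        for prop in rows:
            res = mantel(
                dmat,
                chem_distance(chem_aligned, prop),
                n_permutations=n_permutations,
                seed=seed,
                method=method,
                property_name=prop,
            )
            out.setdefault(f"{group}_R", {})[prop] = res.statistic
            out.setdefault(f"{group}_p", {})[prop] = res.pvalue
    return pd.DataFrame(out).loc[rows]


@dataclass
class CorrelationScreen:
    r: pd.DataFrame            # variables x taxa Pearson r
    p: pd.DataFrame            # two-sided p, t approximation with df = n - 2
    significant: pd.DataFrame  # p < alpha mask
    alpha: float
    flagged: list[tuple[str, str]]  # undefined pairs (constant column)


def pearson_screen(
    chem: pd.DataFrame,
    abundances: pd.DataFrame,
    alpha: float = 0.05,
    top_n_taxa: int | None = None,
    bh_adjust: bool = False,
) -> CorrelationScreen:
    """Pearson correlations between chemistry variables and taxon abundances.

    When ``top_n_taxa`` is given, the screen keeps only the most abundant
    taxa by mean relative abundance (e.g. the top 20 genera). Pairs with a
    constant member have undefined r; they are masked non-significant and
    listed in ``flagged``.
    """
    shared = [s for s in chem.index if s in abundances.index]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    chem = chem.loc[shared]
    abund = abundances.loc[shared]
    if top_n_taxa is not None:
        keep = abund.mean(axis=0).sort_values(ascending=False).index[:top_n_taxa]
        abund = abund.loc[:, list(keep)]

    n = len(shared)
    x_mat = chem.to_numpy(dtype=float)
    y_mat = abund.to_numpy(dtype=float)
    x_c = x_mat - x_mat.mean(axis=0)
    y_c = y_mat - y_mat.mean(axis=0)
    x_norm = np.sqrt((x_c**2).sum(axis=0))
    y_norm = np.sqrt((y_c**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x_c.T @ y_c) / np.outer(x_norm, y_norm)
    r = np.clip(r, -1.0, 1.0)
    flagged = [
        (v, t)
        for i, v in enumerate(chem.columns)
        for j, t in enumerate(abund.columns)
        if x_norm[i] == 0 or y_norm[j] == 0
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    r_df = pd.DataFrame(r, index=chem.columns, columns=abund.columns)
    p_df = pd.DataFrame(p, index=chem.columns, columns=abund.columns)
    if bh_adjust:
        from .network import bh_adjust as _bh

        flat = p_df.to_numpy().ravel()
        finite = np.isfinite(flat)
        adjusted = flat.copy()
        adjusted[finite] = _bh(flat[finite])
        p_df = pd.DataFrame(
            adjusted.reshape(p_df.shape), index=p_df.index, columns=p_df.columns
        )
    significant = (p_df < alpha).fillna(False)
    return CorrelationScreen(r_df, p_df, significant, alpha, flagged)
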