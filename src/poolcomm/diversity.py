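"""Alpha diversity (Shannon-Wiener, Chao1) and group comparisons.

Shannon uses the natural log; Chao1 defaults to the bias-corrected
estimator ``S_obs + F1(F1-1) / (2(F2+1))`` with the classic variant
``S_obs + F1^2 / (2 F2)`` behind a flag. Group differences use classical
one-way ANOVA with all-pairs Tukey HSD (Tukey-Kramer on unbalanced
groups) and a compact letter display built by insert-absorb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _positive_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    pos = arr[arr > 0]
    if pos.size == 0:
        raise ValueError("all-zero count vector")
    return pos


def shannon(counts) -> float:
    """Shannon-Wiener index, -sum p_i ln p_i over positive counts."""
    pos = _positive_counts(counts)
    p = pos / pos.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts."""
    pos = _positive_counts(counts)
    s_obs = pos.size
    f1 = int((pos == 1).sum())
    f2 = int((pos == 2).sum())
    if bias_corrected:
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / 2.0)


def alpha_table(table, rarefied: bool = True) -> pd.DataFrame:
    """Per-sample observed richness, Chao1 and Shannon for a CountTable.

    Indices are depth-sensitive; pass a rarefied table (a warning is logged
    otherwise so unequal-depth comparisons are deliberate).
    """
    if not rarefied:
        logger.warning("alpha_table called on an unrarefied table; indices are depth-sensitive")
    rows = {}
    for s in table.sample_ids:
        counts = table.data.loc[s].to_numpy()
        rows[s] = {
            "observed_richness": int((counts > 0).sum()),
            "chao1": chao1(counts),
            "shannon": shannon(counts),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letters."""

    factor: str
    summary: pd.DataFrame        # per group: mean, n, letters
    anova_f: float
    anova_p: float
    tukey_p: pd.DataFrame        # group x group adjusted p
    alpha: float
    degenerate: bool = False     # zero within-group variance convention used

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index_label=self.factor, float_format="%.10g")


def compact_letter_display(groups, sig_pairs) -> dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different.

    Insert-absorb: start with one letter covering every group; for each
    significant pair split any letter containing both members; drop letters
    that become subsets of others.
    """
    letters: list[set] = [set(groups)]
    for a, b in sig_pairs:
        for current in [l for l in letters if a in l and b in l]:
            letters.remove(current)
            for new in (current - {a}, current - {b}):
                if new and not any(new <= other for other in letters):
                    letters.append(new)
    # absorb duplicates and residual subset letters
    unique = []
    for l in letters:
        if l not in unique:
            unique.append(l)
    letters = [l for l in unique if not any(l < m for m in unique)]
    order = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda l: min(order[g] for g in l))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, str] = {g: "" for g in groups}
    for i, letter_set in enumerate(letters):
        symbol = alphabet[i % len(alphabet)] * (i // len(alphabet) + 1)
        for g in letter_set:
            assigned[g] += symbol
    return {g: "".join(sorted(s)) for g, s in assigned.items()}


def anova_tukey(values, groups, factor: str = "group", alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA + all-pairs Tukey HSD with a compact letter display.

    ``values`` are per-sample measurements, ``groups`` the parallel factor
    labels. Requires >= 2 groups with n >= 2 each. When every group has zero
    internal variance the F statistic degenerates; the convention used is
    p = 0 if any group means differ (flagged), else p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(groups)
    if len(values) != len(labels):
        raise ValueError("values and groups must have equal length")
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [values[(labels == g).to_numpy()] for g in names]
    small = [g for g, arr in zip(names, arrays) if arr.size < 2]
    if small:
        raise ValueError(f"groups with n < 2: {small}")

    within_ss = sum(((arr - arr.mean()) ** 2).sum() for arr in arrays)
    degenerate = within_ss == 0.0
    if degenerate:
        means = [arr.mean() for arr in arrays]
        if np.ptp(means) > 0:
            f_stat, p_val = float("inf"), 0.0
            pmat = np.zeros((len(names), len(names)))
            np.fill_diagonal(pmat, 1.0)
            # equal-valued groups (if any) are not distinguishable
            for i in range(len(names)):
                for j in range(len(names)):
                    if means[i] == means[j]:
                        pmat[i, j] = 1.0
        else:
            f_stat, p_val = float("nan"), 1.0
            pmat = np.ones((len(names), len(names)))
        logger.warning("anova_tukey: zero within-group variance; degenerate convention applied")
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        pmat = stats.tukey_hsd(*arrays).pvalue

    tukey_p = pd.DataFrame(pmat, index=names, columns=names)
    sig_pairs = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if tukey_p.iloc[i, j] < alpha
    ]
    letters = compact_letter_display(names, sig_pairs)
    summary = pd.DataFrame(
        {
            "mean": [arr.mean() for arr in arrays],
            "n": [arr.size for arr in arrays],
            "letters": [letters[g] for g in names],
        },
        index=names,
    )
    return GroupComparison(
        factor=factor,
        summary=summary,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        tukey_p=tukey_p,
        alpha=alpha,
        degenerate=degenerate,
    )
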