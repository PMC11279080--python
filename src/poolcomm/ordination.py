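"""Ordination: Bray-Curtis dissimilarity, non-metric MDS, and chemistry PCA.

NMDS is the classic Kruskal procedure: alternate isotonic (monotone)
regression of the embedded distances on the observed dissimilarities with
SMACOF/Guttman configuration updates, minimizing Kruskal stress-1

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 )

over several seeded starts (one principal-coordinates start plus random
restarts). Ties in the dissimilarities are handled by the primary
approach (tied dissimilarities may map to different disparities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.decomposition import PCA as _SkPCA
from sklearn.isotonic import IsotonicRegression


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity among samples of a count or proportion table.

    d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk); accepts either a
    :class:`~poolcomm.tables.CountTable` or a samples x taxa DataFrame.
    """
    df = table.data if hasattr(table, "data") else table
    totals = df.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-total samples have undefined Bray-Curtis distance: {zero}")
    condensed = pdist(df.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in df.index])


@dataclass
class NmdsResult:
    """Embedding coordinates with Kruskal stress-1 diagnostics."""

    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    converged: bool
    stress_history: list[float] = field(default_factory=list)  # best start, per iteration


def _disparities_and_stress(d: np.ndarray, delta: np.ndarray) -> tuple[np.ndarray, float]:
    """Primary-ties monotone regression of embedded d on dissimilarity delta."""
    order = np.lexsort((d, delta))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(d.size), d[order])
    dhat = np.empty_like(d)
    dhat[order] = fitted
    denom = float((d**2).sum())
    if denom == 0.0:
        return dhat, 0.0
    stress = float(np.sqrt(((d - dhat) ** 2).sum() / denom))
    return dhat, stress


def _guttman_update(coords: np.ndarray, dhat: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    b_mat = -squareform(ratio)
    np.fill_diagonal(b_mat, -b_mat.sum(axis=1))
    return b_mat @ coords / n


def _pcoa_start(dmat: np.ndarray, k: int) -> np.ndarray:
    """Classical-scaling start: eigendecomposition of the double-centered matrix."""
    n = dmat.shape[0]
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b_mat = -0.5 * j_mat @ (dmat**2) @ j_mat
    vals, vecs = np.linalg.eigh(b_mat)
    idx = np.argsort(vals)[::-1][:k]
    return vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmdsResult:
    """Non-metric MDS of a distance matrix into ``k`` dimensions.

    Runs one principal-coordinates start plus ``n_starts - 1`` random
    starts and keeps the configuration with the lowest final stress-1.
    Within a start, a Guttman update is accepted only if it does not
    increase stress (with step halving otherwise), so the per-iteration
    stress sequence is non-increasing. Returned coordinates are centered
    and rotated to principal axes with a deterministic sign convention.
    """
    dmat = np.asarray(dist.data, dtype=float)
    if not np.all(np.isfinite(dmat)):
        raise ValueError("distance matrix contains non-finite values")
    n = dmat.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} samples, have {n}")
    delta = squareform(dmat, checks=False)
    rng = np.random.default_rng(seed)
    scale = delta.max() if delta.max() > 0 else 1.0

    best = None
    for start in range(max(1, n_starts)):
        coords = _pcoa_start(dmat, k) if start == 0 else rng.uniform(-scale, scale, size=(n, k))
        d = pdist(coords)
        dhat, stress = _disparities_and_stress(d, delta)
        history = [stress]
        converged = False
        for _ in range(max_iter):
            candidate = _guttman_update(coords, dhat, d)
            accepted = False
            for _half in range(6):
                d_new = pdist(candidate)
                dhat_new, stress_new = _disparities_and_stress(d_new, delta)
                if stress_new <= stress:
                    accepted = True
                    break
                candidate = 0.5 * (candidate + coords)
            if not accepted:
                converged = True
                break
            improvement = stress - stress_new
            coords, d, dhat, stress = candidate, d_new, dhat_new, stress_new
            history.append(stress)
            if improvement < tol:
                converged = True
                break
        if best is None or stress < best[1]:
            best = (coords, stress, converged, history)

    coords, stress, converged, history = best
    coords = coords - coords.mean(axis=0)
    # rotate to principal axes; fix signs so each axis's largest |loading| is positive
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for j in range(coords.shape[1]):
        extreme = np.argmax(np.abs(coords[:, j]))
        if coords[extreme, j] < 0:
            coords[:, j] *= -1
    frame = pd.DataFrame(
        coords, index=list(dist.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NmdsResult(frame, float(stress), max(1, n_starts), converged, history)


@dataclass
class PcaResult:
    """Scores, loadings, explained variance and per-variable contributions."""

    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # variables x components
    explained_variance_ratio: pd.Series
    contributions: pd.DataFrame   # % of each component carried by each variable


def pca(chem: pd.DataFrame, standardize: bool = True, n_components: int | None = None) -> PcaResult:
    """PCA of a samples x variables table, with % contributions per component.

    Chemistry variables mix units (pH, uS/cm, mg/L...), so columns are
    z-scored by default. Contribution of variable v to component c is
    ``100 * loading_vc^2 / sum_v loading_vc^2``.
    """
    if chem.isna().any().any():
        raise ValueError("missing values in input")
    if chem.shape[0] < 2 or chem.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 variables")
    x_mat = chem.to_numpy(dtype=float)
    if standardize:
        sd = x_mat.std(axis=0, ddof=1)
        dead = [c for c, s in zip(chem.columns, sd) if s == 0]
        if dead:
            raise ValueError(f"zero-variance variables cannot be standardized: {dead}")
        x_mat = (x_mat - x_mat.mean(axis=0)) / sd
    else:
        x_mat = x_mat - x_mat.mean(axis=0)

    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x_mat)
    components = model.components_  # components x variables
    # deterministic orientation: largest |loading| per component is positive
    for c in range(components.shape[0]):
        extreme = np.argmax(np.abs(components[c]))
        if components[c, extreme] < 0:
            components[c] *= -1
            scores[:, c] *= -1
    names = [f"PC{i + 1}" for i in range(components.shape[0])]
    loadings = pd.DataFrame(components.T, index=chem.columns, columns=names)
    contributions = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PcaResult(
        scores=pd.DataFrame(scores, index=chem.index, columns=names),
        loadings=loadings,
        explained_variance_ratio=pd.Series(model.explained_variance_ratio_, index=names),
        contributions=contributions,
    )
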