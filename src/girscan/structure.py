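"""Population structure: genotype PCA, K-means over PCs with BIC, and
linear discriminant functions between the inferred clusters (DAPC-style).

The dosage matrix is mean-imputed per SNP, centred by the mean dosage 2p and
(optionally) scaled by the binomial standard deviation sqrt(2p(1-p)), which
compensates for differences in variance among allele frequencies.  The
percentage of variance carried by a component is its eigenvalue times 100
divided by the sum of all eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import MISSING, GenotypeMatrix


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # all components, descending
    percent_variance: np.ndarray  # shares of the total, sums to 100
    scores: np.ndarray  # samples x retained PCs
    loadings: np.ndarray  # SNPs x retained PCs


@dataclass
class ClusterModel:
    k_grid: list[int]
    bic: np.ndarray
    best_k: int
    assignments: np.ndarray
    discriminant_scores: np.ndarray | None = None


def percent_variance(eigenvalues: np.ndarray, total: float | None = None) -> np.ndarray:
    """Share of variance per component: eigenvalue * 100 / total.

    ``total`` defaults to the sum of the supplied eigenvalues; pass it
    explicitly when only the leading eigenvalues are known.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    total = float(eig.sum()) if total is None else float(total)
    if total <= 0:
        raise ValueError("total variance must be positive")
    return eig * 100.0 / total


def run_pca(g: GenotypeMatrix, n_pc: int, scale: bool = True) -> PCAResult:
    """PCA of the centred (and optionally frequency-scaled) dosage matrix.

    Missing calls are mean-imputed per SNP before centring.  Eigenvalues are
    those of the sample covariance matrix (ddof = 1).  SNPs that are
    monomorphic after imputation carry no information and are dropped from
    the decomposition when scaling (their binomial SD is zero).
    """
    n, m = g.n_samples, g.n_snps
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_pc = min(n - 1, m)
    if not (1 <= n_pc <= max_pc):
        raise ValueError(f"n_pc={n_pc} outside [1, {max_pc}]")
    x = g.calls.astype(float)
    obsmask = g.calls != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        colmean = np.where(obsmask.any(axis=0), np.where(obsmask, x, 0).sum(axis=0) / obsmask.sum(axis=0), 0.0)
    x = np.where(obsmask, x, colmean)
    p = colmean / 2.0
    x = x - colmean
    keep = np.ones(m, dtype=bool)
    if scale:
        sd = np.sqrt(2.0 * p * (1.0 - p))
        keep = sd > 0
        if not keep.any():
            raise ValueError("all SNPs constant; PCA undefined")
        x = x[:, keep] / sd[keep]
    if not x.any():
        raise ValueError("constant genotype matrix; PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    # deterministic sign: largest-magnitude loading positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u[:, :n_pc] * s[:n_pc]
    loadings = np.zeros((m, n_pc))
    loadings[keep] = vt[:n_pc].T
    return PCAResult(
        eigenvalues=eig,
        percent_variance=percent_variance(eig),
        scores=scores,
        loadings=loadings,
    )


def bic_kmeans(scores: np.ndarray, k: int, seed: int, n_starts: int) -> tuple[float, np.ndarray]:
    """BIC(K) = n ln(WSS/n) + K ln(n) for K-means on PC scores."""
    n = scores.shape[0]
    if k == 1:
        centre = scores.mean(axis=0)
        wss = float(((scores - centre) ** 2).sum())
        return n * np.log(wss / n) + np.log(n), np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(scores)
    wss = float(km.inertia_)
    if wss <= 0:  # perfectly collapsed clusters; keep BIC finite
        wss = np.finfo(float).tiny
    return n * np.log(wss / n) + k * np.log(n), labels


def select_k_bic(
    scores: np.ndarray, k_grid: list[int], seed: int, n_starts: int = 10
) -> ClusterModel:
    """K-means over the PC scores for each K in the grid; choose K by BIC.

    The selected K is the smallest one within 1e-9 of the minimum BIC
    (parsimony tie-break).  The seed fixes the k-means++ restart stream, so
    identical inputs give identical assignments.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    k_grid = sorted(int(k) for k in k_grid)
    if any(k < 1 or k > n - 1 for k in k_grid):
        raise ValueError(f"K grid must lie within [1, {n - 1}]")
    bics = np.empty(len(k_grid))
    labelings = []
    for i, k in enumerate(k_grid):
        bics[i], labels = bic_kmeans(scores, k, seed=seed + i, n_starts=n_starts)
        labelings.append(labels)
    best_i = int(np.flatnonzero(bics <= bics.min() + 1e-9)[0])
    return ClusterModel(
        k_grid=k_grid, bic=bics, best_k=k_grid[best_i], assignments=labelings[best_i]
    )


def discriminant_functions(
    scores: np.ndarray, assignments: np.ndarray, n_df: int
) -> np.ndarray:
    """Linear discriminant axes between clusters, evaluated on the PC scores.

    At most K-1 discriminant functions exist for K clusters; a larger request
    is clamped with a warning (e.g. 10 requested for 2 clusters yields 1).
    """
    scores = np.asarray(scores, dtype=float)
    assignments = np.asarray(assignments)
    k = len(np.unique(assignments))
    if k < 2:
        raise ValueError("discriminant functions require at least 2 clusters")
    n_df_eff = min(n_df, k - 1, scores.shape[1])
    if n_df_eff < n_df:
        warnings.warn(
            f"requested {n_df} discriminant functions; only {n_df_eff} exist for {k} clusters"
        )
    lda = LinearDiscriminantAnalysis(n_components=n_df_eff)
    df_scores = lda.fit_transform(scores, assignments)
    # deterministic sign per axis
    for j in range(df_scores.shape[1]):
        i = np.argmax(np.abs(df_scores[:, j]))
        if df_scores[i, j] < 0:
            df_scores[:, j] *= -1.0
    return df_scores
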