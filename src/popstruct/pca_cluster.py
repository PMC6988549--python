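"""PCA of the dosage matrix and cluster-count selection on PC scores.

Missing genotypes are replaced by the locus mean dosage (equivalent, up to a
factor of two, to mean allele-frequency imputation) and columns are centered
but not variance-scaled, matching the geometry adegenet's glPca/scaleGen
pipeline produces for SNP data.  The decomposition is a singular value
decomposition of the centered matrix; loadings are unit-norm right singular
vectors with a deterministic sign convention so that loading values are
comparable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .vcf_io import MISSING, GenotypeMatrix


@dataclass
class PCAFit:
    center: np.ndarray            # per-locus mean dosage
    eigenvalues: np.ndarray       # descending, = s^2 / (n - 1)
    scores: np.ndarray            # n_samples x n_axes
    loadings: np.ndarray          # n_loci x n_axes, unit-norm columns
    samples: list = field(default_factory=list)
    loci: list = field(default_factory=list)
    sign_convention: str = "largest_abs_positive"


def impute_center(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages and center columns; no scaling.

    Returns ``(X, center)`` where X is the real-valued n x m matrix with
    column sums zero and ``center`` the per-locus mean dosage used.
    """
    codes = gm.codes.astype(float)
    obs = gm.codes != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = [gm.loci[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"all-missing loci cannot be imputed: {bad[:5]}")
    center = np.where(obs, codes, 0.0).sum(axis=0) / n_obs
    X = np.where(obs, codes, center[None, :]) - center[None, :]
    return X, center


def pca(matrix: np.ndarray, n_axes: int, center: np.ndarray | None = None,
        samples: list | None = None, loci: list | None = None) -> PCAFit:
    """SVD-based principal component analysis of a centered matrix.

    Scores are the sample projections (U S); eigenvalues are s^2/(n-1),
    i.e. the covariance-matrix eigenvalues.  Requests beyond the matrix
    rank are truncated with a warning.  Each loading column is flipped, if
    needed, so its largest-magnitude entry is positive.
    """
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    if n_axes > min(n, m):
        raise ValueError(f"n_axes={n_axes} exceeds min(n, m)={min(n, m)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if n_axes > rank:
        warnings.warn(f"requested {n_axes} axes but rank is {rank}; truncating")
        n_axes = max(rank, 1) if s.size else 0
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes, :]
    loadings = Vt.T.copy()
    scores = U * s
    for a in range(n_axes):
        i = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[i, a] < 0:
            loadings[:, a] *= -1.0
            scores[:, a] *= -1.0
    eig = s ** 2 / max(n - 1, 1)
    return PCAFit(center=center if center is not None else np.zeros(m),
                  eigenvalues=eig, scores=scores, loadings=loadings,
                  samples=list(samples) if samples else [],
                  loci=list(loci) if loci else [])


def pca_genotypes(gm: GenotypeMatrix, n_axes: int) -> PCAFit:
    """Convenience: impute-and-center a genotype matrix, then run PCA."""
    X, center = impute_center(gm)
    return PCAFit(**{**pca(X, n_axes, center=center).__dict__,
                     "samples": list(gm.samples), "loci": list(gm.loci)})


def find_k_clusters(scores: np.ndarray, max_k: int, seed: int = 0,
                    n_restarts: int = 20) -> tuple[np.ndarray, int]:
    """BIC-scored k-means over retained PC scores.

    BIC(k) = n log(WSS_k / n) + k log(n), with WSS_k the within-cluster sum
    of squares from the best of ``n_restarts`` k-means runs.  Returns the
    per-k BIC array (index 0 = k=1) and the argmin k (ties to smaller k).
    """
    if max_k < 2:
        raise ValueError("max_k must be >= 2")
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if max_k >= n:
        warnings.warn(f"max_k={max_k} >= n={n}; capped at {n - 1}")
        max_k = max(n - 1, 1)
    bics = np.empty(max_k)
    for k in range(1, max_k + 1):
        if k == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            km.fit(X)
            wss = float(km.inertia_)
        wss = max(wss, 1e-300)  # identical-points guard
        bics[k - 1] = n * np.log(wss / n) + k * np.log(n)
    best_k = int(np.argmin(bics)) + 1
    return bics, best_k
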