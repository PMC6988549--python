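"""Ancestry estimation by sparse nonnegative matrix factorization.

Genotypes are encoded as per-locus genotype-class indicators (three columns
per locus, one per dosage class).  The model factorizes this indicator
matrix as Q G, where Q (individuals x K) holds ancestry proportions on the
probability simplex and G (K x 3m) holds per-cluster genotype-class
frequencies, each cluster-locus triple on the simplex.  Fitting alternates
projected-gradient nonnegative least-squares updates of Q and G with exact
per-block Lipschitz steps, which makes the masked squared loss monotonically
non-increasing.

Model choice (K) uses a held-out criterion: a random fraction of observed
genotypes is masked before fitting and the mean negative log predicted
probability of the masked classes (cross-entropy) scores each K.  The
Evanno second-difference statistic over replicate criterion values gives an
alternative K diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .vcf_io import GenotypeMatrix, SampleTable

_CLIP_LO = 1e-10


def project_rows_to_simplex(M: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of M onto the probability simplex."""
    K = M.shape[-1]
    u = np.sort(M, axis=-1)[..., ::-1]
    css = np.cumsum(u, axis=-1) - 1.0
    ind = np.arange(1, K + 1)
    cond = u - css / ind > 0
    rho = K - np.argmax(cond[..., ::-1], axis=-1) - 1  # last True index
    theta = np.take_along_axis(css, rho[..., None], axis=-1) / (rho + 1)[..., None]
    return np.maximum(M - theta, 0.0)


@dataclass
class AdmixtureFit:
    """Result of one NMF ancestry fit."""

    K: int
    Q: np.ndarray                 # n_samples x K ancestry proportions
    F: np.ndarray                 # K x n_loci cluster alt-allele frequencies
    G: np.ndarray                 # K x n_loci x 3 genotype-class frequencies
    cross_entropy: float
    seed: int
    n_iter: int
    converged: bool
    samples: list = field(default_factory=list)
    loci: list = field(default_factory=list)
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def _indicator(codes: np.ndarray) -> np.ndarray:
    """n x m dosage codes -> n x (3m) one-hot indicators (0 rows if missing)."""
    n, m = codes.shape
    X = np.zeros((n, 3 * m))
    obs = codes >= 0
    i, j = np.nonzero(obs)
    X[i, 3 * j + codes[i, j]] = 1.0
    return X


def _spectral_init(codes: np.ndarray, fit_obs: np.ndarray, K: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Initialize Q from k-means on PCA scores of the mean-imputed matrix.

    Random restarts alone find poor optima when differentiation is weak;
    the leading PCs concentrate whatever population signal exists, so
    clustering there gives a reliable starting partition (the same idea
    spectral initializations use in other ancestry factorizations).  A
    seed-dependent jitter keeps replicate fits distinct.
    """
    from sklearn.cluster import KMeans

    n, m = codes.shape
    X = np.where(fit_obs, codes, np.nan).astype(float)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu[None, :], X) - mu[None, :]
    n_axes = min(max(K - 1, 1), min(n, m) - 1)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_axes] * s[:n_axes]
    labels = KMeans(K, n_init=5, random_state=int(rng.integers(2 ** 31))
                    ).fit(scores).labels_
    Q = np.full((n, K), 0.10 / max(K - 1, 1))
    Q[np.arange(n), labels] = 0.90
    Q = project_rows_to_simplex(Q + rng.uniform(0, 0.05, size=(n, K)))
    # Per-cluster genotype-class frequencies from the initial partition.
    G = np.empty((K, m, 3))
    for k in range(K):
        rows = labels == k
        for c in range(3):
            G[k, :, c] = ((codes[rows] == c) & fit_obs[rows]).sum(axis=0)
    G = (G + 1.0) / (G.sum(axis=2, keepdims=True) + 3.0)
    return Q, G.reshape(K, 3 * m)


def snmf_fit(gm: GenotypeMatrix, K: int, seed: int = 0,
             mask_fraction: float = 0.05, max_iter: int = 500,
             tol: float = 1e-6, inner_steps: int = 3,
             alpha: float = 0.0, init: str = "spectral",
             mask_seed: Optional[int] = None) -> AdmixtureFit:
    """Fit the K-cluster NMF ancestry model.

    Parameters
    ----------
    mask_fraction : float
        Fraction of observed genotypes held out (uniformly at random, from
        ``seed``) before fitting; the cross-entropy on these entries is the
        model-choice criterion.
    alpha : float
        Ridge penalty on Q (the sparsity-style regularizer); 0 by default.
    init : {"spectral", "random"}
        Starting point: k-means on leading PCs (default) or random.
    mask_seed : int, optional
        Separate seed for the held-out mask (defaults to ``seed``).  K
        selection passes a per-replicate mask seed shared across K so that
        criterion comparisons between K values are paired on the same
        held-out entries.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_samples:
        raise ValueError(f"K={K} exceeds number of samples ({gm.n_samples})")
    rng = np.random.default_rng(seed)
    codes = gm.codes
    n, m = codes.shape
    obs = codes >= 0
    if not obs.any(axis=0).all():
        raise ValueError("matrix contains all-missing loci")

    # Hold out a random subset of observed entries for the criterion.
    mask_rng = rng if mask_seed is None else np.random.default_rng(mask_seed)
    oi, oj = np.nonzero(obs)
    n_mask = int(round(mask_fraction * oi.size))
    masked_idx = (mask_rng.choice(oi.size, size=n_mask, replace=False)
                  if n_mask else np.empty(0, int))
    fit_obs = obs.copy()
    fit_obs[oi[masked_idx], oj[masked_idx]] = False

    X = _indicator(np.where(fit_obs, codes, -1))
    W = np.repeat(fit_obs, 3, axis=1).astype(float)

    if init == "spectral" and K >= 2:
        Q, G = _spectral_init(codes, fit_obs, K, rng)
    elif init in ("spectral", "random"):
        Q = rng.dirichlet(np.ones(K), size=n)
        cls = np.zeros((m, 3))
        for c in range(3):
            cls[:, c] = ((codes == c) & fit_obs).sum(axis=0)
        cls = (cls + 1.0) / (cls.sum(axis=1, keepdims=True) + 3.0)
        G = np.clip(cls[None, :, :] + rng.uniform(-0.05, 0.05, size=(K, m, 3)),
                    1e-3, None)
        G = project_rows_to_simplex(G).reshape(K, 3 * m)
    else:
        raise ValueError(f"unknown init {init!r}")

    def loss(Qm, Gm):
        R = Qm @ Gm - X
        return float(np.einsum("ij,ij,ij->", W, R, R)) + alpha * float((Qm ** 2).sum())

    history = [loss(Q, G)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Q block: projected gradient with step 1/L, L = 2 lam_max(G G^T).
        GGt = G @ G.T
        L_Q = 2.0 * float(np.linalg.eigvalsh(GGt)[-1]) + 2.0 * alpha + 1e-12
        for _ in range(inner_steps):
            grad = 2.0 * ((W * (Q @ G - X)) @ G.T) + 2.0 * alpha * Q
            Q = project_rows_to_simplex(Q - grad / L_Q)
        # G block: same scheme, simplex per cluster-locus triple.
        QtQ = Q.T @ Q
        L_G = 2.0 * float(np.linalg.eigvalsh(QtQ)[-1]) + 1e-12
        for _ in range(inner_steps):
            grad = 2.0 * (Q.T @ (W * (Q @ G - X)))
            G = project_rows_to_simplex(
                (G - grad / L_G).reshape(K, m, 3)).reshape(K, 3 * m)
        history.append(loss(Q, G))
        prev, cur = history[-2], history[-1]
        if prev - cur <= tol * max(prev, 1e-30):
            converged = True
            break

    # Held-out cross-entropy: -log predicted probability of the observed class.
    if n_mask:
        mi, mj = oi[masked_idx], oj[masked_idx]
        probs = np.einsum("ik,ik->i", Q[mi], G[:, 3 * mj + codes[mi, mj]].T)
        cross_entropy = float(-np.log(np.clip(probs, _CLIP_LO, 1.0)).mean())
    else:
        cross_entropy = float("nan")

    G3 = G.reshape(K, m, 3)
    F = (G3[:, :, 1] + 2.0 * G3[:, :, 2]) / 2.0
    return AdmixtureFit(K=K, Q=Q, F=F, G=G3, cross_entropy=cross_entropy,
                        seed=seed, n_iter=it, converged=converged,
                        samples=list(gm.samples), loci=list(gm.loci),
                        loss_history=np.asarray(history))


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------

@dataclass
class KSelection:
    k_values: list
    criterion: dict               # K -> list of replicate cross-entropies
    best_k: int
    delta_k: dict                 # interior K -> Evanno statistic (NaN if undefined)


def evanno_delta_k(criterion: Mapping[int, Sequence[float]]) -> dict:
    """Evanno second-difference statistic over replicate criterion values.

    For each interior K, DeltaK(K) = mean over replicates of
    ``|L(K-1) - 2 L(K) + L(K+1)|`` divided by the across-replicate standard
    deviation of L(K) (n-1 denominator).  The absolute second difference is
    orientation-free, so likelihoods and cross-entropies give the same value.
    Zero replicate spread makes the statistic undefined (NaN, with warning).
    """
    ks = sorted(criterion)
    if len(ks) < 3:
        raise ValueError("need >=3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    L = {k: np.asarray(criterion[k], dtype=float) for k in ks}
    for k in ks:
        if L[k].size < 2:
            raise ValueError("need >=2 replicates per K")
    out = {}
    for k in ks[1:-1]:
        r = min(L[k - 1].size, L[k].size, L[k + 1].size)
        second = np.abs(L[k - 1][:r] - 2.0 * L[k][:r] + L[k + 1][:r])
        sd = float(np.std(L[k], ddof=1))
        if sd == 0.0:
            warnings.warn(f"DeltaK undefined at K={k}: zero replicate spread")
            out[k] = float("nan")
        else:
            out[k] = float(second.mean() / sd)
    return out


def select_K(gm: GenotypeMatrix, k_range: Sequence[int], replicates: int = 10,
             seed: int = 0, mask_fraction: float = 0.05,
             **fit_kwargs) -> KSelection:
    """Fit every K in a contiguous range with replicate seeds; choose the K
    minimizing mean held-out cross-entropy (ties resolved to the smaller K)."""
    ks = sorted(k_range)
    if not ks:
        raise ValueError("empty K range")
    criterion = {}
    for k in ks:
        vals = []
        for r in range(replicates):
            rep_seed = (seed * 100003 + k * 1009 + r) % (2 ** 31)
            mask_seed = (seed * 7919 + r) % (2 ** 31)   # shared across K
            fit = snmf_fit(gm, k, seed=rep_seed, mask_fraction=mask_fraction,
                           mask_seed=mask_seed, **fit_kwargs)
            vals.append(fit.cross_entropy)
        criterion[k] = vals
    means = np.array([np.mean(criterion[k]) for k in ks])
    best_k = int(ks[int(np.argmin(means))])  # argmin takes first == smaller K
    delta = {}
    if len(ks) >= 3 and replicates >= 2 and all(b - a == 1 for a, b in zip(ks, ks[1:])):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            delta = evanno_delta_k(criterion)
    return KSelection(k_values=ks, criterion=criterion, best_k=best_k, delta_k=delta)


# ---------------------------------------------------------------------------
# Assignment and summaries
# ---------------------------------------------------------------------------

def assign_individuals(fit: AdmixtureFit) -> np.ndarray:
    """Hard cluster label per individual: index of the largest Q entry, ties
    broken toward the lowest cluster index."""
    labels = np.argmax(fit.Q, axis=1)
    row_max = fit.Q[np.arange(len(labels)), labels]
    ties = (np.isclose(fit.Q, row_max[:, None]).sum(axis=1) > 1)
    if ties.any():
        warnings.warn(f"{int(ties.sum())} individuals had tied top clusters; "
                      "assigned to the lowest index")
    return labels


def regional_assignment_summary(labels: np.ndarray, st: SampleTable,
                                sample_ids: Optional[Sequence[str]] = None
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage (and count) of individuals per region assigned to each
    cluster.  Regions with zero samples are omitted with a warning."""
    tbl = st.table
    if sample_ids is not None:
        tbl = tbl.set_index("sample_id").loc[list(sample_ids)].reset_index()
    if len(labels) != len(tbl):
        raise ValueError("labels not aligned to sample table")
    df = pd.DataFrame({"region": tbl["region"].to_numpy(), "cluster": labels})
    counts = df.groupby(["region", "cluster"]).size().unstack(fill_value=0)
    present = counts.sum(axis=1) > 0
    if (~present).any():
        warnings.warn(f"regions with no samples omitted: {list(counts.index[~present])}")
    counts = counts[present]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct, counts


@dataclass
class ClusterSummary:
    net_nucleotide_distance: np.ndarray   # K x K, zero diagonal
    expected_heterozygosity: np.ndarray   # per cluster
    within_cluster_fst: np.ndarray        # per cluster


def cluster_summaries(fit: AdmixtureFit) -> ClusterSummary:
    """Allele-frequency-based cluster descriptors.

    With per-cluster frequencies p_k(l): the raw gene diversity between
    clusters j,k is D(j,k) = mean_l [1 - p_j p_k - (1-p_j)(1-p_k)]; the net
    nucleotide distance subtracts the average of the self terms.  Expected
    heterozygosity is mean_l 2 p_k (1-p_k); the within-cluster Fst compares
    it to the heterozygosity at the equal-weight across-cluster mean
    frequency.
    """
    P = fit.F
    K = P.shape[0]
    D = np.empty((K, K))
    for j in range(K):
        for k in range(K):
            D[j, k] = float(np.mean(1.0 - P[j] * P[k] - (1 - P[j]) * (1 - P[k])))
    net = D - (np.diag(D)[:, None] + np.diag(D)[None, :]) / 2.0
    np.fill_diagonal(net, 0.0)
    het = np.array([float(np.mean(2 * P[k] * (1 - P[k]))) for k in range(K)])
    pbar = P.mean(axis=0)
    h_anc = float(np.mean(2 * pbar * (1 - pbar)))
    fst = 1.0 - het / h_anc if h_anc > 0 else np.zeros(K)
    return ClusterSummary(net_nucleotide_distance=net,
                          expected_heterozygosity=het,
                          within_cluster_fst=fst)


# ---------------------------------------------------------------------------
# Cluster-label alignment (indices are arbitrary across runs)
# ---------------------------------------------------------------------------

def align_clusters(Q_est: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Greedy maximum-correlation matching of estimated to reference columns.

    Returns ``perm`` such that ``Q_est[:, perm]`` is aligned to ``Q_ref``.
    """
    K = Q_ref.shape[1]
    if Q_est.shape[1] != K:
        raise ValueError("column counts differ")
    C = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            xa = Q_est[:, a] - Q_est[:, a].mean()
            xb = Q_ref[:, b] - Q_ref[:, b].mean()
            den = np.sqrt((xa ** 2).sum() * (xb ** 2).sum())
            C[a, b] = (xa * xb).sum() / den if den > 0 else -np.inf
    perm = np.full(K, -1)
    used_a, used_b = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(C, axis=None)[::-1], C.shape))[0]
    for a, b in order:
        if a in used_a or b in used_b:
            continue
        perm[b] = a
        used_a.add(a)
        used_b.add(b)
        if len(used_b) == K:
            break
    return perm


def aligned_q_rmse(Q_est: np.ndarray, Q_true: np.ndarray) -> float:
    """Root-mean-square entrywise error after greedy column alignment."""
    perm = align_clusters(Q_est, Q_true)
    return float(np.sqrt(np.mean((Q_est[:, perm] - Q_true) ** 2)))
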