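"""PCA and Ward hierarchical clustering of cultivar x trait matrices.

Trait matrices mix units (N, %, MPa, µg/kg), so columns are standardized
(and volatile concentrations log-transformed) before any multivariate
step. Cluster count is selected from the Ward merge history by the
relative-inertia-jump (elbow) rule, and agreement between two partitions
of the same cultivars (e.g. phenotypic vs genetic clusters) is scored by
the adjusted Rand index with a permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score

from .errors import InputError

logger = logging.getLogger(__name__)


def prepare_matrix(
    matrix: pd.DataFrame, *, log10: bool = False, standardize: bool = True,
    floor: float = 1e-3,
) -> pd.DataFrame:
    """Impute, optionally log-transform, and standardize a trait matrix.

    Missing cells are imputed by the trait median (count logged);
    ``log10=True`` applies log10 of the floored value (volatile
    concentrations span several orders of magnitude); standardization
    centers and unit-scales columns, dropping zero-variance ones with a
    warning.
    """
    X = matrix.astype(float).copy()
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        logger.info("prepare_matrix: imputing %d missing cells by trait median", n_missing)
        X = X.fillna(X.median())
    if log10:
        X = np.log10(X.clip(lower=floor))
    if standardize:
        sd = X.std(ddof=0)
        dead = sd[sd == 0].index
        if len(dead):
            logger.warning("prepare_matrix: dropping %d zero-variance traits", len(dead))
            X = X.drop(columns=dead)
            sd = sd.drop(dead)
        X = (X - X.mean()) / sd
    return X


@dataclass
class PCAResult:
    scores: pd.DataFrame          # cultivars x components
    loadings: pd.DataFrame        # traits x components, orthonormal columns
    variance_fractions: np.ndarray


def pca(matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Centered (optionally unit-scaled) principal component analysis.

    Component sign is fixed by making each component's largest-magnitude
    loading positive, so results are fully deterministic.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise InputError("pca needs at least 2 rows and 2 columns")
    X = prepare_matrix(matrix, standardize=scale)
    if not scale:
        X = X - X.mean()
    U, s, Vt = np.linalg.svd(X.values, full_matrices=False)
    # deterministic sign: largest |loading| per component made positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    comp = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=X.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp),
        variance_fractions=frac,
    )


@dataclass
class ClusterResult:
    labels: pd.Series             # cultivar -> 1..k
    k: int
    linkage_matrix: np.ndarray    # scipy linkage (merge history)
    method: str = "ward-euclidean"

    def cut(self, k: int) -> pd.Series:
        if k > len(self.labels):
            raise InputError(f"k {k} > n {len(self.labels)}")
        lab = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.labels.index)


def ward_cluster(matrix: pd.DataFrame, k: int | None = None,
                 standardize: bool = True) -> ClusterResult:
    """Agglomerative Ward clustering on Euclidean distances."""
    if matrix.shape[0] < 2:
        raise InputError("ward_cluster needs >= 2 rows")
    if k is not None and k > matrix.shape[0]:
        raise InputError(f"k {k} > n {matrix.shape[0]}")
    X = prepare_matrix(matrix, standardize=standardize)
    Z = linkage(X.values, method="ward")
    kk = k if k is not None else 2
    labels = pd.Series(fcluster(Z, t=kk, criterion="maxclust"), index=matrix.index)
    return ClusterResult(labels=labels, k=kk, linkage_matrix=Z)


@dataclass
class KSelection:
    k: int
    ratios: dict[int, float]
    confident: bool


def choose_k(cluster: ClusterResult, k_max: int = 10,
             flat_ratio: float = 2.0) -> KSelection:
    """Cluster count from the merge history by the relative-jump rule.

    Ward merge heights grow with the inertia cost of each merge. Let
    h(K) be the height of the merge that reduces K clusters to K-1; the
    selected K maximizes h(K) / h(K+1) over 2..k_max — the cut just
    before the cost of merging jumps the most. When no ratio exceeds
    ``flat_ratio`` the structure is considered flat and the default K=2
    is returned with ``confident=False``.
    """
    Z = cluster.linkage_matrix
    n = Z.shape[0] + 1
    k_max = min(k_max, n - 1)
    heights = Z[:, 2]
    eps = max(heights.max(), 1.0) * 1e-12
    ratios = {}
    for k in range(2, k_max + 1):
        h_k = heights[n - k]          # merge K -> K-1 clusters
        h_next = heights[n - k - 1]   # merge K+1 -> K clusters
        ratios[k] = float((h_k + eps) / (h_next + eps))
    k_best = max(ratios, key=lambda k: (ratios[k], -k))
    confident = ratios[k_best] >= flat_ratio
    if not confident:
        logger.info("choose_k: flat inertia profile (max ratio %.2f); defaulting to K=2",
                    ratios[k_best])
        k_best = 2
    return KSelection(k=k_best, ratios=ratios, confident=confident)


def cluster_association(
    labels_a: pd.Series, labels_b: pd.Series, n_perm: int = 999, seed: int = 0,
) -> tuple[float, float]:
    """Adjusted Rand index between two partitions plus a permutation p-value.

    p = (1 + #{permuted ARI >= observed}) / (n_perm + 1) under random
    relabelling of the second partition.
    """
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    a, b = pd.Series(labels_a), pd.Series(labels_b)
    if set(a.index) != set(b.index):
        raise InputError("cluster_association: cultivar sets differ")
    b = b.reindex(a.index)
    ari = float(adjusted_rand_score(a.values, b.values))
    rng = np.random.default_rng(seed)
    count = 0
    bv = b.values.copy()
    for _ in range(n_perm):
        perm = rng.permutation(bv)
        if adjusted_rand_score(a.values, perm) >= ari:
            count += 1
    return ari, (1 + count) / (n_perm + 1)


def linkage_to_newick(cluster: ClusterResult) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    Z = cluster.linkage_matrix
    names = list(cluster.labels.index)
    n = len(names)
    height = {i: 0.0 for i in range(n)}
    node = {i: names[i] for i in range(n)}
    for r in range(Z.shape[0]):
        a, b, h = int(Z[r, 0]), int(Z[r, 1]), float(Z[r, 2])
        la, lb = h - height[a], h - height[b]
        node[n + r] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + r] = h
    return node[n + Z.shape[0] - 1] + ";"
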