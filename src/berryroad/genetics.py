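"""Mixed-ploidy microsatellite genetic structure.

Covers the marker-side analyses of a germplasm panel scored at a handful
of SSR loci across tetraploid and hexaploid accessions:

* allele-size correction for the universal 5' primer tails used in
  fluorescent genotyping;
* Bruvo's genetic distance, a stepwise-mutation-model distance on allele
  repeat counts that remains well defined across ploidy levels (the
  genome-addition model handles tetraploid x hexaploid comparisons);
* neighbour-joining trees with locus-resampling bootstrap supports;
* DAPC-style clustering: K-means on PCA-transformed allele frequencies
  with BIC model selection, followed by a regularized linear discriminant
  step yielding posterior group memberships.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import InputError

logger = logging.getLogger(__name__)

#: Universal 5' primer tail sequences; genotyped fragment sizes include
#: the tail, which must be subtracted to recover the true allele size.
TAIL_SEQUENCES = {
    "T7": "TAATACGACTCACTATAGGG",
    "M13": "TGTAAAACGACGGCCAGT",
    "M13R": "CAGGAAACAGCTATGACC",
    "D12S1090f": "CTATAGGGCACGCGTGGT",
}


def adjust_allele_sizes(sizes, tail: str):
    """Subtract the universal-tail length from raw fragment sizes."""
    if tail not in TAIL_SEQUENCES:
        raise InputError(
            f"unknown tail {tail!r}; known tails: {sorted(TAIL_SEQUENCES)}")
    n = len(TAIL_SEQUENCES[tail])
    arr = np.asarray(sizes, dtype=float) - n
    return arr if np.ndim(sizes) else float(arr)


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class Genotype:
    """One accession's multilocus SSR profile.

    ``alleles`` maps locus name to the tuple of scored allele sizes in
    base pairs (1..ploidy entries; missing loci simply absent).
    """

    cultivar: str
    ploidy: int
    alleles: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ploidy not in (4, 6):
            raise InputError(f"{self.cultivar}: ploidy must be 4 or 6, got {self.ploidy}")
        for locus, a in self.alleles.items():
            if not (1 <= len(a) <= self.ploidy):
                raise InputError(
                    f"{self.cultivar}/{locus}: {len(a)} alleles for ploidy {self.ploidy}")


def genotypes_from_frame(frame: pd.DataFrame) -> list[Genotype]:
    """Parse the long-form genotype table (cultivar, locus, allele_1..6, ploidy)."""
    allele_cols = [c for c in frame.columns if c.startswith("allele_")]
    out = []
    for cultivar, grp in frame.groupby("cultivar", sort=True):
        ploidy = int(grp["ploidy"].iloc[0])
        alleles = {}
        for _, row in grp.iterrows():
            vals = tuple(int(row[c]) for c in allele_cols if pd.notna(row[c]))
            if vals:
                alleles[row["locus"]] = vals
        out.append(Genotype(str(cultivar), ploidy, alleles))
    return out


def to_repeat_units(
    genotypes: list[Genotype], repeat_lengths: dict[str, int],
    offsets: dict[str, int] | None = None,
) -> dict[str, dict[str, tuple[int, ...]]]:
    """Convert allele sizes to integer repeat units per locus.

    units = round((size - offset) / repeat_length); the offset defaults to
    the cohort-minimum allele at each locus, so the smallest allele maps
    to zero repeats.
    """
    if offsets is None:
        offsets = {}
        for locus in repeat_lengths:
            sizes = [a for g in genotypes for a in g.alleles.get(locus, ())]
            offsets[locus] = min(sizes) if sizes else 0
    units: dict[str, dict[str, tuple[int, ...]]] = {}
    for g in genotypes:
        units[g.cultivar] = {}
        for locus, sizes in g.alleles.items():
            rep = repeat_lengths[locus]
            units[g.cultivar][locus] = tuple(
                int(round((s - offsets[locus]) / rep)) for s in sizes)
    return units


# ---------------------------------------------------------------------------
# Bruvo distance


def _allele_distance_matrix(a: tuple[int, ...], b: tuple[int, ...]) -> np.ndarray:
    diff = np.abs(np.subtract.outer(np.asarray(a, float), np.asarray(b, float)))
    return 1.0 - np.power(2.0, -diff)


def _pads(alleles: tuple[int, ...], target: int):
    """All ways to extend a genotype to ``target`` alleles with copies of itself."""
    need = target - len(alleles)
    if need <= 0:
        yield alleles
        return
    for extra in itertools.combinations_with_replacement(sorted(set(alleles)), need):
        yield alleles + extra


def bruvo_locus_distance(a: tuple[int, ...], b: tuple[int, ...],
                         ploidy_a: int, ploidy_b: int) -> float:
    """Bruvo distance at one locus, alleles in repeat units.

    Per allele pair the distance is 1 - 2^-|x| with x the repeat-count
    difference. Each genotype is first completed to its own ploidy
    (partial heterozygotes padded with copies of observed alleles), the
    lower-ploidy genotype is then padded up to the higher ploidy (genome
    addition), and the reported value is the minimum over all pads of the
    minimum-cost perfect matching's mean allele distance.
    """
    n = max(ploidy_a, ploidy_b)
    best = np.inf
    for pa in _pads(a, ploidy_a):
        for pa2 in _pads(pa, n):
            for pb in _pads(b, ploidy_b):
                for pb2 in _pads(pb, n):
                    d = _allele_distance_matrix(pa2, pb2)
                    ri, ci = linear_sum_assignment(d)
                    best = min(best, d[ri, ci].mean())
    return float(best)


def bruvo_distance(
    units_a: dict[str, tuple[int, ...]], units_b: dict[str, tuple[int, ...]],
    ploidy_a: int, ploidy_b: int,
) -> float:
    """Mean Bruvo distance over the loci scored in both genotypes."""
    shared = sorted(set(units_a) & set(units_b))
    if not shared:
        logger.warning("bruvo_distance: no shared loci; distance missing")
        return float("nan")
    return float(np.mean([
        bruvo_locus_distance(units_a[loc], units_b[loc], ploidy_a, ploidy_b)
        for loc in shared]))


def _per_locus_distances(
    genotypes: list[Genotype], repeat_lengths: dict[str, int],
) -> tuple[list[str], list[str], np.ndarray]:
    """Per-locus Bruvo distance matrices (loci x n x n), NaN where unscored."""
    units = to_repeat_units(genotypes, repeat_lengths)
    names = [g.cultivar for g in genotypes]
    ploidy = {g.cultivar: g.ploidy for g in genotypes}
    loci = sorted(repeat_lengths)
    n = len(names)
    out = np.full((len(loci), n, n), np.nan)
    for li, locus in enumerate(loci):
        for i in range(n):
            ui = units[names[i]].get(locus)
            if ui is None:
                continue
            out[li, i, i] = 0.0
            for j in range(i + 1, n):
                uj = units[names[j]].get(locus)
                if uj is None:
                    continue
                d = bruvo_locus_distance(ui, uj, ploidy[names[i]], ploidy[names[j]])
                out[li, i, j] = out[li, j, i] = d
    return names, loci, out


def bruvo_distance_matrix(
    genotypes: list[Genotype], repeat_lengths: dict[str, int],
) -> pd.DataFrame:
    """Pairwise Bruvo distances averaged over shared loci."""
    names, _, per_locus = _per_locus_distances(genotypes, repeat_lengths)
    with np.errstate(invalid="ignore"):
        mat = np.nanmean(per_locus, axis=0)
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Neighbour-joining tree from a complete distance matrix.

    Standard agglomeration; a negative branch length produced by the NJ
    formulas is clamped to zero with the deficit moved to its sibling so
    the path length between the joined nodes is preserved.
    """
    if dist.isna().any().any():
        raise InputError("nj_tree requires a complete distance matrix")
    names = list(dist.index)
    n = len(names)
    if n < 2:
        raise InputError("nj_tree needs >= 2 taxa")
    taxa = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in names:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)
    D = dist.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bi, bj = 0.0, dij
        elif bj < 0:
            bi, bj = dij, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(bi)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(bj)
        # distances from the new node to the remaining taxa
        dnew = 0.5 * (sub[ai, :] + sub[aj, :] - dij)
        for k_pos, k in enumerate(active):
            D[i, k] = D[k, i] = dnew[k_pos]
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j = active
    root = dendropy.Node()
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    if nodes[i].is_leaf() and nodes[j].is_leaf():
        # two-taxon tree: a single edge carrying the full distance
        nodes[i].edge.length = float(D[i, j])
        nodes[j].edge.length = 0.0
    else:
        half = 0.5 * float(D[i, j])
        nodes[i].edge.length = half
        nodes[j].edge.length = half
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance between two trees on shared taxa."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    for t in (a, b):  # compare as unrooted topologies
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.update_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def bootstrap_nj(
    genotypes: list[Genotype], repeat_lengths: dict[str, int],
    n_boot: int = 200, seed: int = 0,
) -> dendropy.Tree:
    """NJ tree on the full data with locus-resampling bootstrap supports.

    Loci are resampled with replacement ``n_boot`` times; the support of
    each internal bipartition of the full-data tree is the fraction of
    replicate trees that contain it, written as the internal node label.
    ``n_boot=0`` returns the tree without supports.
    """
    names, loci, per_locus = _per_locus_distances(genotypes, repeat_lengths)
    if len(loci) < 2 and n_boot > 0:
        raise InputError("bootstrap needs >= 2 loci to resample")
    with np.errstate(invalid="ignore"):
        full = pd.DataFrame(np.nanmean(per_locus, axis=0), index=names, columns=names)
    if full.isna().any().any():
        raise InputError("incomplete distance matrix (cultivar pairs with no shared loci)")
    tree = nj_tree(full)
    if n_boot == 0:
        return tree
    rng = np.random.default_rng(seed)
    tree.encode_bipartitions()
    counts: dict[int, int] = {}
    keys = {}
    for edge in tree.preorder_edge_iter():
        if edge.bipartition and not edge.head_node.is_leaf() and edge.head_node.parent_node:
            keys[int(edge.bipartition.split_bitmask)] = edge.head_node
            counts[int(edge.bipartition.split_bitmask)] = 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(loci), size=len(loci))
        with np.errstate(invalid="ignore"):
            mat = np.nanmean(per_locus[pick], axis=0)
        rep = nj_tree(pd.DataFrame(mat, index=names, columns=names))
        rep2 = dendropy.Tree.get(data=rep.as_string(schema="newick"), schema="newick",
                                 taxon_namespace=tree.taxon_namespace)
        rep2.encode_bipartitions()
        rep_splits = {int(b.split_bitmask) for b in rep2.bipartition_encoding}
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    for key, node in keys.items():
        node.label = f"{100.0 * counts[key] / n_boot:.0f}"
    return tree


# ---------------------------------------------------------------------------
# DAPC


@dataclass
class DAPCResult:
    """Model-selection curve and discriminant assignment of a DAPC run."""

    bic: dict[int, float]
    k: int
    n_pc: int
    labels: np.ndarray           # hard assignment, values in 1..k
    posteriors: np.ndarray       # n x k, rows sum to 1
    scores: np.ndarray           # discriminant-axis coordinates
    cultivars: list[str]


def encode_genotypes(genotypes: list[Genotype]) -> tuple[pd.DataFrame, list[str]]:
    """Within-individual allele frequencies (count / ploidy per allele column)."""
    columns = sorted({(locus, a) for g in genotypes
                      for locus, alleles in g.alleles.items() for a in alleles})
    names = [g.cultivar for g in genotypes]
    X = np.zeros((len(genotypes), len(columns)))
    col = {c: j for j, c in enumerate(columns)}
    for i, g in enumerate(genotypes):
        for locus, alleles in g.alleles.items():
            for a in alleles:
                X[i, col[(locus, a)]] += 1.0 / g.ploidy
    frame = pd.DataFrame(X, index=names,
                         columns=[f"{loc}.{a}" for loc, a in columns])
    return frame, names


class _RidgeLDA:
    """Gaussian LDA with pooled within-class covariance and a ridge term."""

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RidgeLDA":
        self.classes_ = np.unique(y)
        n, p = X.shape
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        S = np.zeros((p, p))
        for c, mu in zip(self.classes_, self.means_):
            R = X[y == c] - mu
            S += R.T @ R
        S /= max(n - len(self.classes_), 1)
        S += self.ridge * np.eye(p)
        self.precision_ = np.linalg.inv(S)
        return self

    def _log_posterior(self, X: np.ndarray) -> np.ndarray:
        logp = np.empty((X.shape[0], len(self.classes_)))
        for j, (mu, pr) in enumerate(zip(self.means_, self.priors_)):
            d = X - mu
            logp[:, j] = -0.5 * np.einsum("ij,jk,ik->i", d, self.precision_, d) + np.log(pr)
        return logp

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logp = self._log_posterior(X)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]

    def transform(self, X: np.ndarray) -> np.ndarray:
        # discriminant axes: eigenvectors of W^-1 B
        B = np.zeros_like(self.precision_)
        grand = (self.priors_[:, None] * self.means_).sum(axis=0)
        for mu, pr in zip(self.means_, self.priors_):
            d = (mu - grand)[:, None]
            B += pr * (d @ d.T)
        vals, vecs = np.linalg.eig(self.precision_ @ B)
        order = np.argsort(-vals.real)
        k = max(len(self.classes_) - 1, 1)
        self.axes_ = vecs[:, order[:k]].real
        return X @ self.axes_


def dapc(
    genotypes: list[Genotype], k_max: int = 20, n_pc: int | None = None,
    n_starts: int = 200, seed: int = 0,
) -> DAPCResult:
    """K-means over PCA-transformed allele frequencies with BIC selection.

    All principal components feed the K-means step (K = 1..k_max,
    best-of-``n_starts`` restarts by within-cluster sum of squares);
    BIC(K) = n ln(WSS_K / n) + K ln(n) is minimized over K. A ridge-
    regularized LDA on the retained PCs then yields discriminant axes and
    posterior memberships.
    """
    if len(genotypes) < 2:
        raise InputError("dapc needs >= 2 cultivars")
    X, names = encode_genotypes(genotypes)
    Xc = X.values - X.values.mean(axis=0)
    n = Xc.shape[0]
    if k_max >= n:
        logger.warning("dapc: k_max %d >= n %d; capped at n - 1", k_max, n)
        k_max = n - 1
    pca = PCA(n_components=min(n - 1, Xc.shape[1]), svd_solver="full")
    pcs = pca.fit_transform(Xc)
    bic = {}
    labels_by_k = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(np.sum(pcs ** 2))
            labels_by_k[1] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
            lab = km.fit_predict(pcs)
            wss = float(km.inertia_)
            labels_by_k[k] = lab
        bic[k] = n * np.log(max(wss, 1e-12) / n) + k * np.log(n)
    k_sel = min(bic, key=lambda k: (bic[k], k))
    labels = labels_by_k[k_sel]
    if n_pc is None:
        n_pc = int(min(n - 1, pcs.shape[1], max(2, n // 3)))
    n_pc = int(min(n_pc, pcs.shape[1]))
    Xr = pcs[:, :n_pc]
    if k_sel == 1:
        posteriors = np.ones((n, 1))
        scores = Xr[:, :1]
    else:
        lda = _RidgeLDA().fit(Xr, labels)
        posteriors = lda.predict_proba(Xr)
        labels = lda.predict(Xr)
        scores = lda.transform(Xr)
    return DAPCResult(bic=bic, k=k_sel, n_pc=n_pc, labels=labels + 1,
                      posteriors=posteriors, scores=scores, cultivars=names)


def select_n_pcs(
    genotypes: list[Genotype], labels: np.ndarray,
    candidates: list[int] | None = None, folds: int = 5, seed: int = 0,
) -> int:
    """Cross-validated PC-count choice for the discriminant step.

    Stratified assignment accuracy on held-out folds per candidate count;
    returns the count with the best mean accuracy, ties going to the
    fewest PCs (parsimony).
    """
    X, _ = encode_genotypes(genotypes)
    Xc = X.values - X.values.mean(axis=0)
    n = Xc.shape[0]
    if folds > n:
        raise InputError(f"folds {folds} > n {n}")
    if len(np.unique(labels)) < 2:
        raise InputError("select_n_pcs needs >= 2 pre-assigned clusters")
    pcs = PCA(n_components=min(n - 1, Xc.shape[1]), svd_solver="full").fit_transform(Xc)
    if candidates is None:
        candidates = sorted({2, 4, 8, min(16, pcs.shape[1]), pcs.shape[1]})
    candidates = [c for c in candidates if 1 <= c <= pcs.shape[1]]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    best = None
    for c in sorted(candidates):
        accs = []
        for f in range(folds):
            train, test = fold_of != f, fold_of == f
            if len(np.unique(labels[train])) < 2 or test.sum() == 0:
                continue
            lda = _RidgeLDA().fit(pcs[train][:, :c], labels[train])
            accs.append(float(np.mean(lda.predict(pcs[test][:, :c]) == labels[test])))
        acc = float(np.mean(accs)) if accs else 0.0
        if best is None or acc > best[0] + 1e-12:
            best = (acc, c)
    return best[1]
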