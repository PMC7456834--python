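"""PCA, Ward clustering, cluster-count selection and partition association."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from berryroad.errors import InputError
from berryroad.multivariate import (
    KSelection, choose_k, cluster_association, linkage_to_newick, pca,
    prepare_matrix, ward_cluster,
)


def blobs(rng, centers, n_per=10, sd=1.0, p=4):
    rows, labels = [], []
    for i, c in enumerate(centers):
        rows.append(rng.normal(c, sd, size=(n_per, p)))
        labels += [i] * n_per
    X = np.vstack(rows)
    idx = [f"cv{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx), pd.Series(labels, index=idx)


def test_rank_one_matrix_concentrates_variance(rng):
    u = rng.normal(size=12)
    v = np.array([1.0, 2.0, -1.0, 0.5])
    X = pd.DataFrame(np.outer(u, v) + 5.0)
    res = pca(X, scale=True)
    assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)


def test_loadings_orthonormal_and_fractions_sum_to_one(rng):
    X = pd.DataFrame(rng.normal(size=(20, 5)))
    res = pca(X)
    L = res.loadings.values
    assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
    assert res.variance_fractions.sum() == pytest.approx(1.0)
    assert np.all(np.diff(res.variance_fractions) <= 1e-12)


def test_pca_sign_convention_deterministic(rng):
    X = pd.DataFrame(rng.normal(size=(15, 4)))
    r1, r2 = pca(X), pca(X)
    assert np.array_equal(r1.loadings.values, r2.loadings.values)
    for k in range(r1.loadings.shape[1]):
        col = r1.loadings.values[:, k]
        assert col[np.argmax(np.abs(col))] > 0


def test_planted_two_factor_variance_split(rng):
    n = 400
    f1 = rng.normal(0, 3.0, n)
    f2 = rng.normal(0, 1.0, n)
    X = np.column_stack([f1, f1, f2, f2]) / np.sqrt(2)
    X += rng.normal(0, 0.01, X.shape)
    res = pca(pd.DataFrame(X), scale=False)
    assert res.variance_fractions[0] == pytest.approx(0.9, abs=0.02)
    assert res.variance_fractions[1] == pytest.approx(0.1, abs=0.02)


def test_zero_variance_column_dropped(rng):
    X = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10),
                      "c": rng.normal(size=10)})
    out = prepare_matrix(X)
    assert list(out.columns) == ["a", "c"]


def test_ward_two_rows_singletons():
    X = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["a", "b"])
    res = ward_cluster(X, k=2, standardize=False)
    assert sorted(res.labels.values) == [1, 2]


def test_ward_duplicated_rows_merge_at_zero(rng):
    X = pd.DataFrame(rng.normal(size=(5, 3)))
    X.iloc[1] = X.iloc[0]
    res = ward_cluster(X, standardize=False)
    assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_ward_merge_heights_monotone(rng):
    X = pd.DataFrame(rng.normal(size=(25, 4)))
    res = ward_cluster(X)
    assert np.all(np.diff(res.linkage_matrix[:, 2]) >= -1e-12)


def test_ward_recovers_separated_clusters(rng):
    centers = np.eye(4) * 30.0
    X, truth = blobs(rng, centers, n_per=8, sd=1.0)
    res = ward_cluster(X, k=4)
    assert adjusted_rand_score(truth.values, res.labels.values) == 1.0


def test_choose_k_finds_planted_four(rng):
    centers = np.eye(4) * 30.0
    X, _ = blobs(rng, centers, n_per=8, sd=1.0)
    sel = choose_k(ward_cluster(X))
    assert sel.k == 4 and sel.confident


def test_choose_k_two_distant_blobs(rng):
    X, _ = blobs(rng, [np.zeros(4), np.full(4, 100.0)], n_per=10, sd=0.5)
    sel = choose_k(ward_cluster(X))
    assert sel.k == 2 and sel.confident


def test_choose_k_flat_structure_defaults_low_confidence(rng):
    X = pd.DataFrame(rng.normal(size=(40, 4)))
    sel = choose_k(ward_cluster(X))
    assert sel.k == 2 and not sel.confident


def test_k_larger_than_n_rejected(rng):
    X = pd.DataFrame(rng.normal(size=(5, 3)))
    with pytest.raises(InputError):
        ward_cluster(X, k=9)


def test_association_identical_labelings():
    # unbalanced blocks: a random permutation essentially never reproduces
    # the partition, so only the observed statistic reaches ARI = 1
    lab = pd.Series([1] * 8 + [2] * 7 + [3] * 5,
                    index=[f"c{i}" for i in range(20)])
    ari, p = cluster_association(lab, lab, n_perm=999, seed=0)
    assert ari == 1.0
    assert p == pytest.approx(1 / 1000)


def test_association_constant_labeling_zero_ari():
    a = pd.Series([1, 2, 1, 2, 1, 2], index=list("abcdef"))
    b = pd.Series([1] * 6, index=list("abcdef"))
    ari, _ = cluster_association(a, b, n_perm=99, seed=0)
    assert ari == 0.0


def test_association_mismatched_sets_rejected():
    a = pd.Series([1, 2], index=["a", "b"])
    b = pd.Series([1, 2], index=["a", "c"])
    with pytest.raises(InputError):
        cluster_association(a, b)


def test_association_null_p_not_small(rng):
    # independent labelings: p should rarely be extreme
    idx = [f"c{i}" for i in range(44)]
    ps = []
    for s in range(30):
        a = pd.Series(rng.integers(1, 5, 44), index=idx)
        b = pd.Series(rng.integers(1, 5, 44), index=idx)
        ps.append(cluster_association(a, b, n_perm=199, seed=s)[1])
    assert np.mean(np.array(ps) < 0.05) < 0.25
    assert np.mean(ps) > 0.25


def test_dendrogram_newick_roundtrip(rng):
    import dendropy

    X = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
    res = ward_cluster(X)
    nwk = linkage_to_newick(res)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert {t.label for t in tree.taxon_namespace} == set("abcdef")
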