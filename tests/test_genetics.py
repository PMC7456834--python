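"""SSR genetics: tail correction, Bruvo distance vs brute force, NJ,
bootstrap supports, DAPC and PC selection."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from berryroad.errors import InputError
from berryroad import genetics as G
from berryroad.synthetic import CohortConfig, GeneticConfig, simulate_cohort


# ---------------------------------------------------------------------------
# allele-size tail correction


@pytest.mark.parametrize("raw,tail,expected", [
    (220, "T7", 200),        # 20-nt tail
    (150, "M13", 132),       # 18-nt tail
    (150, "M13R", 132),
    (150, "D12S1090f", 132),
])
def test_tail_correction(raw, tail, expected):
    assert G.adjust_allele_sizes(raw, tail) == expected


def test_unknown_tail_rejected():
    with pytest.raises(InputError, match="tail"):
        G.adjust_allele_sizes([150], "X")


# ---------------------------------------------------------------------------
# Bruvo distance


def brute_force_bruvo(a, b, ploidy_a, ploidy_b):
    """Independent oracle: enumerate every pad and every permutation."""
    n = max(ploidy_a, ploidy_b)

    def pads(alleles, target):
        need = target - len(alleles)
        if need <= 0:
            return [tuple(alleles)]
        return [tuple(alleles) + extra for extra in
                itertools.combinations_with_replacement(sorted(set(alleles)), need)]

    best = np.inf
    for pa in {q for p in pads(a, ploidy_a) for q in pads(p, n)}:
        for pb in {q for p in pads(b, ploidy_b) for q in pads(p, n)}:
            for perm in itertools.permutations(pb):
                d = np.mean([1.0 - 2.0 ** (-abs(x - y)) for x, y in zip(pa, perm)])
                best = min(best, d)
    return best


def test_bruvo_identity_zero():
    assert G.bruvo_locus_distance((20, 23, 25, 25), (20, 23, 25, 25), 4, 4) == 0.0


def test_bruvo_diploid_style_example():
    # {20,23} vs {20,24}: matchings give (0 + 1/2)/2 = 0.25 or
    # ((1-2^-4)+(1-2^-3))/2 ~ 0.906; the minimum is 0.25
    assert G.bruvo_locus_distance((20, 23), (20, 24), 2, 2) == pytest.approx(0.25)


def test_bruvo_saturates_at_large_offsets():
    d = G.bruvo_locus_distance((0, 0), (25, 25), 2, 2)
    assert d >= 1.0 - 2.0 ** -20


def test_bruvo_matches_brute_force_oracle(rng):
    for _ in range(60):
        pa, pb = rng.choice([2, 3, 4], size=2)
        a = tuple(int(x) for x in rng.integers(10, 30, size=rng.integers(1, pa + 1)))
        b = tuple(int(x) for x in rng.integers(10, 30, size=rng.integers(1, pb + 1)))
        got = G.bruvo_locus_distance(a, b, int(pa), int(pb))
        want = brute_force_bruvo(a, b, int(pa), int(pb))
        assert got == pytest.approx(want, abs=1e-12), (a, b, pa, pb)


def test_bruvo_matrix_properties(small_cohort):
    cfg, _, _, _, geno = small_cohort
    gts = G.genotypes_from_frame(geno)
    dist = G.bruvo_distance_matrix(gts, dict(cfg.genetic.loci))
    M = dist.values
    assert np.allclose(M, M.T)
    assert np.allclose(np.diag(M), 0.0)
    assert M.min() >= 0.0 and M.max() <= 1.0


def test_bruvo_no_shared_loci_missing():
    a = {"L1": (10, 11)}
    b = {"L2": (10, 11)}
    assert np.isnan(G.bruvo_distance(a, b, 4, 4))


def test_repeat_unit_conversion_offsets():
    gts = [G.Genotype("a", 4, {"L1": (150, 154)}),
           G.Genotype("b", 4, {"L1": (152, 158)})]
    units = G.to_repeat_units(gts, {"L1": 2})
    assert units["a"]["L1"] == (0, 2)
    assert units["b"]["L1"] == (1, 4)


# ---------------------------------------------------------------------------
# neighbour joining


def tree_distance_matrix(newick, taxa):
    tns = dendropy.TaxonNamespace(taxa)
    t = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    pdm = t.phylogenetic_distance_matrix()
    n = len(taxa)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            M[i, j] = pdm.patristic_distance(tns[i], tns[j])
    return pd.DataFrame(M, index=taxa, columns=taxa)


def test_nj_recovers_four_taxon_tree():
    taxa = ["A", "B", "C", "D"]
    dist = tree_distance_matrix("((A:1,B:2):1,(C:3,D:1):0);", taxa)
    tree = G.nj_tree(dist)
    # topology: RF distance 0 to the generating tree
    truth = dendropy.Tree.get(data="((A:1,B:2):1,(C:3,D:1):0);", schema="newick")
    assert G.robinson_foulds(tree, truth) == 0
    # additivity: patristic distances reproduced exactly
    rec = tree_distance_matrix(tree.as_string(schema="newick"), taxa)
    assert np.allclose(rec.values, dist.values, atol=1e-9)


def test_nj_two_taxa_single_edge():
    dist = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]], index=["A", "B"], columns=["A", "B"])
    tree = G.nj_tree(dist)
    assert sum(e.length or 0.0 for e in tree.edges()) == pytest.approx(0.7)


def test_nj_incomplete_matrix_rejected():
    dist = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=["A", "B"], columns=["A", "B"])
    with pytest.raises(InputError):
        G.nj_tree(dist)


def random_additive_case(rng, n_taxa=8):
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
        num_extant_tips=n_taxa, rng=__import__("random").Random(int(rng.integers(1 << 30))))
    for e in tree.edges():
        if e.length is not None:
            e.length = float(rng.uniform(0.1, 2.0))
    return tree, tree_distance_matrix(tree.as_string(schema="newick"), taxa)


def test_nj_recovers_random_additive_trees(rng):
    for _ in range(10):
        truth, dist = random_additive_case(rng)
        assert G.robinson_foulds(G.nj_tree(dist), truth) == 0


# ---------------------------------------------------------------------------
# bootstrap


def two_population_genotypes(rng, n_per=8, sep=12):
    gts = []
    for pop in range(2):
        for i in range(n_per):
            alleles = {}
            for locus in ("L1", "L2", "L3", "L4"):
                base = 100 + sep * pop * 2
                alleles[locus] = tuple(int(base + 2 * rng.integers(0, 3)) for _ in range(4))
            gts.append(G.Genotype(f"p{pop}i{i}", 4, alleles))
    return gts


def test_bootstrap_supports_separating_edge(rng):
    gts = two_population_genotypes(rng)
    rep = {loc: 2 for loc in ("L1", "L2", "L3", "L4")}
    tree = G.bootstrap_nj(gts, rep, n_boot=50, seed=3)
    labels = [int(n.label) for n in tree.preorder_node_iter()
              if n.label is not None and not n.is_leaf()]
    assert labels and max(labels) == 100  # the population split is always there


def test_bootstrap_deterministic_given_seed(rng):
    gts = two_population_genotypes(rng)
    rep = {loc: 2 for loc in ("L1", "L2", "L3", "L4")}
    t1 = G.bootstrap_nj(gts, rep, n_boot=25, seed=9)
    t2 = G.bootstrap_nj(gts, rep, n_boot=25, seed=9)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


def test_bootstrap_zero_returns_unlabelled_tree(rng):
    gts = two_population_genotypes(rng)
    rep = {loc: 2 for loc in ("L1", "L2", "L3", "L4")}
    tree = G.bootstrap_nj(gts, rep, n_boot=0, seed=0)
    assert all(n.label is None for n in tree.preorder_node_iter() if not n.is_leaf())


def test_bootstrap_single_locus_rejected(rng):
    gts = [G.Genotype("a", 4, {"L1": (10, 12, 12, 14)}),
           G.Genotype("b", 4, {"L1": (20, 22, 22, 24)}),
           G.Genotype("c", 4, {"L1": (30, 32, 32, 34)})]
    with pytest.raises(InputError):
        G.bootstrap_nj(gts, {"L1": 2}, n_boot=10, seed=0)


# ---------------------------------------------------------------------------
# DAPC


def cohort_genotypes(k_true, seed, n=45):
    cfg = CohortConfig(n_cultivars=n, n_fruit_per_cultivar=1, n_voc_replicates=1,
                       n_extra_signal_peaks=0, n_isotope_peaks=0, n_noise_peaks=0,
                       genetic=GeneticConfig(n_populations=k_true), seed=seed)
    truth, _, _, geno = simulate_cohort(cfg)
    return truth, G.genotypes_from_frame(geno)


def test_dapc_posteriors_normalized_and_k_selected():
    truth, gts = cohort_genotypes(3, seed=1)
    res = G.dapc(gts, k_max=6, n_starts=30, seed=1)
    assert res.k == 3
    assert np.allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-9)
    assert res.labels.min() >= 1 and res.labels.max() <= res.k


def test_dapc_kmax_capped():
    truth, gts = cohort_genotypes(2, seed=2, n=8)
    res = G.dapc(gts, k_max=50, n_starts=10, seed=2)
    assert max(res.bic) <= 7


def test_dapc_deterministic_given_seed():
    _, gts = cohort_genotypes(3, seed=4, n=24)
    r1 = G.dapc(gts, k_max=5, n_starts=20, seed=7)
    r2 = G.dapc(gts, k_max=5, n_starts=20, seed=7)
    assert r1.k == r2.k and np.array_equal(r1.labels, r2.labels)
    assert r1.bic == r2.bic


def test_select_n_pcs_parsimonious_on_separable_data():
    truth, gts = cohort_genotypes(3, seed=5)
    labels = np.array([truth.population[g.cultivar] for g in gts])
    n_pc = G.select_n_pcs(gts, labels, candidates=[2, 5, 10, 20], folds=5, seed=0)
    assert n_pc == 2  # accuracy 1.0 everywhere; smallest wins
    assert G.select_n_pcs(gts, labels, candidates=[2, 5, 10, 20], folds=5, seed=0) == n_pc


def test_select_n_pcs_needs_two_clusters():
    _, gts = cohort_genotypes(2, seed=6, n=10)
    with pytest.raises(InputError):
        G.select_n_pcs(gts, np.zeros(10, dtype=int))


def test_encode_genotypes_frequencies_sum_per_locus(small_cohort):
    _, _, _, _, geno = small_cohort
    gts = G.genotypes_from_frame(geno)
    X, names = G.encode_genotypes(gts)
    for locus in {l for g in gts for l in g.alleles}:
        cols = [c for c in X.columns if c.startswith(f"{locus}.")]
        assert np.allclose(X[cols].sum(axis=1), 1.0)
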