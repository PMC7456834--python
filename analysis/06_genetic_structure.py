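"""Genetic structure of the panel: Bruvo distances, bootstrapped NJ tree
and DAPC clustering, then the phenotype-vs-genotype association test.

Expected outcome at the study's scale: DAPC recovers the planted
populations (hexaploid group well separated), while phenotypic clusters
show no significant association with the genetic groups.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from berryroad import genetics as G
from berryroad.multivariate import choose_k, cluster_association, prepare_matrix, ward_cluster

from common import COHORT_SEED, RESULTS, get_cohort, get_texture_matrices


def main():
    cfg, truth, _, _, geno = get_cohort()
    gts = G.genotypes_from_frame(geno)
    rep = dict(cfg.genetic.loci)
    dist = G.bruvo_distance_matrix(gts, rep)
    dist.to_csv(RESULTS / "bruvo_distances.tsv", sep="\t")
    tree = G.bootstrap_nj(gts, rep, n_boot=200, seed=COHORT_SEED)
    (RESULTS / "nj_tree.nwk").write_text(tree.as_string(schema="newick"))
    res = G.dapc(gts, k_max=20, n_starts=200, seed=COHORT_SEED)
    lab_true = [truth.population[c] for c in res.cultivars]
    print(f"DAPC: BIC selects K={res.k} (planted {cfg.genetic.n_populations}); "
          f"ARI vs planted populations {adjusted_rand_score(lab_true, res.labels):.2f}")
    pd.DataFrame({"cultivar": res.cultivars, "cluster": res.labels}).to_csv(
        RESULTS / "dapc_clusters.tsv", sep="\t", index=False)

    _, tex = get_texture_matrices()
    cl = ward_cluster(prepare_matrix(tex["harvest"]), standardize=False)
    pheno = cl.cut(choose_k(cl).k)
    genetic = pd.Series(res.labels, index=res.cultivars)
    ari, p = cluster_association(pheno, genetic, n_perm=999, seed=COHORT_SEED)
    verdict = "no significant" if p > 0.05 else "a significant"
    print(f"texture clusters vs genetic clusters: ARI {ari:+.3f}, "
          f"permutation p = {p:.3f} -> {verdict} association")


if __name__ == "__main__":
    main()
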