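"""PCA and Ward clustering of the texture and volatile trait matrices
(harvest, postharvest and SI views), with data-driven cluster counts.

Reports the variance captured by the leading components and how well the
phenotypic clusters recover the planted texture archetypes.
"""

from berryroad.multivariate import choose_k, pca, prepare_matrix, ward_cluster
from sklearn.metrics import adjusted_rand_score

from berryroad.storage import si_matrix

from common import RESULTS, get_cohort, get_texture_matrices, get_voc_matrices


def main():
    _, truth, _, _, _ = get_cohort()
    _, tex = get_texture_matrices()
    _, _, voc = get_voc_matrices()
    views = {
        "texture_harvest": (tex["harvest"], False),
        "texture_postharvest": (tex["postharvest"], False),
        "texture_si": (si_matrix(tex["harvest"], tex["postharvest"]), False),
        "voc_harvest": (voc["harvest"], True),
        "voc_postharvest": (voc["postharvest"], True),
    }
    for name, (mat, log10) in views.items():
        X = prepare_matrix(mat, log10=log10)
        pc = pca(X, scale=False)
        cl = ward_cluster(X, standardize=False)
        sel = choose_k(cl)
        labels = cl.cut(sel.k)
        labels.rename("cluster").to_csv(RESULTS / f"clusters_{name}.tsv", sep="\t")
        line = (f"{name:<22} PC1 {pc.variance_fractions[0]:5.1%} "
                f"PC2 {pc.variance_fractions[1]:5.1%}  K={sel.k}"
                f"{'' if sel.confident else ' (low confidence)'}")
        if name.startswith("texture"):
            ari = adjusted_rand_score([truth.archetype[c] for c in labels.index],
                                      labels.values)
            line += f"  ARI vs planted archetypes {ari:.2f}"
        print(line)


if __name__ == "__main__":
    main()
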