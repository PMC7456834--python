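"""Generate the synthetic study cohort and summarize its design.

46 cultivars x 2 timepoints (harvest, 6 weeks cold storage), 20 fruit per
cultivar for texture, triplicate headspace runs plus 6 blanks for
volatiles, and 6 SSR loci over 4 planted populations (one hexaploid).
Writes the genotype table and ground-truth labels; raw curves and the
peak table are regenerated by later steps rather than stored.
"""

import collections
import json

from common import RESULTS, get_cohort


def main():
    cfg, truth, curves, peaks, genotypes = get_cohort()
    print(f"cohort: {cfg.n_cultivars} cultivars, {len(curves)} mechanograms, "
          f"{len(peaks.mz)} m/z channels ({peaks.n_blanks} blanks), "
          f"{genotypes['locus'].nunique()} SSR loci")
    print("archetypes:", dict(collections.Counter(truth.archetype.values())))
    print("VOC over-expression:", dict(collections.Counter(truth.voc_membership.values())))
    print("populations:", dict(collections.Counter(truth.population.values())))
    genotypes.to_csv(RESULTS / "genotypes.tsv", sep="\t", index=False)
    truth.to_json(RESULTS / "truth.json")
    design = {"seed": cfg.seed, "n_cultivars": cfg.n_cultivars,
              "n_fruit": cfg.n_fruit_per_cultivar,
              "n_voc_replicates": cfg.n_voc_replicates,
              "n_mz": len(peaks.mz)}
    (RESULTS / "design.json").write_text(json.dumps(design, indent=1))
    print(f"wrote genotypes, truth and design under {RESULTS}")


if __name__ == "__main__":
    main()
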