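"""Storage indices (log2 post/harvest) for texture and volatile traits.

Positive SI = trait enhanced by storage. Fermentation volatiles (ethanol,
acetaldehyde) and esters rise sharply; terpenes and C6 aldehydes fall —
the planted trajectories the pipeline must recover.
"""

from berryroad.storage import si_matrix, si_summary

from common import RESULTS, get_texture_matrices, get_voc_matrices


def main():
    _, tex = get_texture_matrices()
    _, _, voc = get_voc_matrices()
    si_tex = si_matrix(tex["harvest"], tex["postharvest"])
    si_voc = si_matrix(voc["harvest"], voc["postharvest"])
    si_tex.to_csv(RESULTS / "si_texture.tsv", sep="\t")
    si_voc.to_csv(RESULTS / "si_voc.tsv", sep="\t")
    print("texture SI summary:")
    print(si_summary(si_tex).round(2).to_string())
    marker = {47.043: "ethanol", 45.031: "acetaldehyde", 33.033: "methanol",
              137.134: "monoterpenes", 99.08: "hexenal isomers"}
    print("\nmarker volatile SI (cohort mean):")
    for mz, name in marker.items():
        if mz in si_voc.columns:
            print(f"  m/z {mz:<8} {name:<15} {si_voc[mz].mean():+.2f}")


if __name__ == "__main__":
    main()
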