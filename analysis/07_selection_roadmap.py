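"""Quantile-binned parental-selection roadmap over the curated trait set
(three texture parameters + six marker volatiles), harvest and
postharvest separately.

Prints, per trait, the cultivars in the top bin at both timepoints —
the direct shortlist a breeder would start from.
"""

import pandas as pd

from berryroad.roadmap import build_roadmap

from common import RESULTS, get_texture_matrices, get_voc_matrices


def main():
    _, tex = get_texture_matrices()
    _, _, voc = get_voc_matrices()
    h = pd.concat([tex["harvest"], voc["harvest"]], axis=1)
    p = pd.concat([tex["postharvest"], voc["postharvest"]], axis=1)
    rm = build_roadmap(h, p)
    rm.table.to_csv(RESULTS / "roadmap.tsv", sep="\t", index=False)
    t = rm.table.set_index(["trait", "timepoint", "cultivar"])["bin"]
    print(f"roadmap: {rm.table['trait'].nunique()} traits x "
          f"{rm.table['cultivar'].nunique()} cultivars")
    for trait in rm.table["trait"].unique():
        hh = {c for c in t[trait]["harvest"].index
              if t[(trait, "harvest", c)] == "high"
              and t[(trait, "postharvest", c)] == "high"}
        print(f"  {trait:<12} stable-high cultivars: {', '.join(sorted(hh)) or '(none)'}")


if __name__ == "__main__":
    main()
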