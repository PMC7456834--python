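"""Reduce the raw volatile peak table by the blank (noise) and
correlation (isotope) filters and annotate the survivors.

Also scores the filters against the generator's ground truth: planted
isotopologues and blank-like channels should be removed, planted signal
peaks retained.
"""

from berryroad.voc import annotate

from common import RESULTS, get_cohort, get_voc_matrices


def main():
    _, truth, _, peaks, _ = get_cohort()
    reduced, report, _ = get_voc_matrices()
    print(f"peak reduction: {len(peaks.mz)} -> {len(report.retained)} "
          f"({len(report.removed_noise)} blank-like, "
          f"{len(report.removed_correlated)} correlated/isotopic)")
    retained = set(report.retained)
    iso = set(truth.isotopes)
    noise = set(truth.noise_mz)
    signal = set(truth.voc_class_of_mz)
    print(f"vs truth: isotopes removed {len(iso - retained)}/{len(iso)}, "
          f"noise channels removed {len(noise - retained)}/{len(noise)}, "
          f"signal peaks kept {len(signal & retained)}/{len(signal)}")
    ann = annotate(report.retained)
    ann.to_csv(RESULTS / "peak_annotations.tsv", sep="\t", index=False)
    named = ann[ann["identification"] != "unknown"]
    print(f"annotated {len(named)}/{len(ann)} retained peaks; examples:")
    print(named.head(8).to_string(index=False))


if __name__ == "__main__":
    main()
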