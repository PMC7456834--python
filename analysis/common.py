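"""Shared cohort for the numbered analysis scripts.

Every script regenerates the same default 46-cultivar cohort in memory
from one fixed seed (a few seconds) instead of passing half-gigabyte
curve files between steps; outputs land under results/analysis/.
"""

from functools import lru_cache
from pathlib import Path

COHORT_SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


@lru_cache(maxsize=1)
def get_cohort():
    from berryroad.synthetic import CohortConfig, simulate_cohort

    cfg = CohortConfig(seed=COHORT_SEED)
    truth, curves, peaks, genotypes = simulate_cohort(cfg)
    RESULTS.mkdir(parents=True, exist_ok=True)
    return cfg, truth, curves, peaks, genotypes


@lru_cache(maxsize=1)
def get_texture_matrices():
    from berryroad.pipeline import texture_cultivar_matrices, texture_stage

    _, _, curves, _, _ = get_cohort()
    profiles = texture_stage(curves)
    return profiles, texture_cultivar_matrices(profiles)


@lru_cache(maxsize=1)
def get_voc_matrices():
    from berryroad.pipeline import voc_cultivar_means
    from berryroad.voc import reduce_peaks

    _, _, _, peaks, _ = get_cohort()
    reduced, report = reduce_peaks(peaks)
    return reduced, report, voc_cultivar_means(reduced)
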