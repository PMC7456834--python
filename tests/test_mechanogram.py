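"""Texture-parameter extraction: closed-form cases, exact round trips,
noise robustness and cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from berryroad.errors import DegenerateCurveError, InputError
from berryroad.mechanogram import (
    PROBE_AREA_MM2, MechCurve, cultivar_means, extract_texture_profile,
    profiles_frame, summarize_texture,
)
from berryroad.synthetic import (
    CohortConfig, TextureArchetype, default_archetypes, simulate_cohort,
    simulate_mechanogram,
)

TRAITS = ("gradient", "max_force", "max_force_strain", "min_force",
          "min_force_strain", "area", "final_force")


def _dense_curve(knots_s, knots_f, n=200, **kw):
    s = np.unique(np.concatenate([np.linspace(0, knots_s[-1], n), knots_s]))
    return MechCurve(strain=s, force=np.interp(s, knots_s, knots_f), **kw)


def test_closed_form_piecewise_linear_example():
    # vertices (0,0) -> (50,5) -> (70,1) -> (90,2); trapezoid areas
    # 0.5*5*50 + 0.5*(5+1)*20 + 0.5*(1+2)*20 = 125 + 60 + 30 = 215 N·%
    curve = _dense_curve(np.array([0.0, 50.0, 70.0, 90.0]),
                         np.array([0.0, 5.0, 1.0, 2.0]))
    p = extract_texture_profile(curve)
    assert p.max_force == 5.0 and p.max_force_strain == 50.0
    assert p.min_force == 1.0 and p.min_force_strain == 70.0
    assert p.final_force == 2.0
    assert p.area == pytest.approx(215.0, rel=1e-12)
    assert p.gradient == pytest.approx(5.0 / 50.0, rel=1e-9)


def test_flat_zero_curve_is_degenerate():
    s = np.linspace(0, 90, 50)
    with pytest.raises(DegenerateCurveError):
        extract_texture_profile(MechCurve(strain=s, force=np.zeros_like(s)))


def test_peak_at_last_sample_is_degenerate():
    s = np.linspace(0, 90, 50)
    with pytest.raises(DegenerateCurveError):
        extract_texture_profile(MechCurve(strain=s, force=s / 10.0))


def test_non_monotone_strain_rejected():
    s = np.linspace(0, 90, 50)
    s[10] = s[9]
    f = np.interp(s, [0, 45, 60, 90], [0, 4, 1, 2])
    with pytest.raises(InputError):
        extract_texture_profile(MechCurve(strain=s, force=f))


def test_tie_breaking_first_index():
    s = np.linspace(0, 90, 91)
    f = np.zeros_like(s)
    f[30], f[40] = 5.0, 5.0  # two equal maxima
    f[50], f[60] = 0.0, 0.0
    f[-1] = 1.0
    p = extract_texture_profile(MechCurve(strain=s, force=f))
    assert p.max_force_strain == s[30]
    assert p.min_force_strain == s[31]  # first post-peak minimum index


def test_mpa_mode_is_area_scaled_raw_slope():
    curve = _dense_curve(np.array([0.0, 4.0, 6.0, 90.0]),
                         np.array([0.0, 4.0, 1.0, 1.5]))
    raw = extract_texture_profile(curve, gradient_mode="raw")
    mpa = extract_texture_profile(curve, gradient_mode="mpa")
    assert mpa.gradient == pytest.approx(raw.gradient * 100.0 / PROBE_AREA_MM2)
    for t in TRAITS[1:]:
        assert getattr(mpa, t) == getattr(raw, t)


def test_scale_equivariance_in_force(rng):
    arch = default_archetypes()[0]
    curve = simulate_mechanogram(arch.params, rng, noise_sigma_frac=0.0)
    scaled = MechCurve(strain=curve.strain, force=3.0 * curve.force)
    p1, p3 = extract_texture_profile(curve), extract_texture_profile(scaled)
    for t in ("gradient", "max_force", "min_force", "final_force", "area"):
        assert getattr(p3, t) == pytest.approx(3.0 * getattr(p1, t), rel=1e-12)
    assert p3.max_force_strain == p1.max_force_strain
    assert p3.min_force_strain == p1.min_force_strain


def test_noise_free_cohort_round_trip_is_exact():
    cfg = CohortConfig(n_cultivars=3, n_fruit_per_cultivar=2, noise_free=True, seed=7)
    truth, curves, _, _ = simulate_cohort(cfg)
    planted = truth.mech_params.set_index("fruit")
    for curve in curves:
        p = extract_texture_profile(curve)
        row = planted.loc[curve.fruit]
        for t in TRAITS:
            assert getattr(p, t) == pytest.approx(row[t], rel=1e-9, abs=1e-12), t


def test_storage_shift_signs_on_planted_parameters():
    cfg = CohortConfig(n_cultivars=4, n_fruit_per_cultivar=1, noise_free=True, seed=0)
    truth, _, _, _ = simulate_cohort(cfg)
    m = truth.mech_params.groupby("timepoint")[["gradient", "max_force_strain"]].mean()
    assert m.loc["postharvest", "gradient"] < m.loc["harvest", "gradient"]
    assert m.loc["postharvest", "max_force_strain"] > m.loc["harvest", "max_force_strain"]


def test_strain_spacing_matches_acquisition_settings(rng):
    # 100 mm/min at 500 points/s on a 15 mm berry: (100/60/500)/15*100 %/point
    arch = default_archetypes()[1]
    curve = simulate_mechanogram(arch.params, rng, berry_diameter_mm=15.0,
                                 test_speed_mm_min=100.0, acquisition_rate=500.0)
    steps = np.diff(curve.strain)
    expected = (100.0 / 60.0 / 500.0) / 15.0 * 100.0
    assert np.median(steps) == pytest.approx(expected, rel=1e-9)


def test_noisy_recovery_of_max_force(rng):
    arch = default_archetypes()[0]
    errs = []
    for _ in range(200):
        curve = simulate_mechanogram(arch.params, rng, noise_sigma_frac=0.01)
        p = extract_texture_profile(curve)
        errs.append(abs(p.max_force - arch.params["max_force"]) / arch.params["max_force"])
    assert np.median(errs) < 0.02


def test_summarize_texture_identical_timepoints_gives_zero_si():
    rows = []
    for tp in ("harvest", "postharvest"):
        for k in range(3):
            rows.append({"cultivar": "a", "timepoint": tp, "fruit": f"{tp}{k}",
                         "gradient": 1.0, "max_force": 4.0, "max_force_strain": 3.0,
                         "min_force": 1.0, "min_force_strain": 5.0, "area": 100.0,
                         "final_force": 1.5})
    summ = summarize_texture(pd.DataFrame(rows))
    assert np.allclose(summ["si_mean"], 0.0)


def test_summarize_texture_cohort_stats_over_cultivar_means():
    rows = []
    for cv, val in (("a", 1.0), ("b", 3.0)):
        for tp in ("harvest", "postharvest"):
            rows.append({"cultivar": cv, "timepoint": tp, "fruit": f"{cv}{tp}",
                         "max_force": val})
    summ = summarize_texture(pd.DataFrame(rows))
    assert summ.loc["max_force", "harvest_min"] == 1.0
    assert summ.loc["max_force", "harvest_max"] == 3.0
    assert summ.loc["max_force", "harvest_mean"] == 2.0


def test_planted_gradient_shift_recovered_in_cohort_summary():
    # shift log2(max_force) by -0.5 and log2(strain) by +0.5: gradient SI = -1
    arch = TextureArchetype(
        "shifted", {"max_force": 4.0, "max_force_strain": 3.5, "min_force": 1.0,
                    "min_force_strain": 6.0, "final_force": 1.5},
        storage_shift={"max_force": -0.5, "max_force_strain": 0.5})
    cfg = CohortConfig(n_cultivars=10, n_fruit_per_cultivar=10,
                       texture_archetypes=[arch], seed=11)
    _, curves, _, _ = simulate_cohort(cfg)
    profiles = profiles_frame([extract_texture_profile(c) for c in curves])
    summ = summarize_texture(profiles)
    assert summ.loc["gradient", "si_mean"] == pytest.approx(-1.0, abs=0.1)


def test_missing_timepoint_si_logged_not_fatal():
    rows = [{"cultivar": "a", "timepoint": tp, "fruit": f"a{tp}", "max_force": v}
            for tp, v in (("harvest", 2.0), ("postharvest", 4.0))]
    rows.append({"cultivar": "b", "timepoint": "harvest", "fruit": "bh", "max_force": 1.0})
    summ = summarize_texture(pd.DataFrame(rows))
    assert summ.loc["max_force", "si_mean"] == pytest.approx(1.0)  # only cultivar a


def test_cultivar_means_average_over_fruit():
    df = pd.DataFrame({
        "cultivar": ["a"] * 2, "timepoint": ["harvest"] * 2,
        "fruit": ["f1", "f2"], "max_force": [2.0, 4.0]})
    assert cultivar_means(df).loc[("a", "harvest"), "max_force"] == 3.0
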