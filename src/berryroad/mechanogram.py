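"""Texture-parameter extraction from fruit compression mechanograms.

A mechanogram is the force (N) versus deformation (strain, % of fruit
diameter) profile recorded while a cylindrical probe compresses a berry to
90% deformation. Seven parameters summarize each curve:

* ``max_force`` and ``max_force_strain`` — the global force peak (skin /
  flesh failure) and the strain where it occurs;
* ``min_force`` and ``min_force_strain`` — the post-peak force valley;
* ``final_force`` — force at the end of the compression;
* ``area`` — the integral of force over strain (mechanical work proxy, N·%);
* ``gradient`` — the slope of the initial quasi-linear loading region, an
  imitative Young's modulus used as a turgidity proxy.

The gradient fit window runs from the instrument force trigger (default
0.02 N, i.e. 2 g) up to a configurable fraction of the peak force (default
25%), restricted to the pre-peak ramp; on a piecewise-linear curve the
least-squares slope of that window equals the ramp slope exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateCurveError, InputError
from .storage import si_matrix

logger = logging.getLogger(__name__)

#: Flat-head probe diameter in mm; contact area converts force to stress.
PROBE_DIAMETER_MM = 4.0
PROBE_AREA_MM2 = math.pi * (PROBE_DIAMETER_MM / 2.0) ** 2  # 12.566 mm^2

#: Default instrument force trigger: 2 g under standard gravity, in newtons.
FORCE_TRIGGER_N = 0.02

TEXTURE_TRAITS = (
    "gradient",
    "max_force",
    "max_force_strain",
    "min_force",
    "min_force_strain",
    "area",
    "final_force",
)


@dataclass(frozen=True)
class MechCurve:
    """One fruit's compression profile."""

    strain: np.ndarray  # percent deformation, strictly increasing
    force: np.ndarray  # newtons
    cultivar: str = ""
    timepoint: str = ""
    fruit: str = ""
    acquisition_rate: float = 500.0  # points per second, nominal

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain", np.asarray(self.strain, dtype=float))
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))

    def validate(self) -> None:
        s, f = self.strain, self.force
        if s.shape != f.shape or s.ndim != 1:
            raise InputError(f"curve {self.fruit!r}: strain/force shape mismatch")
        if s.size < 10:
            raise InputError(f"curve {self.fruit!r}: needs >= 10 samples, got {s.size}")
        if not np.all(np.diff(s) > 0):
            raise InputError(f"curve {self.fruit!r}: strain must be strictly increasing")
        if np.any(f < 0):
            raise InputError(f"curve {self.fruit!r}: negative force values")
        if s[-1] > 100:
            raise InputError(f"curve {self.fruit!r}: strain exceeds 100%")


@dataclass(frozen=True)
class TextureProfile:
    """The seven extracted texture parameters for one curve."""

    gradient: float  # N/% or MPa depending on mode
    max_force: float
    max_force_strain: float
    min_force: float
    min_force_strain: float
    area: float
    final_force: float
    cultivar: str = ""
    timepoint: str = ""
    fruit: str = ""
    gradient_mode: str = "raw"

    def as_dict(self) -> dict:
        return {t: getattr(self, t) for t in TEXTURE_TRAITS}


def _gradient_slope(
    strain: np.ndarray, force: np.ndarray, i_max: int, trigger: float, window_frac: float
) -> float:
    """Least-squares slope of the initial quasi-linear loading region."""
    f_max = force[i_max]
    pre_s, pre_f = strain[: i_max + 1], force[: i_max + 1]
    mask = (pre_f >= trigger) & (pre_f <= window_frac * f_max)
    if mask.sum() < 2:
        # Very coarse curve: fall back to the whole pre-peak ramp above trigger.
        mask = pre_f >= min(trigger, f_max / 2.0)
    if mask.sum() < 2:
        mask = np.ones_like(pre_f, dtype=bool)
    x, y = pre_s[mask], pre_f[mask]
    xm, ym = x.mean(), y.mean()
    denom = float(np.sum((x - xm) ** 2))
    if denom == 0.0:
        raise DegenerateCurveError("gradient window has zero strain spread")
    return float(np.sum((x - xm) * (y - ym)) / denom)


def extract_texture_profile(
    curve: MechCurve,
    *,
    trigger: float = FORCE_TRIGGER_N,
    gradient_window_frac: float = 0.25,
    gradient_mode: str = "raw",
) -> TextureProfile:
    """Extract the seven texture parameters from one mechanogram.

    ``gradient_mode='raw'`` reports the slope in N per strain-%;
    ``'mpa'`` converts it to an imitative Young's modulus in MPa by
    dividing force by the probe contact area and strain by 100.
    Ties for the peak or the valley go to the first index. A curve whose
    global maximum is the last sample (or that never rises above zero)
    has no post-peak valley and raises :class:`DegenerateCurveError`.
    """
    curve.validate()
    if gradient_mode not in ("raw", "mpa"):
        raise InputError(f"unknown gradient_mode {gradient_mode!r}")
    force, strain = curve.force, curve.strain
    if force.max() <= 0:
        raise DegenerateCurveError(f"curve {curve.fruit!r}: flat zero force, no peak")
    i_max = int(np.argmax(force))  # first index on ties
    if i_max == force.size - 1:
        raise DegenerateCurveError(f"curve {curve.fruit!r}: no post-peak samples")
    post = force[i_max + 1 :]
    i_min = i_max + 1 + int(np.argmin(post))
    slope = _gradient_slope(strain, force, i_max, trigger, gradient_window_frac)
    if gradient_mode == "mpa":
        # stress (N/mm^2) over dimensionless strain: (F/A) / (s/100)
        slope = slope * 100.0 / PROBE_AREA_MM2
    area = float(np.trapezoid(force, strain))
    return TextureProfile(
        gradient=slope,
        max_force=float(force[i_max]),
        max_force_strain=float(strain[i_max]),
        min_force=float(force[i_min]),
        min_force_strain=float(strain[i_min]),
        area=area,
        final_force=float(force[-1]),
        cultivar=curve.cultivar,
        timepoint=curve.timepoint,
        fruit=curve.fruit,
        gradient_mode=gradient_mode,
    )


def profiles_frame(profiles: list[TextureProfile]) -> pd.DataFrame:
    """Long-form table of extracted profiles (one row per fruit)."""
    rows = []
    for p in profiles:
        row = {"cultivar": p.cultivar, "timepoint": p.timepoint, "fruit": p.fruit}
        row.update(p.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def cultivar_means(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean of each trait over fruit, per cultivar x timepoint."""
    traits = [t for t in TEXTURE_TRAITS if t in profiles.columns]
    return profiles.groupby(["cultivar", "timepoint"], sort=True)[traits].mean()


def summarize_texture(
    profiles: pd.DataFrame,
    harvest_label: str = "harvest",
    post_label: str = "postharvest",
) -> pd.DataFrame:
    """Cohort summary table: per trait and timepoint min/max/mean over
    cultivar means, plus the SI min/max/mean columns.

    Cultivar means are taken over fruit first; cohort statistics are then
    computed across those means, and SI per cultivar from the two
    timepoint means. A cultivar present at only one timepoint yields a
    missing SI (logged), not an error.
    """
    means = cultivar_means(profiles)
    levels = means.index.get_level_values("timepoint").unique()
    for label in (harvest_label, post_label):
        if label not in levels:
            raise InputError(f"timepoint {label!r} absent from profiles")
    h = means.xs(harvest_label, level="timepoint")
    p = means.xs(post_label, level="timepoint")
    si = si_matrix(h, p)
    rows = []
    for trait in means.columns:
        row = {"trait": trait}
        for label, frame in ((harvest_label, h), (post_label, p)):
            col = frame[trait].dropna()
            row[f"{label}_min"] = float(col.min())
            row[f"{label}_max"] = float(col.max())
            row[f"{label}_mean"] = float(col.mean())
        si_col = si[trait].dropna()
        if si_col.empty:
            logger.warning("summarize_texture: no SI available for %r", trait)
            row["si_min"] = row["si_max"] = row["si_mean"] = float("nan")
        else:
            row["si_min"] = float(si_col.min())
            row["si_max"] = float(si_col.max())
            row["si_mean"] = float(si_col.mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
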