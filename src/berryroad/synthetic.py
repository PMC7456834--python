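"""Synthetic blueberry cohort generator with known ground truth.

Emulates a germplasm storability study: 46 cultivars measured at harvest
and again after six weeks of cold storage, with

* per-fruit compression mechanograms drawn from texture archetypes
  (turgid / firm / gummy) whose storage shift lowers the loading slope and
  raises the strain at peak force;
* a samples x m/z volatile peak table with blank headspace runs,
  isotopologue channels that are exact scalar multiples of their parent
  peak, and pure-noise channels distributed like the blanks; volatile
  classes carry planted log2 storage trajectories (fermentation products
  and esters rise, terpenes and C6 aldehydes fall);
* mixed-ploidy microsatellite genotypes (hexaploid "rabbiteye"-like and
  tetraploid highbush-like) drawn from K planted populations at six loci
  under a stepwise mutation model.

Every planted quantity is recorded in :class:`CohortTruth` so downstream
feature extraction, filtering, clustering and selection steps can be
tested for parameter recovery without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mechanogram import MechCurve
from .voc import CONC_FLOOR, PeakTable

logger = logging.getLogger(__name__)

TIMEPOINTS = ("harvest", "postharvest")

MECH_PRIMITIVES = ("max_force", "max_force_strain", "min_force",
                   "min_force_strain", "final_force")

#: 13C - 12C mass difference; isotopologue m/z offset from the parent ion.
ISOTOPE_MZ_OFFSET = 1.00336


# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class TextureArchetype:
    """A texture phenotype: mean curve parameters, spread and storage shift.

    ``params`` are the five primitive curve parameters (N and strain %);
    ``cv`` is the per-fruit multiplicative (log-normal) spread; the
    ``storage_shift`` gives log2 changes applied at the postharvest
    timepoint. The loading slope (gradient, N/%) and curve area are
    derived quantities: gradient = max_force / max_force_strain.
    """

    name: str
    params: dict[str, float]
    cv: float = 0.08
    storage_shift: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class VocClass:
    """A volatile class: member ions with harvest means and log2 storage shifts."""

    name: str
    peaks: dict[float, tuple[float, float]]  # mz -> (harvest mean µg/kg, log2 shift)
    cv: float = 0.3


@dataclass(frozen=True)
class GeneticConfig:
    """Planted population structure for the SSR genotypes."""

    n_populations: int = 4
    loci: dict[str, int] = field(default_factory=lambda: {
        "L1": 2, "L2": 2, "L3": 3, "L4": 2, "L5": 4, "L6": 3})  # locus -> repeat bp
    base_sizes: dict[str, int] = field(default_factory=lambda: {
        "L1": 150, "L2": 180, "L3": 210, "L4": 140, "L5": 160, "L6": 200})
    pop_separation: int = 5       # repeat units between population modal alleles
    mutation_p: float = 0.3       # geometric tail of stepwise offsets
    hexaploid_populations: tuple[int, ...] = (0,)  # rabbiteye-like groups


def default_archetypes() -> list[TextureArchetype]:
    """Three storage-responsive texture phenotypes.

    Turgid fruit have a steep loading slope from high turgor pressure and
    lose it sharply in storage; firm fruit resist force but are less
    elastic; gummy fruit deform far before a modest force peak. Shift
    signs follow the cohort-level pattern: strain at peak force rises
    during storage while the loading slope falls.
    """
    common = {"min_force": 0.21, "min_force_strain": 0.24, "final_force": 0.14}
    return [
        TextureArchetype(
            "turgid",
            {"max_force": 4.4, "max_force_strain": 3.2, "min_force": 1.1,
             "min_force_strain": 5.8, "final_force": 1.7},
            storage_shift={"max_force": 0.05, "max_force_strain": 0.45, **common},
        ),
        TextureArchetype(
            "firm",
            {"max_force": 4.8, "max_force_strain": 4.3, "min_force": 0.9,
             "min_force_strain": 6.2, "final_force": 1.5},
            storage_shift={"max_force": 0.10, "max_force_strain": 0.30, **common},
        ),
        TextureArchetype(
            "gummy",
            {"max_force": 2.8, "max_force_strain": 4.9, "min_force": 0.6,
             "min_force_strain": 6.6, "final_force": 1.0},
            storage_shift={"max_force": 0.05, "max_force_strain": 0.22, **common},
        ),
    ]


def default_voc_classes() -> list[VocClass]:
    """Volatile classes with harvest means and storage trajectories.

    Fermentation metabolites (ethanol, acetaldehyde) and esters increase
    under cold storage; terpenes and C6 (green-leaf) aldehydes decrease;
    methanol, a cell-wall degradation marker, rises mildly.
    """
    return [
        VocClass("alcohols", {33.033: (2228.0, 0.77), 47.043: (2.4, 6.68),
                              85.100: (0.43, 2.14)}),
        VocClass("acetaldehyde", {45.031: (80.8, 3.21)}),
        VocClass("esters", {75.044: (0.5, 2.2), 89.055: (0.8, 2.52),
                            117.092: (0.4, 2.66), 131.107: (0.23, 3.14)}),
        VocClass("terpenes", {137.134: (8.3, -1.15), 81.070: (15.0, -1.0)}),
        VocClass("c6_aldehydes", {99.080: (92.5, -0.61), 101.096: (30.0, -0.29),
                                  83.085: (20.0, -0.5)}),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for one synthetic cohort."""

    n_cultivars: int = 46
    n_fruit_per_cultivar: int = 20
    n_voc_replicates: int = 3
    n_blanks: int = 6
    timepoints: tuple[str, str] = TIMEPOINTS
    texture_archetypes: list[TextureArchetype] = field(default_factory=default_archetypes)
    voc_classes: list[VocClass] = field(default_factory=default_voc_classes)
    n_extra_signal_peaks: int = 40
    n_isotope_peaks: int = 15
    n_noise_peaks: int = 30
    genetic: GeneticConfig = field(default_factory=GeneticConfig)
    seed: int = 0
    # instrument / noise model
    force_noise_frac: float = 0.01      # force noise sigma as fraction of peak force
    berry_diameter_mm: float = 15.0
    test_speed_mm_min: float = 100.0
    acquisition_rate: float = 500.0     # points per second
    blank_level: float = 0.05           # µg/kg, median blank concentration
    blank_sigma: float = 0.5            # log-sd of blank concentrations
    cultivar_effect_sigma: float = 0.4  # log-sd of cultivar-level VOC multipliers
    voc_boost: float = 4.0              # over-expression factor for the boosted class
    noise_free: bool = False            # exact means, no replicate/fruit noise

    def validate(self) -> None:
        for fld in ("n_cultivars", "n_fruit_per_cultivar", "n_voc_replicates",
                    "n_blanks", "n_extra_signal_peaks", "n_isotope_peaks",
                    "n_noise_peaks"):
            v = getattr(self, fld)
            if not isinstance(v, (int, np.integer)) or v < 0 or (
                    fld in ("n_cultivars", "n_fruit_per_cultivar",
                            "n_voc_replicates", "n_blanks") and v < 1):
                raise ConfigError(f"{fld} must be a positive count, got {v!r}")
        if len(self.timepoints) != 2:
            raise ConfigError(f"timepoints must be two labels, got {self.timepoints!r}")
        if not self.texture_archetypes:
            raise ConfigError("texture_archetypes must be non-empty")
        for a in self.texture_archetypes:
            if a.cv < 0:
                raise ConfigError(f"texture_archetypes: cv must be >= 0, got {a.cv}")
            missing = set(MECH_PRIMITIVES) - set(a.params)
            if missing:
                raise ConfigError(f"texture_archetypes: {a.name!r} missing params {sorted(missing)}")
        for c in self.voc_classes:
            if c.cv < 0:
                raise ConfigError(f"voc_classes: cv must be >= 0, got {c.cv}")
        g = self.genetic
        if g.n_populations < 1:
            raise ConfigError(f"genetic.n_populations must be >= 1, got {g.n_populations}")
        if any(r < 1 for r in g.loci.values()):
            raise ConfigError("genetic.loci repeat lengths must be >= 1")
        if not (0 < g.mutation_p <= 1):
            raise ConfigError(f"genetic.mutation_p must be in (0,1], got {g.mutation_p}")


@dataclass
class CohortTruth:
    """Ground truth planted by :func:`simulate_cohort`."""

    archetype: dict[str, str]           # cultivar -> texture archetype name
    voc_membership: dict[str, str]      # cultivar -> over-expressed VOC class
    population: dict[str, int]          # cultivar -> population of origin
    texture_shift_signs: dict[str, int]  # trait -> sign of planted storage shift
    voc_shift_signs: dict[float, int]   # mz -> sign of planted log2 shift
    voc_class_of_mz: dict[float, str]   # signal mz -> class name
    voc_class_shifts: dict[str, float]  # class name -> mean planted log2 shift
    isotopes: dict[float, tuple[float, float]]  # iso mz -> (parent mz, factor)
    noise_mz: list[float]
    mech_params: pd.DataFrame           # planted per-fruit curve parameters
    population_modes: dict[str, dict[int, int]]  # locus -> pop -> modal repeat count

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["mech_params"] = self.mech_params.to_dict(orient="list")
        d["voc_shift_signs"] = {str(k): v for k, v in self.voc_shift_signs.items()}
        d["voc_class_of_mz"] = {str(k): v for k, v in self.voc_class_of_mz.items()}
        d["isotopes"] = {str(k): list(v) for k, v in self.isotopes.items()}
        d["population_modes"] = {loc: {str(p): m for p, m in mm.items()}
                                 for loc, mm in self.population_modes.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# Mechanograms


def _piecewise_truth(params: dict[str, float]) -> dict[str, float]:
    """Closed-form texture parameters of the noise-free piecewise-linear curve."""
    s = [0.0, params["max_force_strain"], params["min_force_strain"], 90.0]
    f = [0.0, params["max_force"], params["min_force"], params["final_force"]]
    area = sum(0.5 * (f[i] + f[i + 1]) * (s[i + 1] - s[i]) for i in range(3))
    return {
        "gradient": params["max_force"] / params["max_force_strain"],
        "max_force": params["max_force"],
        "max_force_strain": params["max_force_strain"],
        "min_force": params["min_force"],
        "min_force_strain": params["min_force_strain"],
        "area": area,
        "final_force": params["final_force"],
    }


def _clip_params(p: dict[str, float]) -> tuple[dict[str, float], bool]:
    """Force the curve parameters into a geometrically valid ordering."""
    q = dict(p)
    clipped = False
    if q["max_force_strain"] < 0.5:
        q["max_force_strain"], clipped = 0.5, True
    if q["min_force_strain"] < q["max_force_strain"] + 0.5:
        q["min_force_strain"], clipped = q["max_force_strain"] + 0.5, True
    if q["min_force_strain"] > 89.0:
        q["min_force_strain"], clipped = 89.0, True
    if q["max_force"] < 0.05:
        q["max_force"], clipped = 0.05, True
    if q["min_force"] > 0.9 * q["max_force"]:
        q["min_force"], clipped = 0.9 * q["max_force"], True
    if q["min_force"] < 0.01:
        q["min_force"], clipped = 0.01, True
    if q["final_force"] < q["min_force"]:
        q["final_force"], clipped = q["min_force"], True
    return q, clipped


def simulate_mechanogram(
    params: dict[str, float],
    rng: np.random.Generator,
    *,
    noise_sigma_frac: float = 0.0,
    berry_diameter_mm: float = 15.0,
    test_speed_mm_min: float = 100.0,
    acquisition_rate: float = 500.0,
    cultivar: str = "",
    timepoint: str = "",
    fruit: str = "",
) -> MechCurve:
    """One piecewise-linear compression curve through the planted vertices.

    Strain is sampled on the grid implied by the acquisition settings
    (test speed / rate / berry diameter) with the exact vertex strains
    inserted, so in noise-free mode the extracted parameters match the
    planted ones to machine precision. Gaussian force noise (sigma as a
    fraction of peak force) is optional; force is clipped at zero.
    """
    q, clipped = _clip_params(params)
    if clipped:
        logger.warning("simulate_mechanogram: parameters clipped to a valid curve (%s)", fruit)
    # strain advance per acquired point, in % of berry diameter
    step = (test_speed_mm_min / 60.0 / acquisition_rate) / berry_diameter_mm * 100.0
    grid = np.arange(0.0, 90.0, step)
    knots_s = np.array([0.0, q["max_force_strain"], q["min_force_strain"], 90.0])
    knots_f = np.array([0.0, q["max_force"], q["min_force"], q["final_force"]])
    strain = np.unique(np.concatenate([grid, knots_s]))
    force = np.interp(strain, knots_s, knots_f)
    if noise_sigma_frac > 0:
        force = force + rng.normal(0.0, noise_sigma_frac * q["max_force"], size=force.size)
        force = np.clip(force, 0.0, None)
    return MechCurve(strain=strain, force=force, cultivar=cultivar,
                     timepoint=timepoint, fruit=fruit,
                     acquisition_rate=acquisition_rate)


def _simulate_texture(
    config: CohortConfig, cultivars: list[str], rng: np.random.Generator
) -> tuple[dict[str, str], list[MechCurve], pd.DataFrame]:
    archetypes = config.texture_archetypes
    assignment = {c: archetypes[i % len(archetypes)].name for i, c in enumerate(cultivars)}
    by_name = {a.name: a for a in archetypes}
    curves: list[MechCurve] = []
    truth_rows = []
    for c in cultivars:
        arch = by_name[assignment[c]]
        for tp_i, tp in enumerate(config.timepoints):
            for k in range(config.n_fruit_per_cultivar):
                p = {}
                for prim in MECH_PRIMITIVES:
                    mean = arch.params[prim]
                    if tp_i == 1:
                        mean *= 2.0 ** arch.storage_shift.get(prim, 0.0)
                    noise = 0.0 if config.noise_free else rng.normal(0.0, arch.cv)
                    p[prim] = mean * math.exp(noise)
                p, _ = _clip_params(p)
                fruit_id = f"{c}-{tp}-{k:02d}"
                curve = simulate_mechanogram(
                    p, rng,
                    noise_sigma_frac=0.0 if config.noise_free else config.force_noise_frac,
                    berry_diameter_mm=config.berry_diameter_mm,
                    test_speed_mm_min=config.test_speed_mm_min,
                    acquisition_rate=config.acquisition_rate,
                    cultivar=c, timepoint=tp, fruit=fruit_id)
                curves.append(curve)
                row = {"cultivar": c, "timepoint": tp, "fruit": fruit_id}
                row.update(_piecewise_truth(p))
                truth_rows.append(row)
    return assignment, curves, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Volatile peak table


def _simulate_voc(
    config: CohortConfig, cultivars: list[str], rng: np.random.Generator
) -> tuple[dict[str, str], dict, PeakTable]:
    classes = config.voc_classes
    class_names = [c.name for c in classes]
    # which class (if any) each cultivar over-expresses
    choices = ["balanced"] + class_names
    probs = np.array([0.4] + [0.6 / len(class_names)] * len(class_names))
    membership = {c: choices[rng.choice(len(choices), p=probs)] for c in cultivars}

    signal: dict[float, tuple[str, float, float]] = {}  # mz -> (class, mean, shift)
    for cl in classes:
        for mz, (mean, shift) in cl.peaks.items():
            signal[round(float(mz), 4)] = (cl.name, float(mean), float(shift))
    for _ in range(config.n_extra_signal_peaks):
        while True:
            mz = round(float(rng.uniform(26.0, 250.0)), 4)
            if mz not in signal:
                break
        mean = float(np.exp(rng.normal(0.0, 1.5)))
        shift = float(rng.normal(0.0, 1.0))
        signal[mz] = ("misc", mean, shift)
    signal_mz = sorted(signal)

    isotopes: dict[float, tuple[float, float]] = {}
    if config.n_isotope_peaks > len(signal_mz):
        raise ConfigError("n_isotope_peaks exceeds the number of signal peaks")
    parents = rng.choice(len(signal_mz), size=config.n_isotope_peaks, replace=False)
    for pi in parents:
        parent = signal_mz[pi]
        iso = round(parent + ISOTOPE_MZ_OFFSET, 4)
        while iso in signal or iso in isotopes:
            iso = round(iso + 1e-4, 4)
        isotopes[iso] = (parent, float(rng.uniform(0.005, 0.2)))

    noise_mz: list[float] = []
    taken = set(signal) | set(isotopes)
    for _ in range(config.n_noise_peaks):
        while True:
            mz = round(float(rng.uniform(26.0, 250.0)), 4)
            if mz not in taken:
                break
        taken.add(mz)
        noise_mz.append(mz)
    noise_mz.sort()

    all_mz = sorted(set(signal) | set(isotopes) | set(noise_mz))
    meta_rows = []
    for c in cultivars:
        for tp in config.timepoints:
            for r in range(config.n_voc_replicates):
                meta_rows.append({"sample": f"{c}-{tp}-r{r}", "cultivar": c,
                                  "timepoint": tp, "replicate": r, "is_blank": False})
    for b in range(config.n_blanks):
        meta_rows.append({"sample": f"blank-{b}", "cultivar": None,
                          "timepoint": None, "replicate": b, "is_blank": True})
    meta = pd.DataFrame(meta_rows)

    # cultivar-level multipliers (shared across timepoints so SI is unaffected)
    cultivar_mult = {}
    for c in cultivars:
        base = {} if config.noise_free else {
            name: math.exp(rng.normal(0.0, config.cultivar_effect_sigma))
            for name in class_names + ["misc"]}
        for name in class_names + ["misc"]:
            m = base.get(name, 1.0)
            if membership[c] == name:
                m *= config.voc_boost
            cultivar_mult[(c, name)] = m

    n_samples = len(meta)
    conc = np.zeros((n_samples, len(all_mz)))
    col = {mz: j for j, mz in enumerate(all_mz)}
    is_blank = meta["is_blank"].astype(bool).values
    cv_of = {cl.name: cl.cv for cl in classes}
    cv_of["misc"] = 0.3

    # blank-like background for every channel in blank samples, and for
    # noise channels everywhere (noise peaks are exchangeable with blanks)
    log_blank = math.log(config.blank_level)
    background = np.exp(rng.normal(log_blank, config.blank_sigma,
                                   size=(n_samples, len(all_mz))))
    noise_set = set(noise_mz)
    for j, mz in enumerate(all_mz):
        if mz in noise_set:
            conc[:, j] = background[:, j]
        else:
            conc[is_blank, j] = background[is_blank, j]

    for i, row in meta.iterrows():
        if row["is_blank"]:
            continue
        c, tp = row["cultivar"], row["timepoint"]
        post = tp == config.timepoints[1]
        for mz in signal_mz:
            name, mean, shift = signal[mz]
            level = mean * cultivar_mult[(c, name)]
            if post:
                level *= 2.0 ** shift
            cv = 0.0 if config.noise_free else cv_of[name]
            if cv > 0:
                level *= math.exp(rng.normal(0.0, cv))
            conc[i, col[mz]] = level

    # isotope channels are exact scalar multiples of their parent channel
    for iso, (parent, factor) in isotopes.items():
        conc[:, col[iso]] = factor * conc[:, col[parent]]

    if not config.noise_free:
        # trace-level reporting floor; skipped in the diagnostic noise-free
        # mode so planted relationships (e.g. exact isotope multiples) stay
        # closed-form
        conc = np.maximum(conc, CONC_FLOOR)
    table = PeakTable(meta, pd.DataFrame(conc, columns=all_mz))
    voc_truth = {
        "class_of_mz": {mz: signal[mz][0] for mz in signal_mz},
        "shift_signs": {mz: int(np.sign(signal[mz][2])) for mz in signal_mz},
        "class_shifts": {
            cl.name: float(np.mean([sh for _, sh in cl.peaks.values()])) for cl in classes},
        "isotopes": isotopes,
        "noise_mz": noise_mz,
    }
    return membership, voc_truth, table


# ---------------------------------------------------------------------------
# Genotypes


def _simulate_genotypes(
    config: CohortConfig, cultivars: list[str], rng: np.random.Generator
) -> tuple[dict[str, int], dict[str, dict[int, int]], pd.DataFrame]:
    g = config.genetic
    population = {c: i % g.n_populations for i, c in enumerate(cultivars)}
    modes: dict[str, dict[int, int]] = {}
    for locus in g.loci:
        base = 20 + int(rng.integers(0, 4))  # modal repeat count of population 0
        modes[locus] = {}
        for p in range(g.n_populations):
            jitter = int(rng.integers(-1, 2))
            modes[locus][p] = base + p * g.pop_separation + jitter
    rows = []
    for c in cultivars:
        pop = population[c]
        ploidy = 6 if pop in g.hexaploid_populations else 4
        for locus, repeat in g.loci.items():
            mode = modes[locus][pop]
            alleles = []
            for _ in range(ploidy):
                offset = int(rng.geometric(g.mutation_p)) - 1
                sign = 1 if rng.random() < 0.5 else -1
                repeats = max(2, mode + sign * offset)
                alleles.append(g.base_sizes[locus] + repeats * repeat)
            alleles.sort()
            row = {"cultivar": c, "locus": locus, "ploidy": ploidy}
            for k in range(6):
                row[f"allele_{k + 1}"] = alleles[k] if k < len(alleles) else None
            rows.append(row)
    return population, modes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort


def simulate_cohort(
    config: CohortConfig,
) -> tuple[CohortTruth, list[MechCurve], PeakTable, pd.DataFrame]:
    """Generate one full cohort: curves, peak table, genotypes and truth.

    Deterministic for a fixed config and seed. Returns the truth object,
    the list of mechanograms (cultivar x timepoint x fruit), the volatile
    peak table (with blanks) and the long-form genotype table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cultivars = [f"cv{i + 1:02d}" for i in range(config.n_cultivars)]

    arch_assign, curves, mech_truth = _simulate_texture(config, cultivars, rng)
    membership, voc_truth, peaks = _simulate_voc(config, cultivars, rng)
    population, modes, genotypes = _simulate_genotypes(config, cultivars, rng)

    texture_signs = {}
    for trait in MECH_PRIMITIVES:
        shifts = [a.storage_shift.get(trait, 0.0) for a in config.texture_archetypes]
        texture_signs[trait] = int(np.sign(np.mean(shifts)))
    # derived traits: gradient falls when strain rises faster than force
    grad_shift = np.mean([a.storage_shift.get("max_force", 0.0)
                          - a.storage_shift.get("max_force_strain", 0.0)
                          for a in config.texture_archetypes])
    texture_signs["gradient"] = int(np.sign(grad_shift))

    truth = CohortTruth(
        archetype=arch_assign,
        voc_membership=membership,
        population=population,
        texture_shift_signs=texture_signs,
        voc_shift_signs=voc_truth["shift_signs"],
        voc_class_of_mz=voc_truth["class_of_mz"],
        voc_class_shifts=voc_truth["class_shifts"],
        isotopes=voc_truth["isotopes"],
        noise_mz=voc_truth["noise_mz"],
        mech_params=mech_truth,
        population_modes=modes,
    )
    return truth, curves, peaks, genotypes
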