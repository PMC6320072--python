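"""Synthetic measurement tables with the statistical structure the
analysis assumes.

The generator emulates the study conditions end to end: Kleiber-law
cohort calorimetry over three decades of size, animal tables linking
plan area, mass and cell number, paradigm-governed growth/degrowth
traces under weekly feeding, Poisson bead counts for the food-intake
assay, bomb-calorimetry cohorts at a fixed gross/physiological factor,
and a per-size-class composition table. Sizes, masses and energies
carry multiplicative lognormal noise (positive, scale-free — the
natural error model for log-log fits); counts are Poisson.

Determinism: one master seed; each table draws from its own derived
substream, so tables are independently reproducible and changing the
seed changes noise realisations, never structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .energy import EnergyBalanceModel, FeedingSchedule, PW_TO_J_PER_DAY
from .powerlaw import PowerLawResults
from . import io as tio

__all__ = ["GeneratorConfig", "gen_scaling_dataset", "gen_animals",
           "gen_traces", "gen_cohorts", "gen_feeding_assay",
           "gen_composition", "gen_bomb_calorimetry", "write_all_tables"]

# fixed substream ids so each table is independently reproducible
_STREAMS = {"scaling": 1, "animals": 2, "traces_growth": 3,
            "traces_degrowth": 4, "cohorts": 5, "feeding_assay": 6,
            "composition": 7, "bomb": 8}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic tables.

    Defaults mirror the measured calibration: Kleiber exponent 0.75,
    cell-number/area exponent 1.19, allometric-reserve paradigm with
    c = 0.38, per-cell metabolic rate p = 1 pW, influx while digesting
    j = 2.5 pW/cell, wet/dry mass ratio 5, gross energy at twice the
    physiological reserve, liver energy density 6.15 J/ul. Noise: CV
    0.10 (lognormal) on masses/areas/energies, CV 0.25 on directly
    generated rates, Poisson on counts. Sizes span >= 3 decades of cell
    number.
    """

    seed: int
    # energy-balance truth
    paradigm: int = 3
    c: float = 0.38
    p_pw: float = 1.0
    j_pw: float = 2.5
    e_ref: float = 3e-6           # J/cell at n_ref
    n_ref: float = 1e6
    feed_pulse_days: float = 3.5  # digestion window per weekly feeding
    # scaling-law truth
    kleiber_exponent: float = 0.75
    n_vs_area_exponent: float = 1.19
    n_vs_area_prefactor: float = 1e5    # cells at A = 1 mm^2
    wet_dry_ratio: float = 5.0
    dry_mass_at_nref_mg: float = 0.3
    length_area_exponent: float = 1.8
    length_area_prefactor: float = 0.15  # mm^2 at L = 1 mm
    assimilation_factor: float = 2.0     # gross / physiological energy
    liver_energy_density: float = 6.15
    red_beads_per_ul_liver: float = 6.5e5
    green_beads_per_drop: float = 300.0
    # noise
    cv_mass: float = 0.10
    cv_rate: float = 0.25
    # size range (cell numbers, >= 3 decades)
    n_min: float = 2e4
    n_max: float = 2e7
    # composition truth: component -> (pg/cell in the 4 mm class,
    # fold change 16 mm vs 4 mm)
    size_classes_mm: tuple[float, ...] = (4.0, 8.0, 16.0)
    composition_truth: tuple = (
        ("TG", 0.35, 88.0),
        ("glycogen", 1.2, 8.8),
        ("other_lipids", 4.0, 1.8),
        ("other_carbohydrates", 1.0, 2.0),
        ("protein", 15.0, 1.5),
    )
    residual_fraction: float = 0.08  # unmeasured share of total dry mass
    cv_composition: float = 0.12

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required")
        for cv in (self.cv_mass, self.cv_rate, self.cv_composition):
            if cv < 0:
                raise ValueError("noise CVs must be >= 0")
        if not (self.n_max / self.n_min >= 1e3):
            raise ValueError("size range must span >= 3 decades")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2 ** 31),
                                      _STREAMS[stream]])

    def energy_model(self) -> EnergyBalanceModel:
        if self.paradigm == 3:
            return EnergyBalanceModel.allometric(
                j=self.j_pw, p=self.p_pw, c=self.c, e_ref=self.e_ref,
                n_ref=self.n_ref)
        if self.paradigm == 2:
            return EnergyBalanceModel.isometric(
                j=self.j_pw, p=self.p_pw, epsilon=self.e_ref)
        # dynamic reserve: set point at 100x the daily per-cell heat loss
        # and a sensitivity giving percent-per-day rates with a reserve
        # relaxation time of weeks, so feeding history stays visible
        e_set = 100.0 * self.p_pw * PW_TO_J_PER_DAY
        return EnergyBalanceModel.dynamic_reserve(
            j=self.j_pw, p=self.p_pw, k=0.04 / e_set, e_set=e_set)

    # derived truths -------------------------------------------------------
    def n_vs_area(self) -> PowerLawResults:
        return PowerLawResults(self.n_vs_area_exponent,
                               math.log(self.n_vs_area_prefactor),
                               0.0, 0.0, 0.0, 3, "derived",
                               derivation="generator truth")

    def length_area(self) -> PowerLawResults:
        return PowerLawResults(self.length_area_exponent,
                               math.log(self.length_area_prefactor),
                               0.0, 0.0, 0.0, 3, "derived",
                               derivation="generator truth")

    def dry_mass_of_cells(self, N):
        """Dry mass [mg]; exponent 1/b so that P ~ M^b with P = p*N."""
        return self.dry_mass_at_nref_mg * (
            np.asarray(N, dtype=float) / self.n_ref
        ) ** (1.0 / self.kleiber_exponent)

    def area_of_cells(self, N):
        return (np.asarray(N, dtype=float) / self.n_vs_area_prefactor) ** (
            1.0 / self.n_vs_area_exponent)

    def cells_at_length(self, length_mm):
        area = self.length_area_prefactor * np.asarray(
            length_mm, dtype=float) ** self.length_area_exponent
        return self.n_vs_area_prefactor * area ** self.n_vs_area_exponent

    def to_dict(self) -> dict:
        d = asdict(self)
        d["composition_truth"] = [list(t) for t in self.composition_truth]
        d["size_classes_mm"] = list(self.size_classes_mm)
        return d


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-median multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _log_uniform(rng, lo, hi, size):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size))


# ---------------------------------------------------------------------------

#: named scaling relations available to gen_scaling_dataset,
#: mapping relation -> (x column, y column)
RELATIONS = {
    "N~A": ("plan_area_mm2", "cell_count"),
    "M_dry~A": ("plan_area_mm2", "dry_mass_mg"),
    "M_wet~M_dry": ("dry_mass_mg", "wet_mass_mg"),
    "P~M_dry": ("dry_mass_mg", "heat_flow_uW"),
    "E~N": ("cell_count", "energy_J"),
}


def gen_scaling_dataset(cfg: GeneratorConfig, relation: str, n: int
                        ) -> pd.DataFrame:
    """Generate one (x, y) cloud for a named scaling relation.

    x is the design variable: log-uniform over the configured size range
    (mapped into the relation's natural units) and noise-free. y follows
    the generator's truth for the relation times lognormal noise of CV
    ``cv_mass``.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; "
                         f"known: {sorted(RELATIONS)}")
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = cfg.rng("scaling")
    N = _log_uniform(rng, cfg.n_min, cfg.n_max, n)
    area = cfg.area_of_cells(N)
    dry = cfg.dry_mass_of_cells(N)
    truth = {
        "N~A": (area, N),
        "M_dry~A": (area, dry),
        "M_wet~M_dry": (dry, dry * cfg.wet_dry_ratio),
        "P~M_dry": (dry, cfg.p_pw * N * 1e-6),  # pW -> uW
        "E~N": (N, cfg.assimilation_factor * cfg.e_ref * N
                * (N / cfg.n_ref) ** cfg.c),
    }[relation]
    xcol, ycol = RELATIONS[relation]
    y = truth[1] * _lognormal(rng, cfg.cv_mass, n)
    return pd.DataFrame({xcol: truth[0], ycol: y})


def gen_animals(cfg: GeneratorConfig, n: int = 80) -> pd.DataFrame:
    """Per-animal table with plan area, dry/wet mass and cell count."""
    rng = cfg.rng("animals")
    N = _log_uniform(rng, cfg.n_min, cfg.n_max, n)
    df = pd.DataFrame({
        "animal_id": [f"an{i:03d}" for i in range(n)],
        "plan_area_mm2": cfg.area_of_cells(N) * _lognormal(rng, cfg.cv_mass, n),
        "dry_mass_mg": cfg.dry_mass_of_cells(N) * _lognormal(rng, cfg.cv_mass, n),
        "wet_mass_mg": (cfg.dry_mass_of_cells(N) * cfg.wet_dry_ratio
                        * _lognormal(rng, cfg.cv_mass, n)),
        "cell_count": N * _lognormal(rng, cfg.cv_mass, n),
    })
    return tio.validate_table(df, "animals")


def gen_cohorts(cfg: GeneratorConfig, n_vials: int = 80) -> pd.DataFrame:
    """Microcalorimetry vials of size-matched cohorts.

    Vial heat is the summed per-animal metabolic rate ``p * N``; pooled
    dry mass follows the mass law; both carry lognormal noise. Animal
    counts per vial scale inversely with size and are clamped to
    [2, 130] so vial signals are size-matched.
    """
    if n_vials < 3:
        raise ValueError("n_vials must be >= 3")
    rng = cfg.rng("cohorts")
    N = _log_uniform(rng, cfg.n_min, cfg.n_max, n_vials)
    n_animals = np.clip(
        np.round(130.0 * (N / cfg.n_min) ** (-2.0 / 3.0)).astype(int), 2, 130)
    heat_uW = (cfg.p_pw * N * 1e-6) * n_animals * _lognormal(rng, cfg.cv_mass,
                                                             n_vials)
    dry_mg = cfg.dry_mass_of_cells(N) * n_animals * _lognormal(
        rng, cfg.cv_mass, n_vials)
    df = pd.DataFrame({
        "vial_id": [f"vial{i:03d}" for i in range(n_vials)],
        "n_animals": n_animals,
        "heat_flow_uW": heat_uW,
        "pooled_dry_mass_mg": dry_mg,
        "starved_weeks": np.where(np.arange(n_vials) % 2 == 0, 2.0, 3.0),
    })
    return tio.validate_table(df, "cohorts")


def gen_traces(cfg: GeneratorConfig, n_animals: int, regime: str,
               history_weeks: tuple[float, ...] = (1.0, 3.0),
               duration_days: float = 42.0,
               sample_every_days: float = 2.0) -> pd.DataFrame:
    """Paradigm-governed plan-area traces in the long traces schema.

    Each animal is simulated with the configured energy model from a
    log-uniform starting size; observed areas go through the inverse
    cell-number/area law with multiplicative measurement noise. Growth
    traces are fed weekly (digestion window ``feed_pulse_days``);
    degrowth traces starve throughout, starting ``history_weeks`` after
    the last feeding (cycled across animals).
    """
    if n_animals < 0:
        raise ValueError("n_animals must be >= 0")
    frames = []
    if n_animals == 0 or duration_days <= 0:
        return pd.DataFrame(columns=["animal_id", "time_days",
                                     "plan_area_mm2", "fed", "regime",
                                     "starved_weeks"])
    rng = cfg.rng("traces_growth" if regime == "growth" else "traces_degrowth")
    model = cfg.energy_model()
    t_grid = np.arange(0.0, duration_days + 1e-9, sample_every_days)
    if regime == "growth":
        schedule = FeedingSchedule.weekly(
            int(math.ceil(duration_days / 7.0)), cfg.feed_pulse_days)
        n0_range = (max(cfg.n_min, 1e5), 1e6)
    elif regime == "degrowth":
        schedule = FeedingSchedule.starvation()
        n0_range = (max(cfg.n_min, 1e5), cfg.n_max)
    else:
        raise ValueError("regime must be 'growth' or 'degrowth'")
    N0s = _log_uniform(rng, *n0_range, n_animals)
    for i in range(n_animals):
        kwargs = {}
        N_start = N0s[i]
        if cfg.paradigm == 1:
            # reserve starts at the set point (just fed); degrowth traces
            # first deplete it over the stated starvation history
            E_start = model.e_set * N_start
            hist = (history_weeks[i % len(history_weeks)]
                    if regime == "degrowth" else 0.0)
            if hist > 0:
                pre = model.simulate(
                    FeedingSchedule.starvation(), N_start, E0=E_start,
                    t_grid=np.linspace(0.0, 7.0 * hist, 8))
                N_start, E_start = pre.N[-1], pre.E[-1]
            kwargs["E0"] = E_start
        traj = model.simulate(schedule, N_start, t_grid=t_grid, **kwargs)
        area = cfg.area_of_cells(traj.N) * _lognormal(rng, cfg.cv_mass,
                                                      traj.N.size)
        frames.append(pd.DataFrame({
            "animal_id": f"{regime[0]}{i:03d}",
            "time_days": traj.times,
            "plan_area_mm2": area,
            "fed": traj.fed.astype(int),
            "regime": regime,
            "starved_weeks": (history_weeks[i % len(history_weeks)]
                              if regime == "degrowth" else 0.0),
        }))
    df = pd.concat(frames, ignore_index=True)
    return tio.validate_table(df, "traces")


def gen_feeding_assay(cfg: GeneratorConfig, n_animals: int = 60
                      ) -> pd.DataFrame:
    """Poisson bead counts around a size-proportional liver intake.

    True ingested volume is the weekly meal energy ``j * N * 7 d``
    divided by the liver energy density, so intake per cell is
    size-independent. Red-bead counts in the 1 ul drops are Poisson
    around the implied densities; a lognormal drop-volume error hits the
    animal drop's red and green counts jointly (the green normalisation
    removes it in expectation).
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = cfg.rng("feeding_assay")
    N = _log_uniform(rng, cfg.n_min, cfg.n_max, n_animals)
    meal_energy_J = cfg.j_pw * PW_TO_J_PER_DAY * 7.0 * N
    volume_ul = meal_energy_J / cfg.liver_energy_density
    macerate_ul = np.clip(300.0 * (N / cfg.n_min) ** 0.35, 300.0, 5000.0)
    drop_err = _lognormal(rng, 0.05, n_animals)
    red_density = volume_ul * cfg.red_beads_per_ul_liver / macerate_ul
    liver_macerate_ul = 500.0
    liver_basis_ul = 2.0
    liver_density = (cfg.red_beads_per_ul_liver * liver_basis_ul
                     / liver_macerate_ul)
    df = pd.DataFrame({
        "animal_id": [f"fa{i:03d}" for i in range(n_animals)],
        "plan_area_mm2": cfg.area_of_cells(N) * _lognormal(rng, cfg.cv_mass,
                                                           n_animals),
        "red_beads_worm_drop": rng.poisson(red_density * drop_err).astype(float),
        "green_beads_drop": rng.poisson(
            cfg.green_beads_per_drop * drop_err).astype(float),
        "green_beads_reference": rng.poisson(
            cfg.green_beads_per_drop, n_animals).astype(float),
        "macerate_volume_ul": macerate_ul,
        "red_beads_liver_drop": rng.poisson(
            liver_density, n_animals).astype(float),
        "liver_macerate_volume_ul": liver_macerate_ul,
        "liver_volume_basis_ul": liver_basis_ul,
        "starved_weeks": np.where(np.arange(n_animals) % 2 == 0, 2.0, 3.0),
    })
    # zero counts in required-positive columns are re-drawn conditional > 0
    for col in ("green_beads_drop", "green_beads_reference",
                "red_beads_liver_drop"):
        zero = df[col] <= 0
        while zero.any():
            df.loc[zero, col] = rng.poisson(
                cfg.green_beads_per_drop, int(zero.sum())).astype(float)
            zero = df[col] <= 0
    return tio.validate_table(df, "feeding_assay")


def gen_bomb_calorimetry(cfg: GeneratorConfig, n_cohorts: int = 40
                         ) -> pd.DataFrame:
    """Combustion energies of pooled size-matched cohorts.

    Gross energy per animal is the physiological reserve ``e(N) * N``
    scaled by the assimilation factor (default 2); pooled dry mass
    follows the mass law.
    """
    if n_cohorts < 3:
        raise ValueError("n_cohorts must be >= 3")
    rng = cfg.rng("bomb")
    N = _log_uniform(rng, cfg.n_min, cfg.n_max, n_cohorts)
    n_animals = np.clip(
        np.round(200.0 * (N / cfg.n_min) ** (-0.75)).astype(int), 2, 200)
    e_phys = cfg.e_ref * (N / cfg.n_ref) ** cfg.c
    energy = (cfg.assimilation_factor * e_phys * N * n_animals
              * _lognormal(rng, cfg.cv_mass, n_cohorts))
    dry = (cfg.dry_mass_of_cells(N) * n_animals
           * _lognormal(rng, cfg.cv_mass, n_cohorts))
    df = pd.DataFrame({
        "cohort_id": [f"bc{i:03d}" for i in range(n_cohorts)],
        "n_animals": n_animals,
        "pooled_dry_mass_mg": dry,
        "energy_J": energy,
        "starved_weeks": np.where(np.arange(n_cohorts) % 2 == 0, 1.0, 3.0),
    })
    return tio.validate_table(df, "bomb_calorimetry")


def gen_composition(cfg: GeneratorConfig, n_replicates: int = 5
                    ) -> pd.DataFrame:
    """Per-size-class component masses (per pooled animal, ug).

    Each component's per-cell mass follows a power law in N anchored by
    its 4 mm value and its 16 mm/4 mm fold change; the independently
    'measured' total dry mass is the component sum inflated by the
    configured unmeasured residual fraction. Replicates carry lognormal
    noise.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = cfg.rng("composition")
    classes = np.asarray(cfg.size_classes_mm, dtype=float)
    ncells = cfg.cells_at_length(classes)
    lo, hi = classes.min(), classes.max()
    n_lo, n_hi = cfg.cells_at_length(lo), cfg.cells_at_length(hi)
    rows = []
    truth_per_cell = {}
    for comp, pg_at_4mm, fold in cfg.composition_truth:
        expo = math.log(fold) / math.log(n_hi / n_lo)
        truth_per_cell[comp] = pg_at_4mm * (ncells / n_lo) ** expo
    total_truth = (1.0 + cfg.residual_fraction) * np.sum(
        np.vstack(list(truth_per_cell.values())), axis=0)
    truth_per_cell["total_dry_mass"] = total_truth
    for comp, per_cell in truth_per_cell.items():
        for irep in range(n_replicates):
            noise = _lognormal(rng, cfg.cv_composition, classes.size)
            mass_ug = per_cell * ncells * 1e-6 * noise
            for sc, m in zip(classes, mass_ug):
                rows.append({"size_class_mm": sc, "component": comp,
                             "replicate_id": f"rep{irep}",
                             "mass_per_animal_ug": m})
    df = pd.DataFrame(rows)
    return tio.validate_table(df, "composition")


def write_all_tables(cfg: GeneratorConfig, out_dir,
                     n_animals: int = 80, n_vials: int = 80,
                     n_growth: int = 40, n_degrowth: int = 60,
                     n_assay: int = 60, n_bomb: int = 40) -> dict:
    """Generate and write every input table the pipeline consumes."""
    from pathlib import Path

    out = Path(out_dir)
    tables = {
        "animals": gen_animals(cfg, n_animals),
        "cohorts": gen_cohorts(cfg, n_vials),
        "traces": pd.concat([
            gen_traces(cfg, n_growth, "growth"),
            gen_traces(cfg, n_degrowth, "degrowth"),
        ], ignore_index=True),
        "feeding_assay": gen_feeding_assay(cfg, n_assay),
        "bomb_calorimetry": gen_bomb_calorimetry(cfg, n_bomb),
        "composition": gen_composition(cfg),
    }
    paths = {}
    for name, df in tables.items():
        paths[name] = str(tio.write_table(df, out / f"{name}.csv"))
    return paths
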