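"""Assay arithmetic and the dry-mass composition budget.

Covers the per-cell bookkeeping around the scaling analysis: the two
cell-counting conversions (quantitative Western blot of histone H3 and
image-based nuclei/bead counting), the bead-based food-intake assay,
Q10 temperature normalisation of metabolic rates, the per-size-class
dry-mass composition budget, and the cross-species cell-number
extrapolation from Kleiber's law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .powerlaw import PowerLawResults

__all__ = ["BeadAssay", "MassBudget", "cells_from_h3",
           "cells_from_image_counts", "ingested_energy", "q10_adjust",
           "build_mass_budget", "allometry_contributions",
           "predict_cell_number", "LIVER_ENERGY_DENSITY_J_PER_UL"]

#: Energy density of calf-liver paste [J/ul].
LIVER_ENERGY_DENSITY_J_PER_UL = 6.15


class AssayError(ValueError):
    pass


def cells_from_h3(cells_loaded: float, volume_loaded_ul: float,
                  total_lysate_volume_ul: float) -> float:
    """Total cell number from a quantitative histone-H3 Western blot.

    ``N = cells_loaded / volume_loaded * total_lysate_volume`` — the
    cells-equivalent of the H3 band (read off the FACS-counted standard
    curve) scaled from the loaded aliquot to the whole lysate.
    """
    if cells_loaded <= 0 or volume_loaded_ul <= 0 or total_lysate_volume_ul <= 0:
        raise AssayError("all inputs must be > 0")
    return cells_loaded / volume_loaded_ul * total_lysate_volume_ul


def cells_from_image_counts(cells_counted: float, beads_counted: float,
                            total_beads: float) -> float:
    """Total cell number from imaged nuclei/bead co-counts.

    ``N = cells_counted / beads_counted * total_beads``: the beads are a
    volume tracer of known total number spiked into the macerate.
    """
    if beads_counted <= 0:
        raise AssayError("beads_counted must be > 0")
    if cells_counted < 0 or total_beads <= 0:
        raise AssayError("counts must be non-negative, total_beads > 0")
    return cells_counted / beads_counted * total_beads


@dataclass(frozen=True)
class BeadAssay:
    """Bead counts for one animal's food-intake measurement.

    Red beads are premixed into the liver paste at a known density;
    yellow-green beads spiked into the maceration solution normalise
    away drop-volume pipetting error. ``liver_volume_basis_ul`` is the
    volume of liver/bead mix dissociated for the calibration macerate
    (2 ul in the reference protocol).
    """

    red_beads_worm_drop: float
    red_beads_liver_drop: float
    green_beads_drop: float
    green_beads_reference: float
    macerate_volume_ul: float
    liver_macerate_volume_ul: float
    liver_volume_basis_ul: float = 2.0

    def __post_init__(self):
        if min(self.red_beads_worm_drop, self.green_beads_drop,
               self.green_beads_reference) < 0:
            raise AssayError("bead counts must be >= 0")
        if self.red_beads_liver_drop <= 0:
            raise AssayError("liver-drop red bead count must be > 0")
        if min(self.macerate_volume_ul, self.liver_macerate_volume_ul,
               self.liver_volume_basis_ul) <= 0:
            raise AssayError("volumes must be > 0")


def ingested_energy(assay: BeadAssay,
                    liver_energy_density: float = LIVER_ENERGY_DENSITY_J_PER_UL
                    ) -> tuple[float, float]:
    """Ingested liver volume (ul) and energy (J) from bead counts.

    total red beads per animal
        = red beads per 1 ul worm drop x macerate volume,
    red beads per 1 ul liver
        = (red beads per 1 ul liver drop / liver volume basis)
          x liver macerate volume,
    volume eaten = the ratio of the two, then normalised by the
    yellow-green drop-volume ratio (animal drop vs maceration-solution
    reference). Energy = volume x liver energy density (6.15 J/ul by
    default).
    """
    total_red_per_animal = assay.red_beads_worm_drop * assay.macerate_volume_ul
    red_per_ul_liver = (assay.red_beads_liver_drop / assay.liver_volume_basis_ul
                        * assay.liver_macerate_volume_ul)
    volume = total_red_per_animal / red_per_ul_liver
    volume /= assay.green_beads_drop / assay.green_beads_reference
    return float(volume), float(volume * liver_energy_density)


def q10_adjust(P, t_measured_c: float, t_target_c: float,
               q10: float = 2.0):
    """Temperature-normalise a metabolic rate: ``P' = P * Q10**(dT/10)``."""
    if q10 <= 0:
        raise AssayError("Q10 must be > 0")
    factor = q10 ** ((t_target_c - t_measured_c) / 10.0)
    out = np.asarray(P, dtype=float) * factor
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MassBudget:
    """Per-cell dry-mass composition across size classes.

    ``per_cell`` maps component -> {size_class: pg/cell} (means over
    replicates, with SEM alongside); ``residual_other`` is the
    independently measured total minus the sum of components and is
    flagged when more negative than 10% of the total.
    """

    size_classes: tuple[float, ...]
    components: tuple[str, ...]
    per_cell: dict
    sem: dict
    total_per_cell: dict
    residual_other: dict
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "size_classes_mm": list(self.size_classes),
            "components": list(self.components),
            "mass_per_cell_pg": {k: dict(v) for k, v in self.per_cell.items()},
            "sem_pg": {k: dict(v) for k, v in self.sem.items()},
            "total_dry_mass_per_cell_pg": dict(self.total_per_cell),
            "residual_other_pg": dict(self.residual_other),
            "flags": list(self.flags),
        }

    def fold_change(self, component: str, large: float | None = None,
                    small: float | None = None) -> float:
        """Mean per-cell mass ratio of the largest over the smallest class."""
        small = small if small is not None else min(self.size_classes)
        large = large if large is not None else max(self.size_classes)
        lo = self.per_cell[component][small]
        if lo <= 0:
            raise AssayError(f"zero {component} mass in the {small} mm class")
        return self.per_cell[component][large] / lo


def _cells_at_length(length_mm, n_vs_area: PowerLawResults,
                     length_area_law: PowerLawResults):
    """N(L) through the length->area and N/A scaling laws."""
    area = length_area_law.predict(np.asarray(length_mm, dtype=float))
    return n_vs_area.predict(area)


def build_mass_budget(composition: pd.DataFrame,
                      n_vs_area: PowerLawResults | None = None,
                      length_area_law: PowerLawResults | None = None
                      ) -> MassBudget:
    """Assemble the per-cell composition budget from a composition table.

    Rows with ``mass_per_animal_ug`` are normalised to pg/cell through
    the length->area and cell-number/area scaling laws (both required in
    that case); pre-normalised ``mass_per_cell_pg`` rows pass through.
    Every size class must include a ``total_dry_mass`` entry (measured
    independently of the components); the residual
    ``total - sum(components)`` is reported per class and flagged when
    below -10% of the total.
    """
    df = composition.copy()
    if "mass_per_cell_pg" not in df.columns:
        df["mass_per_cell_pg"] = np.nan
    need_norm = df["mass_per_cell_pg"].isna()
    if need_norm.any():
        if n_vs_area is None or length_area_law is None:
            raise AssayError("per-animal masses present: both scaling laws "
                             "are required for per-cell normalisation")
        ncells = _cells_at_length(df.loc[need_norm, "size_class_mm"],
                                  n_vs_area, length_area_law)
        df.loc[need_norm, "mass_per_cell_pg"] = (
            df.loc[need_norm, "mass_per_animal_ug"].to_numpy(dtype=float)
            * 1e6 / np.asarray(ncells))

    stats = (df.groupby(["component", "size_class_mm"])["mass_per_cell_pg"]
               .agg(["mean", "sem", "count"]))
    classes = tuple(sorted(df["size_class_mm"].unique()))
    comps = tuple(sorted(c for c in df["component"].unique()
                         if c != "total_dry_mass"))
    if "total_dry_mass" not in set(df["component"]):
        raise AssayError("composition table lacks total_dry_mass rows")
    per_cell: dict = {c: {} for c in comps}
    sem: dict = {c: {} for c in comps}
    total: dict = {}
    for sc in classes:
        try:
            total[sc] = float(stats.loc[("total_dry_mass", sc), "mean"])
        except KeyError:
            raise AssayError(f"size class {sc} mm lacks a total_dry_mass entry")
        for c in comps:
            try:
                per_cell[c][sc] = float(stats.loc[(c, sc), "mean"])
                s = stats.loc[(c, sc), "sem"]
                sem[c][sc] = float(s) if np.isfinite(s) else 0.0
            except KeyError:
                raise AssayError(f"size class {sc} mm lacks component {c!r}")
    residual = {sc: total[sc] - sum(per_cell[c][sc] for c in comps)
                for sc in classes}
    flags = tuple(f"residual in {sc} mm class is {residual[sc]:.3g} pg "
                  f"(< -10% of total)"
                  for sc in classes if residual[sc] < -0.10 * total[sc])
    return MassBudget(size_classes=classes, components=comps,
                      per_cell=per_cell, sem=sem, total_per_cell=total,
                      residual_other=residual, flags=flags)


def allometry_contributions(budget: MassBudget) -> dict:
    """Per-component share of the dry-mass-per-cell increase with size.

    For each component (plus the residual), the change in pg/cell
    between the smallest and largest size class, absolute and as a
    fraction of the change in total dry mass per cell. Fractions sum to
    1 once the residual is included.
    """
    if len(budget.size_classes) < 2:
        raise AssayError("need >= 2 size classes")
    lo, hi = min(budget.size_classes), max(budget.size_classes)
    d_total = budget.total_per_cell[hi] - budget.total_per_cell[lo]
    if d_total == 0:
        raise AssayError("total dry mass per cell identical across classes")
    out = {"size_classes_mm": (lo, hi), "delta_total_pg": float(d_total),
           "delta_pg": {}, "share": {}}
    for c in budget.components:
        d = budget.per_cell[c][hi] - budget.per_cell[c][lo]
        out["delta_pg"][c] = float(d)
        out["share"][c] = float(d / d_total)
    d_res = budget.residual_other[hi] - budget.residual_other[lo]
    out["delta_pg"]["residual_other"] = float(d_res)
    out["share"]["residual_other"] = float(d_res / d_total)
    return out


def predict_cell_number(body_mass_kg: float, kleiber_prefactor: float,
                        per_cell_rate_pw: float) -> dict:
    """Cell-number prediction from Kleiber's law and a per-cell rate.

    Assuming a size-independent metabolic rate per cell,
    ``N = a * M**(3/4) / p`` with the whole-organism rate
    ``P = a M^(3/4)`` [W] and ``p`` [pW/cell]. For a 70 kg human with
    P = 80 W, sweeping p over 0.4-1.3 pW spans roughly 6-20 x 10^13
    cells.
    """
    if min(body_mass_kg, kleiber_prefactor, per_cell_rate_pw) <= 0:
        raise AssayError("all inputs must be > 0")
    P = kleiber_prefactor * body_mass_kg ** 0.75
    N = P / (per_cell_rate_pw * 1e-12)
    return {"cells": float(N), "metabolic_rate_W": float(P),
            "assumptions": {"body_mass_kg": body_mass_kg,
                            "kleiber_prefactor_W_per_kg34": kleiber_prefactor,
                            "kleiber_exponent": 0.75,
                            "per_cell_rate_pW": per_cell_rate_pw}}
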