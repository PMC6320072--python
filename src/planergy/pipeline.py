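"""End-to-end analysis pipeline.

Stages, each skipped with an explicit report gap when its table is
missing:

1. direct power-law fits (wet~dry mass, N~area, dry mass~area,
   metabolic rate~dry mass);
2. derived fits by compose/invert/per-unit with error propagation
   (N~dry mass, N~wet mass, P~N, N~P, P/N~N, J/N~N, E/N~N);
3. windowed growth/degrowth rates from traces;
4. fits of the three energy-balance control paradigms, ranked by RSS;
5. physiological energy-per-cell prediction from the degrowth law and
   the assimilation ratio against the measured gross E/N law;
6. dry-mass composition budget and per-component allometry shares;
7. optional cross-species (human) cell-number extrapolation.

Every derived fit records its derivation chain, and the exponent
algebra (e.g. exponent(P/N~N) = exponent(P~N) - 1) is asserted on every
run.
"""

from __future__ import annotations

import hashlib
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .powerlaw import PowerLawResults, fit_power_law, compose, invert, per_unit
from .rates import Trace, windowed_rates, fit_rate_size_law, history_dependence
from .energy import (compare_paradigms, predict_energy_per_cell,
                     assimilation_ratio, PW_TO_J_PER_DAY)
from .assays import (BeadAssay, ingested_energy, build_mass_budget,
                     allometry_contributions, predict_cell_number)

__all__ = ["run_pipeline", "PipelineConfig"]

log = logging.getLogger("planergy.pipeline")

TABLE_FILES = {
    "animals": "animals.csv",
    "cohorts": "cohorts.csv",
    "traces": "traces.csv",
    "feeding_assay": "feeding_assay.csv",
    "bomb_calorimetry": "bomb_calorimetry.csv",
    "composition": "composition.csv",
}


class PipelineConfig:
    """Plain-dict pipeline configuration with defaults.

    Keys: ``method`` (fit method), ``feed_interval_days`` (meal spacing
    for converting intake energy to influx), ``p_per_cell_pw`` (fallback
    per-cell metabolic rate for the energy prediction),
    ``length_area_exponent``/``length_area_prefactor`` (the length-area
    law used by the composition budget, a config input),
    ``wet_mass_min_mg`` (optional x-threshold on the wet~dry fit),
    ``human_extrapolation`` (dict or None).
    """

    DEFAULTS = {
        "method": "robust_bisquare",
        "feed_interval_days": 7.0,
        "p_per_cell_pw": 1.0,
        "length_area_exponent": 1.8,
        "length_area_prefactor": 0.15,
        "wet_mass_min_mg": None,
        "liver_energy_density": 6.15,
        "n_growth_windows": 2,
        "n_degrowth_windows": 3,
        "human_extrapolation": None,
        "seed": 0,
    }

    def __init__(self, **overrides):
        unknown = set(overrides) - set(self.DEFAULTS)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        self.values = {**self.DEFAULTS, **overrides}

    def __getitem__(self, key):
        return self.values[key]

    def to_dict(self):
        return dict(self.values)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_tables(data_dir: Path) -> tuple[dict, dict, list[str]]:
    tables, hashes, gaps = {}, {}, []
    for schema, fname in TABLE_FILES.items():
        path = data_dir / fname
        if path.exists():
            tables[schema] = tio.read_table(path, schema)
            hashes[fname] = _sha256(path)
        else:
            gaps.append(f"table {fname} missing; dependent stages skipped")
    return tables, hashes, gaps


def _fit_col(df, xcol, ycol, method, x_min=None) -> PowerLawResults | None:
    sub = df[[xcol, ycol]].dropna()
    if len(sub) < 3:
        return None
    return fit_power_law(sub[xcol].to_numpy(), sub[ycol].to_numpy(),
                         method=method, x_min=x_min)


def _assert_algebra(fits: dict) -> None:
    """Exponent identities that must hold for derived fits."""
    def close(a, b):
        assert abs(a - b) < 1e-9, f"exponent algebra violated: {a} vs {b}"

    if "P~N" in fits and "P/N~N" in fits:
        close(fits["P/N~N"].exponent, fits["P~N"].exponent - 1.0)
    if all(k in fits for k in ("N~M_dry", "N~A", "M_dry~A")):
        close(fits["N~M_dry"].exponent,
              fits["N~A"].exponent / fits["M_dry~A"].exponent)


def run_pipeline(data_dir, config: PipelineConfig | dict | None = None) -> dict:
    """Run every analysis stage available from the tables in ``data_dir``.

    Returns the report bundle (a plain dict, serialisable with
    :func:`planergy.io.write_results`).
    """
    t_start = time.time()
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig(**config)
    method = config["method"]
    data_dir = Path(data_dir)
    tables, hashes, gaps = _load_tables(data_dir)

    fits: dict[str, PowerLawResults] = {}
    report: dict = {"fits": {}, "rates": None, "paradigms": None,
                    "energy_prediction": None, "budget": None,
                    "human_extrapolation": None, "gaps": gaps,
                    "provenance": {"config": config.to_dict(),
                                   "input_hashes": hashes}}

    # ---- stage 1: direct fits ---------------------------------------------
    stage_t = time.time()
    if "animals" in tables:
        an = tables["animals"]
        for name, (xc, yc) in {
            "N~A": ("plan_area_mm2", "cell_count"),
            "M_dry~A": ("plan_area_mm2", "dry_mass_mg"),
            "M_wet~M_dry": ("dry_mass_mg", "wet_mass_mg"),
        }.items():
            f = _fit_col(an, xc, yc, method)
            if f is not None:
                fits[name] = f
    if "cohorts" in tables:
        co = tables["cohorts"].dropna(subset=["heat_flow_uW",
                                              "pooled_dry_mass_mg"])
        per_heat = co["heat_flow_uW"] / co["n_animals"]
        per_dry = co["pooled_dry_mass_mg"] / co["n_animals"]
        fits["P~M_dry"] = fit_power_law(per_dry.to_numpy(),
                                        per_heat.to_numpy(), method=method)
    log.info("stage 1 (direct fits): %.2fs", time.time() - stage_t)

    # ---- stage 2: derived fits --------------------------------------------
    if all(k in fits for k in ("N~A", "M_dry~A")):
        fits["N~M_dry"] = compose(fits["N~A"], invert(fits["M_dry~A"]))
        if "M_wet~M_dry" in fits:
            fits["N~M_wet"] = compose(fits["N~M_dry"],
                                      invert(fits["M_wet~M_dry"]))
    if "P~M_dry" in fits and "N~M_dry" in fits:
        fits["P~N"] = compose(fits["P~M_dry"], invert(fits["N~M_dry"]))
        fits["N~P"] = invert(fits["P~N"])
        fits["P/N~N"] = per_unit(fits["P~N"])
        if "M_wet~M_dry" in fits:
            fits["P~M_wet"] = compose(fits["P~M_dry"],
                                      invert(fits["M_wet~M_dry"]))

    # ---- feeding assay: J/N ~ N -------------------------------------------
    if "feeding_assay" in tables and "N~A" in fits:
        fa = tables["feeding_assay"]
        vols, energies = [], []
        for _, row in fa.iterrows():
            assay = BeadAssay(
                red_beads_worm_drop=row["red_beads_worm_drop"],
                red_beads_liver_drop=row["red_beads_liver_drop"],
                green_beads_drop=row["green_beads_drop"],
                green_beads_reference=row["green_beads_reference"],
                macerate_volume_ul=row["macerate_volume_ul"],
                liver_macerate_volume_ul=row["liver_macerate_volume_ul"],
                liver_volume_basis_ul=row["liver_volume_basis_ul"])
            v, e = ingested_energy(assay, config["liver_energy_density"])
            vols.append(v)
            energies.append(e)
        n_cells = fits["N~A"].predict(fa["plan_area_mm2"].to_numpy())
        influx_pw = (np.asarray(energies) / config["feed_interval_days"]
                     / PW_TO_J_PER_DAY)  # J per interval -> pW
        keep = influx_pw > 0
        if keep.sum() >= 3:
            fits["J~N"] = fit_power_law(n_cells[keep], influx_pw[keep],
                                        method=method)
            fits["J/N~N"] = per_unit(fits["J~N"])
    elif "feeding_assay" in tables:
        gaps.append("feeding assay present but N~A law unavailable")

    # ---- bomb calorimetry: E/N ~ N ----------------------------------------
    bomb_n_range = None
    if "bomb_calorimetry" in tables and "N~M_dry" in fits:
        bc = tables["bomb_calorimetry"]
        per_dry = (bc["pooled_dry_mass_mg"] / bc["n_animals"]).to_numpy()
        per_E = (bc["energy_J"] / bc["n_animals"]).to_numpy()
        n_cells = fits["N~M_dry"].predict(per_dry)
        fits["E~N"] = fit_power_law(n_cells, per_E, method=method)
        fits["E/N~N"] = per_unit(fits["E~N"])
        bomb_n_range = (float(np.min(n_cells)), float(np.max(n_cells)))
    elif "bomb_calorimetry" in tables:
        gaps.append("bomb calorimetry present but N~M_dry law unavailable")

    _assert_algebra(fits)
    report["fits"] = {k: {**v.to_dict()} for k, v in fits.items()}

    # ---- stage 3: rates -----------------------------------------------------
    growth_pts, degrowth_pts = [], []
    if "traces" in tables and "N~A" in fits:
        stage_t = time.time()
        for tr in Trace.from_frame(tables["traces"]):
            n_win = (config["n_growth_windows"] if tr.regime == "growth"
                     else config["n_degrowth_windows"])
            pts = windowed_rates(tr, n_windows=n_win,
                                 n_vs_area=fits["N~A"])
            for pt in pts:
                if tr.regime == "growth" and pt.rate_pct_per_day > 0:
                    growth_pts.append(pt)
                elif tr.regime == "degrowth" and pt.rate_pct_per_day < 0:
                    degrowth_pts.append(pt)
        rates_section = {"n_growth_points": len(growth_pts),
                         "n_degrowth_points": len(degrowth_pts)}
        if len(growth_pts) >= 3:
            fits["|rate_growth|~N"] = fit_rate_size_law(growth_pts,
                                                        method=method)
            rates_section["growth_law"] = fits["|rate_growth|~N"].to_dict()
        if len(degrowth_pts) >= 3:
            fits["|rate_degrowth|~N"] = fit_rate_size_law(degrowth_pts,
                                                          method=method)
            rates_section["degrowth_law"] = fits["|rate_degrowth|~N"].to_dict()
            groups = {pt.history_group for pt in degrowth_pts}
            if len(groups) >= 2:
                rates_section["history_dependence"] = history_dependence(
                    degrowth_pts, seed=config["seed"])
        report["rates"] = rates_section
        report["fits"] = {k: v.to_dict() for k, v in fits.items()}
        log.info("stage 3 (rates): %.2fs", time.time() - stage_t)
    elif "traces" in tables:
        gaps.append("traces present but N~A law unavailable")

    # ---- stage 4: paradigm fits ---------------------------------------------
    best = None
    if growth_pts and degrowth_pts:
        stage_t = time.time()
        p_fixed = config["p_per_cell_pw"]
        if "P/N~N" in fits:
            # per-cell rate at the reference size, uW -> pW
            p_fixed = float(fits["P/N~N"].predict(1e6)) * 1e6
        ranked = compare_paradigms(growth_pts, degrowth_pts, p_fixed=p_fixed)
        best = ranked[0]
        report["paradigms"] = {
            "ranked": [r.to_dict() for r in ranked],
            "best": best.paradigm,
            "p_per_cell_pw": p_fixed,
        }
        log.info("stage 4 (paradigms): %.2fs", time.time() - stage_t)

    # ---- stage 5: energy prediction -----------------------------------------
    if "|rate_degrowth|~N" in fits:
        c = None
        if best is not None and best.paradigm == 3:
            c = best.params["c"]
        p_pw = report["paradigms"]["p_per_cell_pw"] if best is not None \
            else config["p_per_cell_pw"]
        e_law = predict_energy_per_cell(fits["|rate_degrowth|~N"], c=c,
                                        p=p_pw)
        section = {"e_per_cell_law": e_law.to_dict(), "p_per_cell_pw": p_pw}
        if "E/N~N" in fits and bomb_n_range is not None:
            section["assimilation_ratio"] = assimilation_ratio(
                fits["E/N~N"], e_law, n_range=bomb_n_range)
        report["energy_prediction"] = section

    # ---- stage 6: composition budget ----------------------------------------
    if "composition" in tables and "N~A" in fits:
        length_area = PowerLawResults(
            config["length_area_exponent"],
            math.log(config["length_area_prefactor"]),
            0.0, 0.0, 0.0, 3, "derived", derivation="config length-area law")
        budget = build_mass_budget(tables["composition"], fits["N~A"],
                                   length_area)
        report["budget"] = {
            **budget.to_dict(),
            "contributions": allometry_contributions(budget),
            "fold_changes": {c: budget.fold_change(c)
                             for c in budget.components},
        }
    elif "composition" in tables:
        gaps.append("composition present but N~A law unavailable")

    # ---- stage 7: optional human extrapolation ------------------------------
    if config["human_extrapolation"]:
        h = config["human_extrapolation"]
        report["human_extrapolation"] = predict_cell_number(
            h.get("body_mass_kg", 70.0),
            h.get("kleiber_prefactor", 80.0 / 70.0 ** 0.75),
            h.get("per_cell_rate_pw", 1.0))

    report["fits"] = {k: v.to_dict() for k, v in fits.items()}
    report["provenance"]["runtime_s"] = round(time.time() - t_start, 3)
    return report
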