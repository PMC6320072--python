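"""Measurement-table schemas, validation and result serialisation.

All input tables are UTF-8, comma-separated CSV with a required header
row, '.' decimals and '#' comment lines. Units are fixed per schema
(mm^2, mg, uW, pg/cell, days); optional fields are empty cells, never 0.

Schemas
-------
animals
    One row per animal (optionally per time point): plan area, length,
    dry/wet mass, cell count, feeding flag.
cohorts
    Microcalorimetry vials of size-matched animals: total heat flow
    (uW) and pooled dry mass (mg); per-animal values are totals / n.
traces
    Long-format growth/degrowth time courses of plan area.
feeding_assay
    Bead counts from the food-intake assay, per animal.
bomb_calorimetry
    Pooled combustion energies of size-matched cohorts.
composition
    Per-size-class biochemical component masses (per animal or
    pre-normalised per cell).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "TableValidationError",
           "read_table", "validate_table", "write_results", "read_results",
           "write_table", "COMPOSITION_COMPONENTS"]

COMPOSITION_COMPONENTS = frozenset({
    "TG", "glycogen", "other_lipids", "other_carbohydrates", "protein",
    "total_dry_mass",
})


class SchemaError(ValueError):
    """A table is structurally incompatible with its schema."""


class TableValidationError(ValueError):
    """Rows violate schema invariants; carries row-indexed diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("table validation failed:\n  " + "\n  ".join(problems))


# column spec: name -> (dtype, required, positivity)
#   positivity: ">0", ">=0" or None
_S = {
    "animals": {
        "animal_id": ("str", True, None),
        "time_days": ("float", False, ">=0"),
        "plan_area_mm2": ("float", False, ">0"),
        "length_mm": ("float", False, ">0"),
        "dry_mass_mg": ("float", False, ">0"),
        "wet_mass_mg": ("float", False, ">0"),
        "cell_count": ("float", False, ">0"),
        "fed": ("int", False, ">=0"),
    },
    "cohorts": {
        "vial_id": ("str", True, None),
        "n_animals": ("int", True, ">0"),
        "heat_flow_uW": ("float", True, ">0"),
        "pooled_dry_mass_mg": ("float", True, ">0"),
        "starved_weeks": ("float", False, ">=0"),
    },
    "traces": {
        "animal_id": ("str", True, None),
        "time_days": ("float", True, ">=0"),
        "plan_area_mm2": ("float", True, ">0"),
        "fed": ("int", False, ">=0"),
        "regime": ("str", False, None),
        "starved_weeks": ("float", False, ">=0"),
    },
    "feeding_assay": {
        "animal_id": ("str", True, None),
        "plan_area_mm2": ("float", True, ">0"),
        "red_beads_worm_drop": ("float", True, ">=0"),
        "green_beads_drop": ("float", True, ">0"),
        "green_beads_reference": ("float", True, ">0"),
        "macerate_volume_ul": ("float", True, ">0"),
        "red_beads_liver_drop": ("float", True, ">0"),
        "liver_macerate_volume_ul": ("float", True, ">0"),
        "liver_volume_basis_ul": ("float", True, ">0"),
        "starved_weeks": ("float", False, ">=0"),
    },
    "bomb_calorimetry": {
        "cohort_id": ("str", True, None),
        "n_animals": ("int", True, ">0"),
        "pooled_dry_mass_mg": ("float", True, ">0"),
        "energy_J": ("float", True, ">0"),
        "starved_weeks": ("float", False, ">=0"),
    },
    "composition": {
        "size_class_mm": ("float", True, ">0"),
        "component": ("str", True, None),
        "replicate_id": ("str", True, None),
        "mass_per_animal_ug": ("float", False, ">=0"),
        "mass_per_cell_pg": ("float", False, ">=0"),
    },
}

SCHEMAS = {name: dict(cols) for name, cols in _S.items()}


def _coerce(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    cols = SCHEMAS[schema]
    missing = [c for c, (_, req, _) in cols.items() if req and c not in df.columns]
    if missing:
        raise SchemaError(
            f"schema {schema!r}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in cols]
    if unknown:
        raise SchemaError(f"schema {schema!r}: unknown column(s) {unknown}")
    out = df.copy()
    for c in out.columns:
        dtype = cols[c][0]
        if dtype == "str":
            out[c] = out[c].astype("string")
        else:
            out[c] = pd.to_numeric(out[c], errors="coerce")
    return out


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Coerce ``df`` to ``schema`` and check every row invariant.

    Raises :class:`TableValidationError` listing each offending row
    (0-based data-row index) and the violated constraint.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; "
                          f"known: {sorted(SCHEMAS)}")
    df = _coerce(df, schema)
    cols = SCHEMAS[schema]
    problems: list[str] = []
    for c in df.columns:
        dtype, required, pos = cols[c]
        vals = df[c]
        if dtype != "str":
            bad_nan = vals.isna()
            if required and bad_nan.any():
                problems += [f"row {i}: {c} missing or non-numeric"
                             for i in np.flatnonzero(bad_nan.to_numpy())]
            if pos is not None:
                with np.errstate(invalid="ignore"):
                    if pos == ">0":
                        bad = (vals <= 0) & ~bad_nan
                        msg = "must be > 0"
                    else:
                        bad = (vals < 0) & ~bad_nan
                        msg = "must be >= 0"
                problems += [f"row {i}: {c} {msg} (got {vals.iloc[i]})"
                             for i in np.flatnonzero(bad.to_numpy())]
    if schema == "composition":
        bad = ~df["component"].isin(COMPOSITION_COMPONENTS)
        problems += [
            f"row {i}: component {df['component'].iloc[i]!r} not in "
            f"{sorted(COMPOSITION_COMPONENTS)}"
            for i in np.flatnonzero(bad.to_numpy())
        ]
        has_mass = pd.Series(False, index=df.index)
        for c in ("mass_per_animal_ug", "mass_per_cell_pg"):
            if c in df.columns:
                has_mass |= df[c].notna()
        problems += [f"row {i}: neither mass_per_animal_ug nor mass_per_cell_pg"
                     for i in np.flatnonzero((~has_mass).to_numpy())]
    if schema in ("animals", "traces") and "time_days" in df.columns:
        for aid, grp in df.groupby("animal_id", sort=False):
            t = grp["time_days"].to_numpy(dtype=float)
            t = t[~np.isnan(t)]
            if t.size and np.any(np.diff(t) < 0):
                problems.append(
                    f"animal {aid}: time_days must be non-decreasing")
    if problems:
        raise TableValidationError(problems)
    return df


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV/TSV measurement table and validate it against ``schema``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> Path:
    """Write a table as CSV (validating first when a schema is given)."""
    if schema is not None:
        df = validate_table(df, schema)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_results(report: dict, path) -> Path:
    """Serialise a pipeline result bundle to JSON with stable key order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_results(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
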