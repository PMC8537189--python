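"""Delimited-text I/O for study inputs and report outputs.

All tables are UTF-8 CSV with a header row, long format, one row per
physical measurement (one filter weighing replicate, one contact-angle
droplet).  Units are fixed by the schema — mg, m, m^2, L, mg/L, degrees,
days — and never auto-detected.

Input schemas
-------------
species.csv          species_id, binomial, life_form, leaf_habit
morphometrics.csv    species_id, lai, crown_diameter_m
batches.csv          batch_id, species_id, leaf_area_m2, n_leaves, exposure_days
weighings.csv        batch_id, wash_step, pore_um, replicate, tare_mg, loaded_mg
tds.csv              batch_id, wash_step, concentration_mg_per_l, volume_l
contact_angles.csv   species_id, liquid, replicate, angle_deg
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ReferentialError, SchemaError, ValidationError

LIFE_FORMS = ("tree", "shrub", "herb", "tree-dwelling")

SCHEMAS: dict[str, list[str]] = {
    "species": ["species_id", "binomial", "life_form", "leaf_habit"],
    "morphometrics": ["species_id", "lai", "crown_diameter_m"],
    "batches": ["batch_id", "species_id", "leaf_area_m2", "n_leaves", "exposure_days"],
    "weighings": ["batch_id", "wash_step", "pore_um", "replicate", "tare_mg", "loaded_mg"],
    "tds": ["batch_id", "wash_step", "concentration_mg_per_l", "volume_l"],
    "contact_angles": ["species_id", "liquid", "replicate", "angle_deg"],
}


@dataclass
class StudyBundle:
    """Validated study: metadata plus raw measurement tables."""

    species: pd.DataFrame
    morphometrics: pd.DataFrame
    batches: pd.DataFrame
    weighings: pd.DataFrame
    tds: pd.DataFrame
    contact_angles: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _load_table(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df[SCHEMAS[name]]


def read_study(input_dir: str | Path) -> StudyBundle:
    """Read and validate the six study tables from ``input_dir``.

    Raises :class:`SchemaError` for missing files/columns,
    :class:`ReferentialError` for measurement rows that do not join to a
    known batch or species, and :class:`ValidationError` for physically
    impossible values.
    """
    d = Path(input_dir)
    tables = {name: _load_table(d / f"{name}.csv", name) for name in SCHEMAS}
    bundle = StudyBundle(**tables)
    validate_bundle(bundle)
    return bundle


def validate_bundle(b: StudyBundle) -> None:
    """Referential and invariant checks across the six tables."""
    if b.species["species_id"].duplicated().any():
        dups = b.species.loc[b.species["species_id"].duplicated(), "species_id"]
        raise ValidationError(f"duplicate species_id: {sorted(set(dups))}")
    bad_lf = set(b.species["life_form"]) - set(LIFE_FORMS)
    if bad_lf:
        raise ValidationError(
            f"life_form must be one of {LIFE_FORMS}; got {sorted(bad_lf)}"
        )

    known_species = set(b.species["species_id"])
    known_batches = set(b.batches["batch_id"])

    for tab, col, known, what in [
        (b.morphometrics, "species_id", known_species, "morphometrics"),
        (b.batches, "species_id", known_species, "batches"),
        (b.weighings, "batch_id", known_batches, "weighings"),
        (b.tds, "batch_id", known_batches, "tds"),
        (b.contact_angles, "species_id", known_species, "contact_angles"),
    ]:
        orphans = sorted(set(tab[col]) - known)
        if orphans:
            raise ReferentialError(f"{what}.csv: unknown {col} {orphans}")

    if (b.morphometrics["lai"] <= 0).any():
        raise ValidationError("morphometrics.csv: lai must be > 0")
    if (b.morphometrics["crown_diameter_m"] <= 0).any():
        raise ValidationError("morphometrics.csv: crown_diameter_m must be > 0")
    if (b.batches["leaf_area_m2"] <= 0).any():
        raise ValidationError("batches.csv: leaf_area_m2 must be > 0")
    if (b.batches["exposure_days"] <= 0).any():
        raise ValidationError("batches.csv: exposure_days must be > 0")
    if (b.tds["volume_l"] <= 0).any():
        raise ValidationError("tds.csv: volume_l must be > 0")
    if (b.tds["concentration_mg_per_l"] < 0).any():
        raise ValidationError("tds.csv: concentration_mg_per_l must be >= 0")
    if ((b.contact_angles["angle_deg"] <= 0) | (b.contact_angles["angle_deg"] >= 180)).any():
        raise ValidationError("contact_angles.csv: angle_deg must be in (0, 180)")


def write_study(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Write the six study tables as CSV; inverse of :func:`read_study`."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        df.to_csv(d / f"{name}.csv", index=False, float_format="%.12g")


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    precision: int = 1,
    expected_species: list[str] | None = None,
) -> list[Path]:
    """Write result tables: one-decimal human CSVs plus full-precision companions.

    Each table ``name`` is written as ``name.csv`` (numbers rounded to
    ``precision`` decimals) and ``name_full.csv`` (full precision, the
    machine-readable companion).  Column order is preserved as given, so
    identical inputs yield byte-identical files.

    If ``expected_species`` is given, every table carrying a ``species_id``
    column must cover all of them; otherwise an error lists the missing
    species.
    """
    if not tables:
        raise ValidationError("empty result set: nothing to report")
    if expected_species is not None:
        for name, df in tables.items():
            cols = df.reset_index().columns if df.index.name else df.columns
            if "species_id" in cols:
                have = set(
                    df.reset_index()["species_id"]
                    if df.index.name == "species_id"
                    else df["species_id"]
                )
                missing = sorted(set(expected_species) - have)
                if missing:
                    raise ValidationError(
                        f"report table {name!r} missing species {missing}"
                    )

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        out = df.reset_index() if df.index.name else df.copy()
        human = out.copy()
        num = human.select_dtypes("number").columns
        human[num] = human[num].round(precision)
        p1 = d / f"{name}.csv"
        p2 = d / f"{name}_full.csv"
        human.to_csv(p1, index=False, float_format=f"%.{precision}f")
        out.to_csv(p2, index=False, float_format="%.12g")
        written += [p1, p2]
    return written
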