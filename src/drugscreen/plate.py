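"""Read, validate, and normalize 384-well plate viability tables.

Viability normalization is per plate: each well's raw luminescence is
divided by the mean raw luminescence of that plate's vehicle (DMSO) wells,
yielding relative CTG intensity (1 = vehicle-equivalent viability).  Values
above 1 are legitimate (growth stimulation) and are never clipped.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._exceptions import IntegrityError, NormalizationError, SchemaError
from .synthetic import BUFFER_COLS, BUFFER_ROWS

__all__ = [
    "REQUIRED_COLUMNS",
    "ROLES",
    "read_plate_table",
    "validate_layout",
    "normalize_plate",
]

REQUIRED_COLUMNS = (
    "plate_id", "row", "col", "cell_line", "compound", "dose_uM",
    "arm", "replicate", "raw_intensity", "role",
)
ROLES = frozenset({"treated", "vehicle", "buffer"})

EXPECTED_VEHICLE_WELLS = 18
EXPECTED_REPLICATES = 3


def _check_schema(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format plate CSV into a typed WellRecord table.

    Raises ``SchemaError`` for missing columns or unknown role tokens (the
    offending row numbers are reported) and ``IntegrityError`` for duplicate
    (plate_id, row, col) wells.
    """
    table = pd.read_csv(path)
    return check_plate_table(table)


def check_plate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and type an in-memory WellRecord table (see read_plate_table)."""
    _check_schema(table)
    table = table.copy()

    bad_roles = ~table["role"].isin(ROLES)
    if bad_roles.any():
        rows = [int(i) for i in table.index[bad_roles][:10]]
        raise SchemaError(
            f"unknown role token(s) at row(s) {rows}: "
            f"{sorted(table.loc[bad_roles, 'role'].unique())}"
        )

    table["col"] = table["col"].astype(int)
    table["replicate"] = table["replicate"].astype(int)
    table["dose_uM"] = table["dose_uM"].astype(float)
    table["raw_intensity"] = table["raw_intensity"].astype(float)

    if (table["raw_intensity"] < 0).any():
        raise IntegrityError("negative raw intensities are not valid luminescence")
    dup = table.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        keys = table.loc[dup, ["plate_id", "row", "col"]].head(5).to_records(index=False)
        raise IntegrityError(f"duplicate wells: {list(keys)}")
    return table


def validate_layout(table: pd.DataFrame, strict: bool = False) -> dict:
    """Check each plate against the screening design.

    Per plate the report records the vehicle-well count (expected 18),
    breaches of the unseeded two-well buffer ring (rows A, B, O, P and
    columns 1, 2, 23, 24 must carry role ``buffer``), and incomplete
    triplicates per compound x dose x arm.  ``strict=True`` raises
    ``IntegrityError`` when any violation is found.
    """
    _check_schema(table)
    report: dict = {"plates": {}, "violations": []}

    for plate_id, plate in table.groupby("plate_id", sort=True):
        n_vehicle = int((plate["role"] == "vehicle").sum())
        entry = {"vehicle_count": n_vehicle, "violations": []}

        if n_vehicle != EXPECTED_VEHICLE_WELLS:
            entry["violations"].append(
                {"code": "vehicle_count",
                 "detail": f"expected {EXPECTED_VEHICLE_WELLS} vehicle wells, found {n_vehicle}"}
            )

        ring = plate["row"].isin(BUFFER_ROWS) | plate["col"].isin(BUFFER_COLS)
        breach = plate.loc[ring & (plate["role"] != "buffer")]
        for _, well in breach.iterrows():
            entry["violations"].append(
                {"code": "buffer_breach",
                 "detail": f"non-buffer well at {well['row']}{well['col']} (role={well['role']})"}
            )

        treated = plate[plate["role"] == "treated"]
        if len(treated):
            counts = treated.groupby(["compound", "dose_uM", "arm"]).size()
            for key, n in counts.items():
                if n != EXPECTED_REPLICATES:
                    entry["violations"].append(
                        {"code": "replicate_incomplete",
                         "detail": f"{key[0]} at {key[1]} µM ({key[2]}): {n} replicates"}
                    )

        report["plates"][plate_id] = entry
        for v in entry["violations"]:
            report["violations"].append({"plate_id": plate_id, **v})

    report["n_violations"] = len(report["violations"])
    if strict and report["n_violations"]:
        raise IntegrityError(
            f"layout validation failed with {report['n_violations']} violation(s); "
            f"first: {report['violations'][0]}"
        )
    return report


def normalize_plate(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plate vehicle-mean normalization to relative CTG intensity.

    Adds a ``relative_ctg`` column (raw intensity / mean vehicle raw
    intensity on the same plate) and drops buffer wells from the output.
    Raises ``NormalizationError`` for plates without a usable (positive
    mean) vehicle set.
    """
    _check_schema(table)
    out = []
    for plate_id, plate in table.groupby("plate_id", sort=False):
        vehicle = plate.loc[plate["role"] == "vehicle", "raw_intensity"]
        if vehicle.empty:
            raise NormalizationError(f"plate {plate_id!r} has no vehicle wells")
        vmean = float(vehicle.mean())
        if not vmean > 0:
            raise NormalizationError(
                f"plate {plate_id!r} vehicle mean is not positive ({vmean})"
            )
        plate = plate.loc[plate["role"] != "buffer"].copy()
        plate["relative_ctg"] = plate["raw_intensity"] / vmean
        out.append(plate)
    return pd.concat(out, ignore_index=True)
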