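"""Schema-validated TSV/CSV readers and writers.

Canonical format is TSV (CSV accepted), UTF-8, '.' decimal separator,
header row required.  Units are embedded in column names (``_um`` for μm).
Validation failures raise :class:`SchemaError` naming the file, row
(1-based data row as it appears in the file, header = line 1) and column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .photoreceptors import SectionRecord
from .rpe import RPETrace


class SchemaError(ValueError):
    """A table violated its schema (missing column, bad value, duplicate key)."""


@dataclass(frozen=True)
class Column:
    name: str
    kind: str  # "str" | "float" | "int"
    minimum: float | None = None
    strict_min: bool = False
    required: bool = True


SCHEMAS: dict[str, dict] = {
    "sections": {
        "columns": [
            Column("animal_id", "str"),
            Column("region", "str"),
            Column("section_id", "str"),
            Column("width_um", "float", minimum=0, strict_min=True),
            Column("thickness_um", "float", minimum=0, strict_min=True),
            Column("cone_count", "float", minimum=0),
            Column("onl_rows", "float", minimum=0),
            Column("nucleus_diameter_um", "float", minimum=0, strict_min=True),
            Column("os_length_um", "float", minimum=0),
            Column("rpe_height_um", "float", minimum=0),
            Column("phagosome_count", "float", minimum=0),
            Column("rpe_cell_count", "float", minimum=0),
        ],
        "key": ["animal_id", "region", "section_id"],
    },
    "traces": {
        "columns": [
            Column("animal_id", "str"),
            Column("region", "str"),
            Column("trace_id", "str"),
            Column("segment_length_um", "float", minimum=0, strict_min=True),
            Column("position_um", "float", minimum=0),
        ],
        "key": None,
    },
    "groups": {
        "columns": [Column("sample_id", "str"), Column("group", "str")],
        "key": ["sample_id"],
    },
}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)


def validate_and_load(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Load and validate a table against a named schema.

    Returns a typed DataFrame.  The proteins matrix has a variable column
    set and is handled by :func:`load_protein_matrix` instead.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    raw = _read_table(path)
    missing = [c.name for c in schema["columns"] if c.required and c.name not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    out = pd.DataFrame(index=raw.index)
    for col in schema["columns"]:
        if col.name not in raw.columns:
            continue
        series = raw[col.name]
        if col.kind == "str":
            out[col.name] = series.astype(str)
            continue
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() & series.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {series[row]!r} in column "
                f"{col.name!r} at data row {row + 1} (file line {row + 2})"
            )
        if col.minimum is not None:
            viol = (numeric <= col.minimum) if col.strict_min else (numeric < col.minimum)
            viol &= numeric.notna()
            if viol.any():
                row = int(viol.idxmax())
                op = ">" if col.strict_min else ">="
                raise SchemaError(
                    f"{path}: column {col.name!r} must be {op} {col.minimum:g}, "
                    f"got {numeric[row]:g} at data row {row + 1} (file line {row + 2})"
                )
        out[col.name] = numeric.astype(float)

    key = schema.get("key")
    if key:
        dup = out[key].duplicated()
        if dup.any():
            row = int(dup.idxmax())
            raise SchemaError(
                f"{path}: duplicated key {tuple(out.loc[row, key])} on "
                f"{key} at data row {row + 1} (file line {row + 2})"
            )
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a TSV with full numeric precision (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def sections_from_table(
    df: pd.DataFrame, known_regions: Sequence[str] | None = None
) -> list[SectionRecord]:
    """Convert a validated sections table into records."""
    records = []
    for i, row in df.iterrows():
        if known_regions is not None and row["region"] not in known_regions:
            raise SchemaError(
                f"unknown region label {row['region']!r} at data row {int(i) + 1}; "
                f"known regions: {list(known_regions)}"
            )
        records.append(
            SectionRecord(
                animal_id=row["animal_id"],
                region=row["region"],
                section_id=row.get("section_id", ""),
                width=row["width_um"],
                thickness=row["thickness_um"],
                cone_count=row["cone_count"],
                onl_rows=row["onl_rows"],
                nucleus_diameter=row["nucleus_diameter_um"],
                os_length=row["os_length_um"],
                rpe_height=row["rpe_height_um"],
                phagosome_count=row["phagosome_count"],
                rpe_cell_count=row["rpe_cell_count"],
            )
        )
    return records


def traces_from_table(df: pd.DataFrame) -> list[RPETrace]:
    """Convert a validated long-format trace table into RPETrace objects."""
    traces = []
    group_cols = ["animal_id", "region", "trace_id"]
    for (animal, region, _), grp in df.groupby(group_cols, sort=True):
        seg = float(grp["segment_length_um"].iloc[0])
        positions = np.sort(grp["position_um"].to_numpy(dtype=float))
        traces.append(
            RPETrace(animal_id=animal, region=region, positions=positions, segment_length=seg)
        )
    return traces


def load_protein_matrix(matrix_path: str | Path, groups_path: str | Path):
    """Read proteins.tsv (first column = protein id, empty cell = missing)
    and the sample → group mapping; returns a raw-scale ProteinMatrix."""
    from .proteomics import ProteinMatrix

    mpath = Path(matrix_path)
    if not mpath.exists():
        raise SchemaError(f"{mpath}: file not found")
    sep = "," if mpath.suffix.lower() == ".csv" else "\t"
    matrix = pd.read_csv(mpath, sep=sep)
    if matrix.shape[1] < 3:
        raise SchemaError(f"{mpath}: expected a protein id column plus >= 2 samples")
    groups = validate_and_load(groups_path, "groups")
    return ProteinMatrix.from_tables(matrix, groups)
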