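"""Readers and writers for the tidy TSV exchange schemas.

Dialect: UTF-8, tab-separated, one header row, long format, decimal point
".", missing value encoded as an empty cell.  ``read_table(write_table(t))``
is an exact round trip for every table type, including "/" in taxon labels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .model import (
    AbundanceMatrix,
    CulturomicsTable,
    DesignThresholds,
    GeneContentMatrix,
    PathwayMap,
    PeakTable,
    PersistenceLog,
    VocConfig,
    VOCTable,
)

Table = Union[
    CulturomicsTable,
    AbundanceMatrix,
    GeneContentMatrix,
    PathwayMap,
    VOCTable,
    PeakTable,
    PersistenceLog,
]

# schema name -> (class, {column: kind}); kinds: str, int, float, bool
SCHEMAS: dict[str, tuple[type, dict[str, str]]] = {
    "culturomics": (
        CulturomicsTable,
        {
            "sample": "str",
            "taxon": "str",
            "guild": "str",
            "isolate_count": "int",
            "cell_density": "float",
        },
    ),
    "abundance": (
        AbundanceMatrix,
        {"sample": "str", "taxon": "str", "rel_abundance_pct": "float"},
    ),
    "gene_content": (
        GeneContentMatrix,
        {
            "taxon": "str",
            "sample": "str",
            "function_id": "str",
            "copy_number": "int",
            "tpm": "float",
            "phase": "str",
        },
    ),
    "pathways": (
        PathwayMap,
        {
            "pathway": "str",
            "mega_pathway": "str",
            "function_id": "str",
            "is_key": "bool",
        },
    ),
    "voc": (
        VOCTable,
        {
            "community": "str",
            "timepoint": "str",
            "replicate": "str",
            "compound": "str",
            "chem_class": "str",
            "concentration": "float",
        },
    ),
    "peaks": (
        PeakTable,
        {
            "compound": "str",
            "retention_time": "float",
            "peak_area": "float",
            "spectral_match": "float",
        },
    ),
    "persistence": (
        PersistenceLog,
        {"day": "int", "member": "str", "detected": "bool", "dilution": "float"},
    ),
}

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}

# float-kind columns where NaN means "not recorded", not an error
_NULLABLE = {("culturomics", "cell_density"), ("persistence", "dilution"), ("gene_content", "phase")}


def _coerce_column(raw: pd.Series, kind: str, schema: str, col: str) -> pd.Series:
    nullable = (schema, col) in _NULLABLE
    if kind == "str":
        s = raw.astype("string")
        if nullable:
            return s.astype(object).where(~s.isna(), np.nan)
        if s.isna().any():
            row = int(s.isna().idxmax())
            raise ParseError(f"{schema}.{col}: empty cell at row {row}")
        return s.astype(object)
    if kind == "bool":
        out = []
        for i, v in enumerate(raw):
            token = str(v).strip().lower()
            if token in _TRUE:
                out.append(True)
            elif token in _FALSE:
                out.append(False)
            else:
                raise ParseError(f"{schema}.{col}: non-boolean cell {v!r} at row {i}")
        return pd.Series(out, index=raw.index, dtype=bool)
    # numeric kinds
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        raise ParseError(f"{schema}.{col}: non-numeric cell {raw[row]!r} at row {row}")
    if kind == "int":
        if num.isna().any():
            row = int(num.isna().idxmax())
            raise ParseError(f"{schema}.{col}: missing integer at row {row}")
        if not np.allclose(num, np.round(num)):
            raise ParseError(f"{schema}.{col}: non-integral value present")
        return num.astype(np.int64)
    if not nullable and num.isna().any():
        row = int(num.isna().idxmax())
        raise ParseError(f"{schema}.{col}: missing value at row {row}")
    return num.astype(float)


def read_table(path: Union[str, Path], schema_name: str) -> Table:
    """Read and validate a TSV file against the named schema.

    Raises :class:`SchemaError` for missing/unknown columns,
    :class:`ParseError` for unparseable cells (with the row index), and
    :class:`~fermentome.errors.ValidationError` when a domain invariant
    fails.  A header-only file yields an empty, valid table.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema_name!r}; expected one of {sorted(SCHEMAS)}"
        )
    cls, columns = SCHEMAS[schema_name]
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})
    missing = [c for c in columns if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in raw.columns if c not in columns]
    if extra:
        raise SchemaError(f"{path.name}: unexpected column(s) {extra}")
    data = {
        col: _coerce_column(raw[col], kind, schema_name, col)
        for col, kind in columns.items()
    }
    return cls(pd.DataFrame(data))


def _format_cell(v, kind: str) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if kind == "bool":
        return "true" if v else "false"
    if kind == "float":
        return repr(float(v))
    if kind == "int":
        return str(int(v))
    return str(v)


def write_table(table: Table, path: Union[str, Path]) -> Path:
    """Write a validated table as TSV; exact round trip with read_table.

    Floats are written with ``repr`` so the binary value survives the trip.
    """
    schema_name = next(n for n, (cls, _) in SCHEMAS.items() if isinstance(table, cls))
    _, columns = SCHEMAS[schema_name]
    path = Path(path)
    lines = ["\t".join(columns)]
    for _, row in table.df.iterrows():
        lines.append(
            "\t".join(_format_cell(row[c], kind) for c, kind in columns.items())
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_config(path: Union[str, Path]) -> tuple[DesignThresholds, VocConfig]:
    """Load thresholds + VOC constants from one JSON file.

    Keys ``design`` and ``voc`` are each optional; omitted sections fall
    back to package defaults.
    """
    blob = json.loads(Path(path).read_text(encoding="utf-8"))
    return (
        DesignThresholds(**blob.get("design", {})),
        VocConfig(**blob.get("voc", {})),
    )


def write_config(
    thresholds: DesignThresholds, voc: VocConfig, path: Union[str, Path]
) -> Path:
    path = Path(path)
    payload = {"design": thresholds.model_dump(), "voc": voc.model_dump()}
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path
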