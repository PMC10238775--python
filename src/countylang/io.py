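"""Validated table I/O shared by all stages.

All CSVs are UTF-8, comma-delimited with a header row and '.' decimals;
token/user tables are TSV.  County identifiers are zero-padded 5-character
strings (FIPS convention) everywhere, and are always read as strings so
spreadsheet-style integer mangling cannot occur.  Validation collects every
offending row/column before raising, not just the first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """Raised with the full list of validation problems."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        super().__init__(f"{path}: " + "; ".join(problems))


@dataclass
class TableSchema:
    """Column names/types, key columns, and allowed numeric ranges."""

    columns: dict[str, str]                       # name -> {str,int,float}
    key: list[str] = field(default_factory=list)
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    sep: str = ","
    allow_extra: bool = True


TOKENS_SCHEMA = TableSchema(
    columns={"user_id": "str", "county_id": "str", "year": "int", "word": "str", "count": "int"},
    ranges={"count": (0, np.inf)},
    sep="\t",
)
USERS_SCHEMA = TableSchema(
    columns={"user_id": "str", "county_id": "str", "year": "int", "tweet_count": "int"},
    key=["user_id", "year"],
    ranges={"tweet_count": (1, np.inf)},
    sep="\t",
)
LEXICON_SCHEMA = TableSchema(
    columns={"term": "str", "topic": "int", "weight": "float"},
    ranges={"weight": (0, np.inf)},
)
COUNTY_TABLE_SCHEMA = TableSchema(
    columns={
        "county_id": "str",
        "mortality_rate": "float",
        "death_count": "int",
        "population": "int",
        "n_reports": "int",
    },
    key=["county_id"],
    ranges={
        "mortality_rate": (0, np.inf),
        "death_count": (0, np.inf),
        "population": (1, np.inf),
        "n_reports": (0, np.inf),
    },
)
WORD_FREQ_SCHEMA = TableSchema(
    columns={"county_id": "str", "word": "str", "freq": "float"},
    ranges={"freq": (0.0, 1.0)},
)
LOADINGS_SCHEMA = TableSchema(
    columns={"county_id": "str", "topic": "int", "loading": "float"},
    key=["county_id", "topic"],
    ranges={"loading": (0, np.inf)},
)

_DTYPES = {"str": "object", "int": "int64", "float": "float64"}


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a delimited text table against ``schema``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    str_cols = [c for c, t in schema.columns.items() if t == "str"]
    table = pd.read_csv(path, sep=schema.sep, dtype={c: str for c in str_cols})
    problems: list[str] = []
    missing = [c for c in schema.columns if c not in table.columns]
    if missing:
        raise SchemaError(path, [f"missing columns: {missing}"])
    for col, kind in schema.columns.items():
        if kind == "str":
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna() & table[col].notna()]
        if len(bad):
            problems.append(f"column {col!r}: non-{kind} values at rows {list(bad[:20])}")
            continue
        if kind == "int" and not np.allclose(coerced.dropna() % 1, 0):
            frac = table.index[(coerced % 1 != 0).fillna(False)]
            problems.append(f"column {col!r}: non-integer values at rows {list(frac[:20])}")
        table[col] = coerced.astype(_DTYPES[kind])
    for col, (lo, hi) in schema.ranges.items():
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[(vals < lo) | (vals > hi)]
        if len(bad):
            problems.append(
                f"column {col!r}: {len(bad)} values outside [{lo}, {hi}] at rows {list(bad[:20])}"
            )
    if schema.key:
        dup = table.duplicated(subset=schema.key, keep=False)
        if dup.any():
            keys = table.loc[dup, schema.key].astype(str).agg("/".join, axis=1).unique()
            problems.append(f"duplicate keys on {schema.key}: {list(keys[:20])}")
    if problems:
        raise SchemaError(path, problems)
    return table


def write_table(table: pd.DataFrame, path: str | Path, sep: str = ",", index: bool = False) -> None:
    """Deterministic delimited-text writer (fixed float formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=sep, index=index, float_format=FLOAT_FORMAT)


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, no timestamps)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
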