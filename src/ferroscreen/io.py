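"""TSV readers and writers with schema validation.

All tables are tab-separated with a header row, UTF-8, "." decimals, empty
cell = missing.  Readers validate column presence and dtypes and convert
empty cells to explicit missing values; writers round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crispr_screen import ScreenCountTable
from .lipidomics import LipidAbundanceTable, parse_annotation
from .selectivity import SensitivityMatrix

__all__ = [
    "TableSchema",
    "read_table",
    "write_table",
    "load_screen_counts",
    "write_screen_counts",
    "load_lipid_table",
    "write_lipid_table",
    "load_sensitivity_matrix",
    "write_sensitivity_matrix",
]


@dataclass(frozen=True)
class TableSchema:
    """Declarative TSV schema: required columns and their kinds.

    ``columns`` maps a column name to "str" or "num".  ``extra_numeric``
    means any column not named in ``columns`` must parse as numeric
    (sample columns of a measurement matrix).
    """

    columns: dict = field(default_factory=dict)
    extra_numeric: bool = False
    min_extra: int = 0


def read_table(path, schema: TableSchema | None = None, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a delimited table.

    Raises a clear error naming the first missing column, or the row number
    of the first non-numeric cell in a numeric column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if schema is None:
        return df
    for col, kind in schema.columns.items():
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in schema.columns]
    if len(extra) < schema.min_extra:
        raise ValueError(
            f"{path.name}: expected at least {schema.min_extra} data column(s), "
            f"found {len(extra)}"
        )
    numeric_cols = [c for c, k in schema.columns.items() if k == "num"]
    if schema.extra_numeric:
        numeric_cols += extra
    out = df.copy()
    for col in numeric_cols:
        cell = df[col].replace("", np.nan)
        parsed = pd.to_numeric(cell, errors="coerce")
        bad = parsed.isna() & cell.notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, data row {row + 1}"
            )
        out[col] = parsed
    return out


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Screen counts
# ---------------------------------------------------------------------------

def load_screen_counts(counts_path, meta_path) -> ScreenCountTable:
    """Load an sgRNA count TSV plus its sample-metadata TSV.

    Counts: columns ``sgrna_id``, ``gene_id`` then one integer column per
    sample.  Metadata: columns ``sample``, ``condition`` (and optionally
    ``timepoint``).
    """
    counts = read_table(
        counts_path,
        TableSchema({"sgrna_id": "str", "gene_id": "str"},
                    extra_numeric=True, min_extra=1),
    )
    meta = read_table(
        meta_path, TableSchema({"sample": "str", "condition": "str"})
    )
    sample_cols = [c for c in counts.columns if c not in ("sgrna_id", "gene_id")]
    conditions = dict(zip(meta["sample"], meta["condition"]))
    missing = set(sample_cols) - set(conditions)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    mat = counts[sample_cols].astype(float).round().astype(int)
    mat.index = counts["sgrna_id"]
    return ScreenCountTable(
        counts=mat,
        gene_map=pd.Series(counts["gene_id"].values, index=counts["sgrna_id"].values),
        sample_conditions={s: conditions[s] for s in sample_cols},
    )


def write_screen_counts(table: ScreenCountTable, counts_path, meta_path) -> None:
    df = table.counts.copy()
    df.insert(0, "gene_id", table.gene_map.reindex(df.index).values)
    df.insert(0, "sgrna_id", df.index)
    write_table(df, counts_path)
    meta = pd.DataFrame(
        {"sample": list(table.sample_conditions),
         "condition": list(table.sample_conditions.values())}
    )
    write_table(meta, meta_path)


# ---------------------------------------------------------------------------
# Lipid tables
# ---------------------------------------------------------------------------

def load_lipid_table(table_path, meta_path, reference_group: str) -> LipidAbundanceTable:
    """Load a lipid abundance TSV (``annotation`` + sample columns) and its
    ``sample``/``group`` metadata."""
    df = read_table(
        table_path,
        TableSchema({"annotation": "str"}, extra_numeric=True, min_extra=2),
    )
    meta = read_table(meta_path, TableSchema({"sample": "str", "group": "str"}))
    sample_cols = [c for c in df.columns if c != "annotation"]
    groups = dict(zip(meta["sample"], meta["group"]))
    missing = set(sample_cols) - set(groups)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    species = [parse_annotation(a) for a in df["annotation"]]
    mat = df[sample_cols].astype(float)
    mat.index = df["annotation"]
    return LipidAbundanceTable(
        species=species,
        abundances=mat,
        sample_groups={s: groups[s] for s in sample_cols},
        reference_group=reference_group,
    )


def write_lipid_table(table: LipidAbundanceTable, table_path, meta_path) -> None:
    df = table.abundances.copy()
    df.insert(0, "annotation", [sp.annotation for sp in table.species])
    write_table(df, table_path)
    meta = pd.DataFrame(
        {"sample": list(table.sample_groups),
         "group": list(table.sample_groups.values())}
    )
    write_table(meta, meta_path)


# ---------------------------------------------------------------------------
# Sensitivity matrices (long format)
# ---------------------------------------------------------------------------

_SENS_SCHEMA = TableSchema(
    {"cell_line": "str", "lineage": "str", "is_ccc": "str",
     "compound": "str", "auc": "num"}
)


def load_sensitivity_matrix(path) -> SensitivityMatrix:
    """Load a long-format sensitivity TSV:
    ``cell_line``, ``lineage``, ``is_ccc``, ``compound``, ``auc``."""
    df = read_table(path, _SENS_SCHEMA)
    wide = df.pivot_table(index="cell_line", columns="compound", values="auc",
                          aggfunc="first")
    lineages = dict(zip(df["cell_line"], df["lineage"]))
    flag_of = {
        cl: str(v).strip().lower() in ("1", "true", "yes")
        for cl, v in zip(df["cell_line"], df["is_ccc"])
    }
    return SensitivityMatrix(
        auc=wide,
        lineages={cl: lineages[cl] for cl in wide.index},
        group_flags={cl: flag_of[cl] for cl in wide.index},
    )


def write_sensitivity_matrix(matrix: SensitivityMatrix, path) -> None:
    rows = []
    for cl in matrix.auc.index:
        for cpd in matrix.auc.columns:
            v = matrix.auc.at[cl, cpd]
            rows.append(
                {
                    "cell_line": cl,
                    "lineage": matrix.lineages[cl],
                    "is_ccc": str(bool(matrix.group_flags.get(cl, False))).lower(),
                    "compound": cpd,
                    "auc": "" if pd.isna(v) else v,
                }
            )
    write_table(pd.DataFrame(rows), path)
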