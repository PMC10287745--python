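"""Readers and writers for the on-disk text formats.

Expression matrices are TSV/CSV with genes as rows and samples as columns;
the first column holds gene ids and the header row holds sample ids.
Clinical tables are TSV/CSV with a ``sample_id`` column plus ``bcr`` (0/1),
``dfs_months`` and optionally ``psa``, ``gleason``, ``age``, ``stage``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import BinsigError, ClinicalTable, ExpressionMatrix


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, scale: str = "raw") -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise BinsigError(f"non-numeric expression values in {path}: {exc}") from exc
    return ExpressionMatrix(df, scale=scale)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep=_sep(path), index_label="gene_id")


def read_clinical(path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if "sample_id" not in df.columns:
        raise BinsigError(f"{path} has no sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep(path), index_label="sample_id")
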