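"""Readers and writers for the pipeline's on-disk formats.

Everything is tab-separated text: an expression TSV (probe id first
column, one column per sample), a sample sheet, a probe annotation table,
and standard GMT gene-set files.  TSV rather than CSV because gene
descriptions routinely contain commas.

Writers and readers are inverse up to float formatting: values are
written with six decimal places.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    SAMPLE_COLUMNS,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PlatformAnnotation,
)
from .exceptions import DataError, ParseError

FLOAT_FORMAT = "%.6f"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path, samples_path=None, platform: str = "APlus2"
) -> ExpressionMatrix:
    """Read an expression TSV (and optionally a sample sheet).

    Raises :class:`ParseError` with a line number for ragged rows,
    non-numeric cells, and duplicate probe or sample ids.
    """
    matrix_path = Path(matrix_path)
    with open(matrix_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty expression file", matrix_path, 1) from None
        sample_ids = header[1:]
        dupes = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()]
        if len(dupes):
            raise ParseError(
                f"duplicate sample column {dupes[0]!r}", matrix_path, 1
            )
        probes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0]):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, found {len(row)}",
                    matrix_path,
                    lineno,
                )
            if row[0] in seen:
                raise ParseError(f"duplicate probe id {row[0]!r}", matrix_path, lineno)
            seen.add(row[0])
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise ParseError(f"non-numeric cell ({exc})", matrix_path, lineno)
            probes.append(row[0])
    values = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(probes), len(sample_ids)),
        index=pd.Index(probes, name="probe_id"),
        columns=sample_ids,
    )
    if samples_path is not None:
        samples = read_sample_sheet(samples_path)
    else:
        samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values, samples, platform=platform)


def write_expression(matrix: ExpressionMatrix, matrix_path, samples_path=None) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT)
    if samples_path is not None:
        write_sample_sheet(matrix.samples, samples_path)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in sheet.columns:
        raise ParseError("sample sheet lacks a 'sample_id' column", path, 1)
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"duplicate sample id {dup!r}", path)
    sheet = sheet.set_index("sample_id")
    for col in SAMPLE_COLUMNS:
        if col not in sheet.columns:
            sheet[col] = ""
    return sheet[list(SAMPLE_COLUMNS)]


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path) -> PlatformAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"probe_id", "gene_id", "symbol", "platforms"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"annotation lacks columns {sorted(missing)}", path, 1)
    if table["probe_id"].duplicated().any():
        dup = table["probe_id"][table["probe_id"].duplicated()].iloc[0]
        raise ParseError(f"duplicate probe id {dup!r}", path)
    return PlatformAnnotation(table.set_index("probe_id"))


def write_annotation(annotation: PlatformAnnotation, path) -> None:
    out = annotation.table.copy()
    out["platforms"] = out["platforms"].map(lambda p: ",".join(sorted(p)))
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name TAB description TAB members."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} fields, need >= 3", path, lineno
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"gene set {name!r} is empty", path, lineno)
            try:
                coll.add(GeneSet(name, description, tuple(members)))
            except DataError as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")
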