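"""Reading and writing the delimited-text formats.

Outcome tables and label tables are plain TSV/CSV with a header; the
response matrix is stored either as a wide TSV (rows = compounds, first
column ``compound_id``, one column per assay, cells in {1,-1,0}) or as a
sparse long TSV (``compound_id, assay_id, value``) in which 0 cells may be
omitted.  All writers accept an optional comment header of ``# key: value``
lines; readers skip ``#`` lines.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    Outcome,
    OutcomeRecord,
    ResponseMatrix,
    ToxicityLabels,
    classify_ld50,
)

__all__ = [
    "FormatError",
    "read_outcomes",
    "read_labels",
    "write_labels",
    "write_matrix",
    "read_matrix",
    "write_matrix_long",
    "read_matrix_long",
    "write_table",
]


class FormatError(ValueError):
    """A file does not match the documented layout."""


def _delimiter(path: Path, dialect: str | None) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def _require_columns(header: Sequence[str], required: Sequence[str], path: Path) -> None:
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_outcomes(path: str | Path, dialect: str | None = None) -> list[OutcomeRecord]:
    """Read a long-format outcome table into records.

    The file must have header columns ``compound_id``, ``assay_id`` and
    ``outcome``; outcome strings are matched case-insensitively against
    {active, inactive, inconclusive, untested}.  An unknown outcome string
    raises a :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    delim = _delimiter(path, dialect)
    records: list[OutcomeRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter=delim
        )
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row") from None
        _require_columns(header, ("compound_id", "assay_id", "outcome"), path)
        idx = {name: header.index(name) for name in ("compound_id", "assay_id", "outcome")}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                outcome = Outcome.from_string(row[idx["outcome"]])
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from None
            records.append(
                OutcomeRecord(
                    compound_id=row[idx["compound_id"]].strip(),
                    assay_id=row[idx["assay_id"]].strip(),
                    outcome=outcome,
                )
            )
    return records


def read_labels(path: str | Path, dialect: str | None = None) -> ToxicityLabels:
    """Read a compound toxicity table.

    Requires a ``compound_id`` column plus either ``neg_log_ld50`` (the
    class is then derived from the 3.00 / 2.00 thresholds) or ``tox_class``
    with values in {toxic, marginal, nontoxic}.
    """
    path = Path(path)
    delim = _delimiter(path, dialect)
    df = pd.read_csv(path, sep=delim, comment="#", dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'compound_id'")
    df = df.set_index("compound_id")
    if "neg_log_ld50" in df.columns:
        vals = pd.to_numeric(df["neg_log_ld50"], errors="raise")
        return ToxicityLabels.from_ld50(vals)
    if "tox_class" in df.columns:
        classes = df["tox_class"].astype(str).str.strip().str.lower()
        try:
            return ToxicityLabels(classes=classes)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    raise FormatError(f"{path}: need a 'neg_log_ld50' or 'tox_class' column")


def write_labels(labels: ToxicityLabels, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"compound_id": labels.classes.index, "tox_class": labels.classes.values})
    if labels.neg_log_ld50 is not None:
        df["neg_log_ld50"] = labels.neg_log_ld50.reindex(labels.classes.index).values
    df.to_csv(path, sep="\t", index=False)


def _write_comments(fh, comments: Mapping[str, object] | None) -> None:
    if comments:
        for key, val in comments.items():
            fh.write(f"# {key}: {val}\n")


def write_matrix(
    m: ResponseMatrix,
    path: str | Path,
    comments: Mapping[str, object] | None = None,
) -> None:
    """Write the matrix as wide TSV (first column ``compound_id``)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_comments(fh, comments)
        fh.write("\t".join(["compound_id", *m.assay_ids]) + "\n")
        for cid, row in zip(m.compound_ids, m.data.to_numpy()):
            fh.write("\t".join([cid, *(str(int(v)) for v in row)]) + "\n")


def read_matrix(path: str | Path) -> ResponseMatrix:
    """Read a wide-TSV matrix written by :func:`write_matrix`.

    Any cell outside {1, -1, 0} raises a :class:`FormatError` naming the
    (compound, assay) coordinates.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if not header or header[0] != "compound_id":
        raise FormatError(f"{path}: first column must be 'compound_id'")
    assay_ids = header[1:]
    compound_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}, line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        cid = fields[0]
        row = []
        for aid, cell in zip(assay_ids, fields[1:]):
            try:
                val = int(cell)
            except ValueError:
                val = None
            if val not in (-1, 0, 1):
                raise FormatError(
                    f"{path}: cell ({cid}, {aid}) has value {cell!r}, expected 1, -1 or 0"
                )
            row.append(val)
        compound_ids.append(cid)
        rows.append(row)
    df = pd.DataFrame(
        np.asarray(rows, dtype=np.int8).reshape(len(rows), len(assay_ids)),
        index=pd.Index(compound_ids, dtype=str),
        columns=pd.Index(assay_ids, dtype=str),
    )
    return ResponseMatrix(df)


def write_matrix_long(
    m: ResponseMatrix,
    path: str | Path,
    comments: Mapping[str, object] | None = None,
) -> None:
    """Sparse long-format TSV: 0 cells are omitted, but the full id universe
    is preserved in ``## compounds:`` / ``## assays:`` header comments so the
    round trip is exact even for all-zero rows or columns."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_comments(fh, comments)
        fh.write("## compounds: " + ",".join(m.compound_ids) + "\n")
        fh.write("## assays: " + ",".join(m.assay_ids) + "\n")
        fh.write("compound_id\tassay_id\tvalue\n")
        arr = m.data.to_numpy()
        for i, cid in enumerate(m.compound_ids):
            for j, aid in enumerate(m.assay_ids):
                if arr[i, j] != 0:
                    fh.write(f"{cid}\t{aid}\t{int(arr[i, j])}\n")


def read_matrix_long(path: str | Path) -> ResponseMatrix:
    path = Path(path)
    compounds: list[str] | None = None
    assays: list[str] | None = None
    data_lines: list[tuple[int, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("## compounds:"):
                tail = line.split(":", 1)[1].strip()
                compounds = tail.split(",") if tail else []
            elif line.startswith("## assays:"):
                tail = line.split(":", 1)[1].strip()
                assays = tail.split(",") if tail else []
            elif line.startswith("#") or not line.strip():
                continue
            else:
                data_lines.append((lineno, line))
    if compounds is None or assays is None:
        raise FormatError(f"{path}: missing '## compounds:' / '## assays:' header")
    if not data_lines or data_lines[0][1].split("\t") != ["compound_id", "assay_id", "value"]:
        raise FormatError(f"{path}: expected header 'compound_id\\tassay_id\\tvalue'")
    df = pd.DataFrame(
        np.zeros((len(compounds), len(assays)), dtype=np.int8),
        index=pd.Index(compounds, dtype=str),
        columns=pd.Index(assays, dtype=str),
    )
    for lineno, line in data_lines[1:]:
        cid, aid, cell = line.split("\t")
        try:
            val = int(cell)
        except ValueError:
            val = None
        if val not in (-1, 1):
            raise FormatError(
                f"{path}: cell ({cid}, {aid}) has value {cell!r}, expected 1 or -1"
            )
        if cid not in df.index or aid not in df.columns:
            raise FormatError(f"{path}, line {lineno}: unknown id pair ({cid}, {aid})")
        df.at[cid, aid] = val
    return ResponseMatrix(df)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    comments: Mapping[str, object] | None = None,
) -> None:
    """Write an analysis result table (relevance ranking, compound scores)
    as TSV with an optional ``# key: value`` provenance header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_comments(fh, comments)
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
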