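"""Readers and writers for the pipeline's tab-separated interchange formats.

Three tables move between stages:

* expression table — ``gene_id<TAB>rep1<TAB>rep2 ...``, one row per gene;
* time-course reference — ``gene_id<TAB>0-2<TAB>2-4 ...`` with bin labels
  ``start-end`` in hours;
* differential-expression table — one row per gene with status, condition
  means, log2 fold change, p, q and direction.

All tables carry a mandatory header, use "." as the decimal separator and
no thousands separators. Structural problems (ragged rows, duplicate ids,
bad bin labels) raise :class:`TableFormatError`; bad cell values raise
``ValueError`` naming the offending row and column.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import DEResult, ExpressionMatrix, TimeCourseReference


class TableFormatError(ValueError):
    """A table's structure (not a cell value) violates the format contract."""


def _read_rows(path: str | Path) -> list[list[str]]:
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t") if row]
    if len(rows) < 2:
        raise TableFormatError(f"{path}: expected a header row and at least one data row")
    width = len(rows[0])
    for lineno, row in enumerate(rows, start=1):
        if len(row) != width:
            raise TableFormatError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, header has {width})"
            )
    return rows


def _parse_cell(text: str, path: str | Path, gene: str, column: str) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric value {text!r} at gene {gene!r}, column {column!r}"
        ) from None
    if math.isnan(value):
        raise ValueError(f"{path}: missing value at gene {gene!r}, column {column!r}")
    if value < 0:
        raise ValueError(
            f"{path}: negative value {value} at gene {gene!r}, column {column!r}"
        )
    return value


def _parse_body(
    rows: list[list[str]], path: str | Path
) -> tuple[list[str], np.ndarray]:
    header = rows[0]
    gene_ids: list[str] = []
    seen: set[str] = set()
    body = np.empty((len(rows) - 1, len(header) - 1), dtype=float)
    for i, row in enumerate(rows[1:]):
        gene = row[0]
        if gene in seen:
            raise TableFormatError(f"{path}: duplicate gene id {gene!r}")
        seen.add(gene)
        gene_ids.append(gene)
        for j, text in enumerate(row[1:]):
            body[i, j] = _parse_cell(text, path, gene, header[j + 1])
    return gene_ids, body


def read_expression_table(
    path: str | Path, unit: str = "FPKM", condition_label: str = ""
) -> ExpressionMatrix:
    """Read a gene x replicate expression TSV into an :class:`ExpressionMatrix`.

    Row order is preserved. Duplicate gene ids and ragged rows raise
    :class:`TableFormatError`; negative or non-numeric cells raise
    ``ValueError`` naming the gene and column.
    """
    rows = _read_rows(path)
    if len(rows[0]) < 2:
        raise TableFormatError(f"{path}: expected gene_id plus >=1 replicate column")
    gene_ids, body = _parse_body(rows, path)
    return ExpressionMatrix(gene_ids, body, unit=unit, condition_label=condition_label)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    header = ["gene_id"] + [f"rep{j + 1}" for j in range(matrix.n_replicates)]
    _write_numeric_table(path, header, matrix.gene_ids, matrix.values)


def _parse_bin_label(label: str, path: str | Path) -> tuple[float, float]:
    parts = label.split("-")
    if len(parts) != 2:
        raise TableFormatError(f"{path}: bad bin label {label!r} (expected 'start-end')")
    try:
        a, b = float(parts[0]), float(parts[1])
    except ValueError:
        raise TableFormatError(f"{path}: non-numeric bin label {label!r}") from None
    if not b > a:
        raise TableFormatError(f"{path}: empty bin {label!r}")
    return a, b


def read_time_course(path: str | Path) -> TimeCourseReference:
    """Read a developmental reference TSV into a :class:`TimeCourseReference`.

    Bin columns may arrive in any order; they are sorted by start hour and
    then validated as non-overlapping and contiguous, so a column-permuted
    table parses to the same object as its sorted form.
    """
    rows = _read_rows(path)
    if len(rows[0]) < 2:
        raise TableFormatError(f"{path}: expected gene_id plus >=1 bin column")
    bins = [_parse_bin_label(lab, path) for lab in rows[0][1:]]
    order = sorted(range(len(bins)), key=lambda i: bins[i])
    gene_ids, body = _parse_body(rows, path)
    try:
        return TimeCourseReference(
            gene_ids, [bins[i] for i in order], body[:, order]
        )
    except ValueError as exc:  # overlapping/non-contiguous bins are a format fault
        raise TableFormatError(f"{path}: {exc}") from None


def write_time_course(reference: TimeCourseReference, path: str | Path) -> None:
    header = ["gene_id"] + reference.bin_labels
    _write_numeric_table(path, header, reference.gene_ids, reference.values)


def _write_numeric_table(
    path: str | Path, header: Sequence[str], gene_ids: Sequence[str], values: np.ndarray
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for gene, row in zip(gene_ids, values):
            writer.writerow([gene] + [_fmt(v) for v in row])


def _fmt(v: float) -> str:
    # repr round-trips floats exactly, keeping read(write(x)) an identity
    return str(int(v)) if float(v).is_integer() else repr(float(v))


DE_COLUMNS = [
    "gene_id",
    "status",
    "mean_control",
    "mean_mutant",
    "log2fc",
    "p",
    "q",
    "direction",
]


def write_de_table(results: Iterable[DEResult], path: str | Path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "status": r.status,
                "mean_control": r.mean_control,
                "mean_mutant": r.mean_mutant,
                "log2fc": "" if r.log2_fold_change is None else r.log2_fold_change,
                "p": "" if r.p_value is None else r.p_value,
                "q": "" if r.q_value is None else r.q_value,
                "direction": r.direction,
            }
        )
    pd.DataFrame(rows, columns=DE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> list[DEResult]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    results = []
    for row in df.itertuples(index=False):
        results.append(
            DEResult(
                gene_id=row.gene_id,
                status=row.status,
                mean_control=float(row.mean_control),
                mean_mutant=float(row.mean_mutant),
                log2_fold_change=_opt(row.log2fc),
                p_value=_opt(row.p),
                q_value=_opt(row.q),
                direction=row.direction,
            )
        )
    return results


def _opt(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_annotation_table(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a ``gene_id<TAB>term_id<TAB>term_name`` annotation TSV.

    Returns (gene -> set of term ids, term id -> term name).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id"}
    if not required <= set(df.columns):
        raise TableFormatError(f"{path}: expected columns gene_id, term_id[, term_name]")
    gene_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene_terms.setdefault(row.gene_id, set()).add(row.term_id)
        if "term_name" in df.columns and isinstance(row.term_name, str):
            term_names[row.term_id] = row.term_name
    return gene_terms, term_names


def read_edge_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a ``parent_id<TAB>child_id`` term-hierarchy edge TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"parent_id", "child_id"} <= set(df.columns):
        raise TableFormatError(f"{path}: expected columns parent_id, child_id")
    return [(row.parent_id, row.child_id) for row in df.itertuples(index=False)]
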