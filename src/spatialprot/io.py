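"""Readers and writers for the tab-delimited formats the pipeline touches.

Dialect: UTF-8, tab-delimited, ``#`` comment lines ignored, missing values
encoded as the literal ``NA``.  Writers emit a deterministic column order and
format floats with 12 significant digits so that write-then-read round-trips
are exact for decimal representations of <= 12 significant digits.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    PSM_META_COLUMNS,
    AnnotationSet,
    DesignTable,
    FormatError,
    ProteinMatrix,
    PsmTable,
    QpcrTable,
    ValidationError,
)

_FLOAT_FMT = "%.12g"
_BOOL_TRUE = {"true", "1", "yes"}
_BOOL_FALSE = {"false", "0", "no"}


def _fmt(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if isinstance(value, (float, np.floating)):
        return _FLOAT_FMT % value
    return str(value)


def _parse_bool(raw: str, *, context: str) -> bool:
    low = raw.strip().lower()
    if low in _BOOL_TRUE:
        return True
    if low in _BOOL_FALSE:
        return False
    raise FormatError(f"cannot parse boolean {raw!r} in {context}")


def _read_rows(path) -> tuple[list[str], list[list[str]]]:
    """Read a commented TSV into (header, rows) without reordering."""
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None:
        raise FormatError(f"{path}: empty file, no header")
    return header, rows


def _write_table(path, header: list[str], rows) -> None:
    buf = _io.StringIO()
    buf.write("\t".join(header) + "\n")
    for row in rows:
        buf.write("\t".join(_fmt(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def read_psm_table(path) -> PsmTable:
    """Parse a PSM-level reporter-intensity table.

    Raises :class:`FormatError` when a required column is absent and
    :class:`ValidationError` (citing the row index) for unparseable or
    negative intensities.
    """
    header, rows = _read_rows(path)
    missing = [c for c in PSM_META_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    channels = [c for c in header if c not in PSM_META_COLUMNS]
    if not channels:
        raise FormatError(f"{path}: no intensity columns found")
    idx = {c: header.index(c) for c in header}
    records = []
    for i, fields in enumerate(rows):
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: row {i} has {len(fields)} fields, expected {len(header)}"
            )
        rec: dict = {
            "peptide_id": fields[idx["peptide_id"]],
            "protein_group": fields[idx["protein_group"]],
            "proteotypic": _parse_bool(fields[idx["proteotypic"]], context=f"row {i}"),
            "is_contaminant": _parse_bool(
                fields[idx["is_contaminant"]], context=f"row {i}"
            ),
            "is_decoy": _parse_bool(fields[idx["is_decoy"]], context=f"row {i}"),
        }
        for ch in channels:
            raw = fields[idx[ch]]
            try:
                val = float(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}: unparseable intensity {raw!r} at row {i}, channel {ch}"
                ) from None
            if not np.isfinite(val) or val < 0:
                raise ValidationError(
                    f"{path}: invalid intensity {raw!r} at row {i}, channel {ch}"
                )
            rec[ch] = val
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=list(PSM_META_COLUMNS) + channels)
    if not records:
        df = pd.DataFrame(columns=list(PSM_META_COLUMNS) + channels)
        df[channels] = df[channels].astype(float)
    return PsmTable(df=df, channels=channels)


def write_psm_table(psm: PsmTable, path) -> None:
    header = list(PSM_META_COLUMNS) + psm.channels
    _write_table(path, header, psm.df[header].itertuples(index=False))


# ---------------------------------------------------------------------------
# Design tables
# ---------------------------------------------------------------------------

def read_design(path) -> DesignTable:
    header, rows = _read_rows(path)
    required = ["channel", "patient", "region"]
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    idx = {c: header.index(c) for c in required}
    mapping: dict[str, tuple[str, str]] = {}
    for i, fields in enumerate(rows):
        ch = fields[idx["channel"]]
        if ch in mapping:
            raise ValidationError(f"{path}: channel {ch!r} mapped twice (row {i})")
        mapping[ch] = (fields[idx["patient"]], fields[idx["region"]])
    return DesignTable(mapping=mapping)


def write_design(design: DesignTable, path) -> None:
    rows = [(ch, p, r) for ch, (p, r) in design.mapping.items()]
    _write_table(path, ["channel", "patient", "region"], rows)


# ---------------------------------------------------------------------------
# Protein matrices
# ---------------------------------------------------------------------------

def read_protein_matrix(path) -> ProteinMatrix:
    header, rows = _read_rows(path)
    if header[:2] != ["protein_group", "n_peptides"]:
        raise FormatError(
            f"{path}: expected leading columns 'protein_group', 'n_peptides'"
        )
    samples = header[2:]
    index, n_pep, values = [], [], []
    for i, fields in enumerate(rows):
        index.append(fields[0])
        n_pep.append(int(fields[1]))
        vals = []
        for s, raw in zip(samples, fields[2:]):
            if raw == "NA":
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(raw))
                except ValueError:
                    raise ValidationError(
                        f"{path}: unparseable value {raw!r} at row {i}, sample {s}"
                    ) from None
        values.append(vals)
    df = pd.DataFrame(values, index=pd.Index(index, name="protein_group"), columns=samples)
    return ProteinMatrix(
        values=df, n_peptides=pd.Series(n_pep, index=df.index, name="n_peptides")
    )


def write_protein_matrix(pm: ProteinMatrix, path) -> None:
    header = ["protein_group", "n_peptides"] + pm.samples
    rows = (
        [prot, int(pm.n_peptides.loc[prot])] + [pm.values.at[prot, s] for s in pm.samples]
        for prot in pm.proteins
    )
    _write_table(path, header, rows)


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def read_qpcr(path) -> QpcrTable:
    header, rows = _read_rows(path)
    required = ["sample", "gene", "ct"]
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    idx = {c: header.index(c) for c in required}
    records = []
    for i, fields in enumerate(rows):
        try:
            ct = float(fields[idx["ct"]])
        except ValueError:
            raise ValidationError(
                f"{path}: unparseable Ct {fields[idx['ct']]!r} at row {i}"
            ) from None
        records.append((fields[idx["sample"]], fields[idx["gene"]], ct))
    df = pd.DataFrame(records, columns=["sample", "gene", "ct"])
    return QpcrTable(df=df)


def write_qpcr(table: QpcrTable, path) -> None:
    _write_table(path, ["sample", "gene", "ct"], table.df.itertuples(index=False))


# ---------------------------------------------------------------------------
# Gene sets and annotations
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: term, description, members (tab-delimited)."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            term = fields[0]
            if term in sets:
                raise FormatError(f"{path}: duplicate term id {term!r} at line {lineno}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise FormatError(f"{path}: term {term!r} has no members (line {lineno})")
            sets[term] = members
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, members in gene_sets.items():
            fh.write("\t".join([term, term] + sorted(members)) + "\n")


def read_annotations(path) -> AnnotationSet:
    """Read a protein annotation table with columns protein_group, compartment."""
    header, rows = _read_rows(path)
    required = ["protein_group", "compartment"]
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    idx = {c: header.index(c) for c in required}
    compartment = {}
    for fields in rows:
        label = fields[idx["compartment"]]
        if label and label != "NA":
            compartment[fields[idx["protein_group"]]] = label
    return AnnotationSet(compartment=compartment)


def write_annotations(annotations: AnnotationSet, path) -> None:
    rows = [(p, c) for p, c in annotations.compartment.items()]
    _write_table(path, ["protein_group", "compartment"], rows)


def read_fold_changes(path) -> dict[str, float]:
    """Read a two-column protein -> log2 fold-change table."""
    header, rows = _read_rows(path)
    if len(header) < 2:
        raise FormatError(f"{path}: expected >= 2 columns (protein, log2_fc)")
    fc = {}
    for i, fields in enumerate(rows):
        if fields[1] == "NA":
            continue
        try:
            fc[fields[0]] = float(fields[1])
        except ValueError:
            raise ValidationError(
                f"{path}: unparseable fold change {fields[1]!r} at row {i}"
            ) from None
    return fc


def write_fold_changes(fc: dict[str, float], path) -> None:
    _write_table(path, ["protein_group", "log2_fc"], fc.items())
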