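"""Read, validate and write summary-statistics and pipeline tables.

Input tables are delimited text (tab or comma, auto-detected from the
header line).  Column headers can be remapped to the canonical names via
``column_map``.  Rows violating record invariants are rejected
individually and logged; a table where more than half the rows fail is
considered mislabelled and rejected wholesale.

All pipeline outputs are tab-delimited with a header line and floats at
6 significant digits; every writer round-trips through the generic reader
at that precision.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .records import (
    AncestryStratum,
    SchemaError,
    ValidationError,
    VariantRecord,
    record_fields,
)

logger = logging.getLogger(__name__)

#: canonical summary-statistics column names
CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p_value",
    "eaf",
    "locus",
)

FLOAT_FORMAT = "%.6g"


def _detect_separator(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path,
    ancestry_label: str,
    column_map: Optional[Mapping[str, str]] = None,
) -> AncestryStratum:
    """Load one ancestry's summary statistics into a validated stratum.

    Parameters
    ----------
    path
        Delimited text file; separator auto-detected from the header line
        (tab preferred, comma fallback).
    ancestry_label
        Label stamped on every record (the file need not carry one).
    column_map
        Maps canonical field names to the file's column headers.  Supply
        ``"odds_ratio"`` instead of ``"beta"`` when the file reports OR;
        beta is then computed as its natural log.  Defaults to the
        canonical names themselves (with an ``odds_ratio`` fallback if the
        file has no ``beta`` column).

    Returns
    -------
    AncestryStratum
        Row order preserved; rows failing record invariants are dropped
        and logged.

    Raises
    ------
    SchemaError
        A mapped column is absent, or more than 50% of rows fail
        validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_separator(path)
    df = pd.read_csv(path, sep=sep, dtype=str)

    cmap = dict(column_map) if column_map else {c: c for c in CANONICAL_COLUMNS}
    if column_map is None and "beta" not in df.columns and "odds_ratio" in df.columns:
        del cmap["beta"]
        cmap["odds_ratio"] = "odds_ratio"
    uses_or = "odds_ratio" in cmap
    if uses_or and "beta" in cmap:
        raise SchemaError("column_map must name either 'beta' or 'odds_ratio', not both")

    required = [c for c in CANONICAL_COLUMNS if c not in ("beta",)] + (
        ["odds_ratio"] if uses_or else ["beta"]
    )
    for canonical in required:
        header = cmap.get(canonical, canonical)
        if header not in df.columns:
            raise SchemaError(f"missing column {header!r} (mapped from {canonical!r}) in {path}")

    records: list[VariantRecord] = []
    n_failed = 0
    for idx, row in df.iterrows():
        try:
            if uses_or:
                odds_ratio = float(row[cmap.get("odds_ratio", "odds_ratio")])
                if odds_ratio <= 0:
                    raise ValidationError(f"row {idx}: non-positive odds ratio {odds_ratio}")
                beta = math.log(odds_ratio)
            else:
                beta = float(row[cmap.get("beta", "beta")])
            rec = VariantRecord(
                variant_id=str(row[cmap.get("variant_id", "variant_id")]),
                chrom=str(row[cmap.get("chrom", "chrom")]),
                pos=int(row[cmap.get("pos", "pos")]),
                effect_allele=str(row[cmap.get("effect_allele", "effect_allele")]).upper(),
                other_allele=str(row[cmap.get("other_allele", "other_allele")]).upper(),
                beta=beta,
                se=float(row[cmap.get("se", "se")]),
                p_value=float(row[cmap.get("p_value", "p_value")]),
                eaf=float(row[cmap.get("eaf", "eaf")]),
                locus=str(row[cmap.get("locus", "locus")]),
                ancestry=ancestry_label,
            )
        except (ValidationError, ValueError) as exc:
            n_failed += 1
            logger.warning("%s row %d rejected: %s", path.name, idx, exc)
            continue
        records.append(rec)

    n_total = len(df)
    if n_total > 0 and n_failed * 2 > n_total:
        raise SchemaError(
            f"{path}: {n_failed}/{n_total} rows failed validation; input presumed malformed"
        )
    stratum = AncestryStratum(label=ancestry_label, variants=records, source_name=str(path))
    n_palindromic = sum(v.is_palindromic for v in records)
    if n_palindromic:
        logger.warning(
            "%s: %d strand-ambiguous (A/T or C/G) SNPs passed through unresolved",
            path.name,
            n_palindromic,
        )
    return stratum


def _format_value(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return FLOAT_FORMAT % value
    return str(value)


def write_table(records: Sequence, path) -> None:
    """Write homogeneous records as tab-delimited text with a header.

    Floats render at 6 significant digits; an empty collection still
    produces a header line when a record type can be inferred (an empty
    untyped collection raises).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot infer columns from an empty untyped collection; "
                         "use write_empty_table(record_type, path)")
    rtype = type(records[0])
    if any(type(r) is not rtype for r in records):
        raise TypeError("records must share one type")
    write_records(records, rtype, path)


def write_records(records: Sequence, record_type, path) -> None:
    """Like :func:`write_table` but explicit about the type (allows empty)."""
    cols = record_fields(record_type)
    rows = [
        {name: _format_value(getattr(r, name)) for name in cols} for r in records
    ]
    df = pd.DataFrame(rows, columns=list(cols))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_empty_table(record_type, path) -> None:
    write_records([], record_type, path)


_BOOL = {"True": True, "False": False, "true": True, "false": False}


def read_table(path, record_type) -> list:
    """Read a tab-delimited table written by :func:`write_table` back into
    records of ``record_type``, casting each column per its annotation."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    casts = {}
    for f in dataclasses.fields(record_type):
        ann = f.type if isinstance(f.type, type) else str(f.type)
        if ann in (int, "int"):
            casts[f.name] = int
        elif ann in (float, "float"):
            casts[f.name] = float
        elif ann in (bool, "bool"):
            casts[f.name] = _BOOL.__getitem__
        else:
            casts[f.name] = str
    names = record_fields(record_type)
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for {record_type.__name__}")
    out = []
    for _, row in df.iterrows():
        out.append(record_type(**{n: casts[n](row[n]) for n in names}))
    return out
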