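"""Readers and writers for the pipeline's plain-text formats.

Wide TSV/CSV intensity matrices (first column protein IDs, optional gene
column, remaining columns samples), TSV/CSV sample metadata, GMT annotation
catalogs, and generic result tables. Parsing is locale-independent
(decimal point only) and round-trips preserve values, missingness and
ordering.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationCatalog,
    AnnotationTerm,
    IntensityMatrix,
    ProteinRecord,
    SampleMeta,
    Scale,
)

__all__ = [
    "read_intensity_matrix",
    "write_intensity_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_annotations",
    "write_annotations",
    "write_table",
    "read_table",
]

logger = logging.getLogger(__name__)

#: Cell contents treated as missing by default. "0" is included because DIA
#: software conventionally exports unquantified proteins as zero intensity.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "0", "0.0"})

_GENE_COLUMN_NAMES = {"gene", "gene_name", "genes", "gene_names"}
_ISOFORM_COLUMN_NAMES = {"isoform", "isoform_tag"}


def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_intensity_matrix(
    path: str | Path,
    dialect: str = "tsv",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> IntensityMatrix:
    """Parse a wide intensity table into a linear-scale IntensityMatrix.

    The first column holds protein-group IDs; a column named gene/gene_name
    (any case) directly after it is read as gene names, likewise an optional
    isoform/isoform_tag column. All remaining columns are samples. Cells
    matching ``missing_tokens`` become missing; anything else must parse as
    a positive float.
    """
    tokens = {str(t) for t in missing_tokens}
    df = pd.read_csv(Path(path), sep=_sep(dialect), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("intensity table needs a protein column and >= 1 sample")
    cols = list(df.columns)
    protein_col = cols[0]
    gene_col = next((c for c in cols[1:] if c.lower() in _GENE_COLUMN_NAMES), None)
    iso_col = next((c for c in cols[1:] if c.lower() in _ISOFORM_COLUMN_NAMES), None)
    annot_cols = [c for c in (gene_col, iso_col) if c is not None]
    sample_cols = [c for c in cols[1:] if c not in annot_cols]
    if not sample_cols:
        raise ValueError("no sample columns found")

    ids = df[protein_col].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate protein IDs in {path}: {dupes}")

    values = np.full((len(ids), len(sample_cols)), np.nan)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in tokens:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at protein {ids[i]!r}, sample {col!r}: {cell!r}"
                ) from None

    proteins = [
        ProteinRecord(
            protein_id=pid,
            gene_name=(df[gene_col].iloc[i] if gene_col else ""),
            isoform_tag=(df[iso_col].iloc[i] or None) if iso_col else None,
        )
        for i, pid in enumerate(ids)
    ]
    frame = pd.DataFrame(values, index=pd.Index(ids, name=protein_col), columns=sample_cols)
    return IntensityMatrix(proteins=proteins, values=frame, scale=Scale.LINEAR)


def write_intensity_matrix(
    matrix: IntensityMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a matrix in the wide format read_intensity_matrix accepts."""
    df = matrix.values.copy()
    df.index.name = "protein_id"
    genes = [p.gene_name for p in matrix.proteins]
    if any(genes):
        df.insert(0, "gene_name", genes)
    df.to_csv(Path(path), sep=_sep(dialect), float_format="%.10g", na_rep="")


_META_NUMERIC = {"age", "t_tau", "p_tau181", "ab42", "ab40"}


def read_sample_metadata(path: str | Path, dialect: str = "tsv") -> list[SampleMeta]:
    """Parse per-sample metadata; unknown columns are ignored with a warning."""
    df = pd.read_csv(Path(path), sep=_sep(dialect), dtype=str, keep_default_na=False)
    known = {f.name for f in dataclasses.fields(SampleMeta)}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown metadata columns: %s", unknown)
    if "sample_id" not in df.columns:
        raise ValueError("metadata requires a sample_id column")
    ids = df["sample_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate sample IDs: {dupes}")

    records = []
    for _, row in df.iterrows():
        kwargs: dict = {}
        for name in known & set(df.columns):
            cell = str(row[name]).strip()
            if cell in ("", "NA", "NaN", "nan"):
                continue
            if name in _META_NUMERIC:
                kwargs[name] = float(cell)
            elif name == "mmse":
                kwargs[name] = int(float(cell))
            elif name == "control_override":
                kwargs[name] = cell.lower() in ("true", "1", "yes")
            else:
                kwargs[name] = cell
        if "cohort" not in kwargs:
            raise ValueError(f"sample {kwargs.get('sample_id')}: cohort is required")
        records.append(SampleMeta(**kwargs))
    return records


def write_sample_metadata(
    metas: Sequence[SampleMeta], path: str | Path, dialect: str = "tsv"
) -> None:
    df = pd.DataFrame([vars(m) for m in metas])
    df.to_csv(Path(path), sep=_sep(dialect), index=False, float_format="%.10g", na_rep="")


def read_annotations(path: str | Path) -> AnnotationCatalog:
    """Parse a GMT file (term <tab> description <tab> member...) into a catalog.

    Duplicate members within a line are stored once; terms that end up with
    no members are dropped with a warning.
    """
    terms: dict[str, AnnotationTerm] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        term_id, description = parts[0], parts[1]
        members = frozenset(m for m in parts[2:] if m)
        if not members:
            logger.warning("dropping empty term %s (line %d)", term_id, lineno)
            continue
        category = "other"
        upper = term_id.upper()
        if upper.startswith("GOBP") or "BIOLOGICAL_PROCESS" in upper:
            category = "GOBP"
        elif upper.startswith("GOCC") or "CELLULAR_COMPONENT" in upper:
            category = "GOCC"
        elif upper.startswith("KW") or "KEYWORD" in upper:
            category = "Keyword"
        terms[term_id] = AnnotationTerm(
            term_id=term_id, category=category, description=description, members=members
        )
    return AnnotationCatalog(terms=terms)


def write_annotations(catalog: AnnotationCatalog, path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, t.description, *sorted(t.members)]) for t in catalog
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_table(
    rows, path: str | Path, dialect: str = "tsv", columns: Sequence[str] | None = None
) -> None:
    """Write homogeneous result records (dataclasses, dicts or a DataFrame).

    Column order is deterministic (field order of the first record); floats
    are serialized with 10 significant digits; missing values as "". For an
    empty record list pass ``columns`` to still emit a header-only file.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        dicts = [vars(r) if dataclasses.is_dataclass(r) else dict(r) for r in rows]
        df = pd.DataFrame(dicts, columns=columns if (columns or not dicts) else None)
    df.to_csv(Path(path), sep=_sep(dialect), index=False, float_format="%.10g", na_rep="")


def read_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    return pd.read_csv(Path(path), sep=_sep(dialect))
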